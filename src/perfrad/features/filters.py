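"""Image filter bank: Laplacian-of-Gaussian and one-level 3D wavelet.

LoG images carry a scale-space response (sigma in mm, converted to voxel
units per axis); the wavelet transform is a one-level undecimated 3D
decomposition (coif1), yielding eight same-shape sub-bands named by the
L/H sequence applied along (z, y, x).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import gaussian_laplace

__all__ = ["log_image", "wavelet_bands", "WAVELET_BAND_NAMES"]

WAVELET_BAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def log_image(
    image: np.ndarray, sigma_mm: float, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response at ``sigma_mm``."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in spacing]
    # sigma^2 scale normalization keeps responses comparable across scales
    return sigma_mm**2 * gaussian_laplace(np.asarray(image, float), sigma=sigma_vox)


def wavelet_bands(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """One-level undecimated 3D wavelet decomposition into 8 sub-bands.

    Sub-bands have the same shape as the input (odd axes are edge-padded
    to even length for the transform and cropped back), so the original
    ROI mask applies unchanged.
    """
    image = np.asarray(image, float)
    if image.ndim != 3:
        raise ValueError("expected a 3D image")
    shape = image.shape
    pad = [(0, s % 2) for s in shape]
    padded = np.pad(image, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = {}
    for key, arr in coeffs.items():
        band = "".join("L" if c == "a" else "H" for c in key)
        out[band] = arr[: shape[0], : shape[1], : shape[2]]
    return {name: out[name] for name in WAVELET_BAND_NAMES}
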