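"""Temporal smoothing, hemisphere/ROI geometry, and feature normalization.

Smoothing is a triple moving average: three successive passes of a
centered 1x3 mean filter along the time axis with repeat-padded edges,
applied voxel-by-voxel.  Feature normalization is mean-centered range
scaling, F* = (F - mean(F)) / (max(F) - min(F)), applied per column; a
conventional min-max variant is available behind a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingConfig", "smooth_time_series", "mirror_roi",
    "split_hemispheres", "normalize_features",
]


@dataclass(frozen=True)
class SmoothingConfig:
    window: int = 3
    passes: int = 3
    edge_mode: str = "repeat-pad"

    def __post_init__(self) -> None:
        if self.window != 3 or self.window % 2 == 0:
            raise ValueError("window is fixed at 3")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.edge_mode != "repeat-pad":
            raise ValueError("only repeat-pad edges are supported")


def smooth_time_series(
    volume: np.ndarray, cfg: SmoothingConfig = SmoothingConfig()
) -> np.ndarray:
    """Apply ``cfg.passes`` centered length-3 moving averages along axis 0.

    Edges are repeat-padded (first/last sample replicated), so constant
    series are exact fixed points.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to smooth")
    out = volume
    for _ in range(cfg.passes):
        # mode='nearest' replicates the edge sample: repeat-pad
        out = uniform_filter1d(out, size=cfg.window, axis=0, mode="nearest")
    return out


def mirror_roi(mask: np.ndarray) -> np.ndarray:
    """Reflect a (z, y, x) mask about the mid-x plane x = (W - 1) / 2."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z, y, x)")
    return mask[:, :, ::-1].copy()


def split_hemispheres(
    volume: np.ndarray, brain_mask: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Split into (left, right) hemisphere samples.

    Returns ``((volume, mask), (volume, mask))`` with the hemisphere-
    restricted brain masks; for odd widths the midline column belongs to
    neither side.  Volumes are returned unsliced — the masks carry the
    hemisphere restriction, which keeps downstream mirror geometry intact.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    W = brain_mask.shape[-1]
    half = W // 2
    left = brain_mask.copy()
    left[..., half:] = False
    right = brain_mask.copy()
    right[..., : W - half] = False
    return (volume, left), (volume, right)


def normalize_features(
    table: pd.DataFrame, variant: str = "mean-range"
) -> pd.DataFrame:
    """Column-wise feature normalization.

    ``mean-range`` (default): (x - mean) / (max - min), so each output
    column has range exactly 1 and mean 0.  ``min-max``: (x - min) /
    (max - min).  Constant columns cannot be scaled and are dropped with
    a logged warning.
    """
    if variant not in ("mean-range", "min-max"):
        raise ValueError(f"unknown variant {variant!r}")
    values = table.to_numpy(dtype=float)
    rng = values.max(axis=0) - values.min(axis=0)
    constant = rng == 0
    if constant.any():
        dropped = table.columns[constant].tolist()
        logger.warning(
            "dropping %d constant feature column(s): %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    keep = ~constant
    values = values[:, keep]
    rng = rng[keep]
    if variant == "mean-range":
        out = (values - values.mean(axis=0)) / rng
    else:
        out = (values - values.min(axis=0)) / rng
    return pd.DataFrame(out, index=table.index, columns=table.columns[keep])
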