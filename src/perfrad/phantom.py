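"""Synthetic DSC-PWI phantom cohorts with ground-truth hypoperfusion masks.

A dynamic susceptibility contrast (DSC) perfusion series records the
first pass of a gadolinium bolus as a transient signal *drop*: the local
concentration time curve C(t) is well described by a gamma-variate, and
T2*-weighted signal follows I(t) = I0 * exp(-k * C(t)).  Hypoperfused
tissue receives less contrast agent later, so its signal drop is shallower
and delayed relative to healthy tissue.  The phantom reproduces exactly
this contrast between a grown hypoperfusion region (HA) and its
mirror-symmetric normal counterpart (NA), with per-voxel heterogeneity so
texture features are non-degenerate.

Array convention: volumes are (t, z, y, x), 0-based; the left/right
hemisphere axis is x, and mirroring reflects about x = (W - 1) / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionSpec", "BolusModel", "LesionSpec", "Phantom4D",
    "gamma_variate_curve", "signal_from_concentration",
    "generate_phantom", "generate_cohort", "save_phantom", "load_phantom",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry of one 4D acquisition.

    Defaults follow a typical 1.5T stroke protocol (50 dynamics, 20
    slices); the in-plane matrix defaults to 64x64 so the full pipeline
    runs quickly, with 256x256 supported.
    """

    n_timepoints: int = 50
    n_slices: int = 20
    height: int = 64
    width: int = 64
    slice_thickness_mm: float = 5.0
    spacing_mm: tuple[float, float] = (3.6, 3.6)  # (y, x) in-plane

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if min(self.n_slices, self.height, self.width) < 8:
            raise ValueError("all spatial dims must be >= 8")
        if self.slice_thickness_mm <= 0 or min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_timepoints, self.n_slices, self.height, self.width)

    @property
    def voxel_spacing(self) -> tuple[float, float, float]:
        """(z, y, x) spacing in mm."""
        return (self.slice_thickness_mm, *self.spacing_mm)


@dataclass(frozen=True)
class BolusModel:
    """Gamma-variate bolus passage and the DSC signal-loss relation.

    The concentration curve peaks at ``arrival_t0 + shape_alpha *
    scale_beta`` with value ``amplitude`` (peak-normalized gamma-variate);
    signal is ``baseline * exp(-contrast_k * C(t))``.
    """

    baseline: float = 300.0
    arrival_t0: float = 8.0
    shape_alpha: float = 3.0
    scale_beta: float = 1.5
    amplitude: float = 1.0
    contrast_k: float = 1.2

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape_alpha <= 0 or self.scale_beta <= 0:
            raise ValueError("shape_alpha and scale_beta must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """One hypoperfusion lesion.

    ``attenuation`` scales the bolus amplitude inside the lesion (1 means
    no effect) and ``delay`` shifts its arrival; together they reproduce
    the shallower, later signal drop of hypoperfused tissue.
    """

    hemisphere: str = "left"
    target_fraction: float = 0.2
    attenuation: float = 0.4
    delay: float = 2.0
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if not 0.0 <= self.target_fraction <= 0.7:
            raise ValueError("target_fraction must be in [0, 0.7]")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class Phantom4D:
    """A synthetic 4D acquisition with ground-truth ROI masks."""

    volume: np.ndarray          # (t, z, y, x) float
    brain_mask: np.ndarray      # (z, y, x) bool
    ha_mask: np.ndarray         # (z, y, x) bool, hypoperfusion
    na_mask: np.ndarray         # (z, y, x) bool, mirrored normal ROI
    achieved_fraction: float
    noise_sd: float
    seed: int
    acq: AcquisitionSpec = field(default=None)  # type: ignore[assignment]


def gamma_variate_curve(t: np.ndarray, model: BolusModel) -> np.ndarray:
    """Peak-normalized gamma-variate concentration curve on time grid ``t``.

    C(t) = amplitude * ((t - t0) / (alpha * beta))**alpha
                     * exp(alpha - (t - t0) / beta)   for t >= t0, else 0.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be a 1D ascending time grid")
    a, b, t0 = model.shape_alpha, model.scale_beta, model.arrival_t0
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    x = dt[pos] / (a * b)
    out[pos] = model.amplitude * np.power(x, a) * np.exp(a - dt[pos] / b)
    return out


def signal_from_concentration(C: np.ndarray, model: BolusModel) -> np.ndarray:
    """T2* signal from concentration: I(t) = baseline * exp(-k * C(t))."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    return model.baseline * np.exp(-model.contrast_k * C)


def _ellipsoid_brain_mask(acq: AcquisitionSpec) -> np.ndarray:
    """Axis-aligned ellipsoid, slightly shrunk at the top/bottom slices."""
    Z, H, W = acq.n_slices, acq.height, acq.width
    z, y, x = np.ogrid[:Z, :H, :W]
    cz, cy, cx = (Z - 1) / 2, (H - 1) / 2, (W - 1) / 2
    rz, ry, rx = 0.95 * Z / 2, 0.85 * H / 2, 0.80 * W / 2
    d = ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
    return d <= 1.0


def _grow_lesion(
    hemi_brain: np.ndarray, target_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow a 6-connected region inside ``hemi_brain`` to ``target_voxels``.

    Greedy randomized breadth-first growth from a random interior seed
    voxel; raises if the hemisphere cannot host the requested volume.
    """
    avail = int(hemi_brain.sum())
    if target_voxels > avail:
        raise ValueError(
            f"lesion of {target_voxels} voxels infeasible in hemisphere "
            f"of {avail} brain voxels"
        )
    lesion = np.zeros_like(hemi_brain)
    if target_voxels == 0:
        return lesion
    coords = np.argwhere(hemi_brain)
    # prefer a seed away from the hemisphere border so growth has room
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    seed_idx = coords[rng.choice(np.flatnonzero(d2 <= np.percentile(d2, 25)))]
    lesion[tuple(seed_idx)] = True
    frontier = [tuple(seed_idx)]
    n = 1
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    shape = hemi_brain.shape
    while n < target_voxels:
        if not frontier:
            raise ValueError("lesion growth exhausted the connected region")
        i = int(rng.integers(len(frontier)))
        vz, vy, vx = frontier[i]
        added = False
        for dz, dy, dx in offsets:
            nz, ny, nx_ = vz + dz, vy + dy, vx + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx_ < shape[2]):
                continue
            if hemi_brain[nz, ny, nx_] and not lesion[nz, ny, nx_]:
                lesion[nz, ny, nx_] = True
                frontier.append((nz, ny, nx_))
                n += 1
                added = True
                break
        if not added:
            frontier.pop(i)
    return lesion


def generate_phantom(
    acq: AcquisitionSpec = AcquisitionSpec(),
    bolus: BolusModel = BolusModel(),
    lesion: LesionSpec = LesionSpec(),
    noise_sd: float = 2.0,
    seed: int = 0,
) -> Phantom4D:
    """Simulate one 4D acquisition with an HA lesion and its mirrored NA.

    Lesion voxels use an attenuated, delayed bolus; every brain voxel gets
    ±5% jitter on arrival time and amplitude so in-ROI texture is
    non-degenerate; additive Gaussian noise with ``noise_sd`` everywhere.
    """
    rng = np.random.default_rng(seed)
    T, Z, H, W = acq.shape
    brain = _ellipsoid_brain_mask(acq)

    half = W // 2
    hemi = brain.copy()
    if lesion.hemisphere == "left":
        hemi[:, :, half:] = False
    else:
        hemi[:, :, : W - half] = False
    # keep the mirror inside the other hemisphere even for odd W
    if W % 2 == 1:
        hemi[:, :, half] = False

    hemi_n = int(hemi.sum())
    target_voxels = int(round(lesion.target_fraction * hemi_n))
    grow_rng = np.random.default_rng(lesion.geometry_seed)
    ha = _grow_lesion(hemi, target_voxels, grow_rng)
    na = ha[:, :, ::-1].copy()  # mirror about x = (W-1)/2
    achieved = ha.sum() / hemi_n if hemi_n else 0.0

    t = np.arange(T, dtype=float)
    flat_brain = np.flatnonzero(brain)
    nb = flat_brain.size
    flat_ha = ha.reshape(-1)[flat_brain]

    # per-voxel bolus heterogeneity: +-5% uniform jitter
    t0 = bolus.arrival_t0 * (1 + 0.05 * rng.uniform(-1, 1, nb))
    amp = bolus.amplitude * (1 + 0.05 * rng.uniform(-1, 1, nb))
    amp = np.where(flat_ha, amp * lesion.attenuation, amp)
    t0 = np.where(flat_ha, t0 + lesion.delay, t0)

    # spatial baseline heterogeneity: a smooth field (~6% relative sd)
    # plus voxel-scale jitter (~2%), so in-ROI texture is non-degenerate
    # at any timepoint and for arbitrarily small ROIs
    from scipy.ndimage import gaussian_filter
    field = gaussian_filter(rng.standard_normal((Z, H, W)), sigma=1.5)
    field = 0.5 * (field + field[:, :, ::-1])  # bilateral (mirror) symmetry
    sd = field.std()
    field = field / sd if sd > 0 else field
    baseline_v = bolus.baseline * (
        1 + 0.06 * field.reshape(-1)[flat_brain] + 0.02 * rng.standard_normal(nb)
    )

    a, b = bolus.shape_alpha, bolus.scale_beta
    dt = t[None, :] - t0[:, None]                      # (nb, T)
    C = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / (a * b)
    C[pos] = np.power(x, a) * np.exp(a - dt[pos] / b)
    C *= amp[:, None]
    signals = baseline_v[:, None] * np.exp(-bolus.contrast_k * C)  # (nb, T)

    background = 0.02 * bolus.baseline
    vol = np.full((T, Z * H * W), background, dtype=float)
    vol[:, flat_brain] = signals.T
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, vol.shape)
    vol = np.maximum(vol, 1e-3)  # keep intensities positive
    vol = vol.reshape(T, Z, H, W)

    return Phantom4D(
        volume=vol, brain_mask=brain, ha_mask=ha, na_mask=na,
        achieved_fraction=float(achieved), noise_sd=float(noise_sd),
        seed=int(seed), acq=acq,
    )


def generate_cohort(
    n_subjects: int,
    acq: AcquisitionSpec = AcquisitionSpec(),
    bolus: BolusModel = BolusModel(),
    lesion_distribution=None,
    seed: int = 0,
    noise_sd: float = 2.0,
    attenuation: float = 0.4,
    delay: float = 2.0,
) -> list[Phantom4D]:
    """Generate ``n_subjects`` phantoms with reproducible per-subject seeds.

    ``lesion_distribution(rng) -> (fraction, hemisphere)`` draws the lesion
    volume fraction and side per subject; the default draws fractions
    uniformly on [0.02, 0.5] and sides with equal probability — a stand-in
    for real lesion-volume statistics, not a claim of equivalence.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if lesion_distribution is None:
        def lesion_distribution(rng):
            return rng.uniform(0.02, 0.5), ("left", "right")[int(rng.integers(2))]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    phantoms = []
    for i, child in enumerate(children):
        frac, side = lesion_distribution(draw_rng)
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        les = LesionSpec(
            hemisphere=side, target_fraction=float(frac),
            attenuation=attenuation, delay=delay, geometry_seed=sub_seed,
        )
        phantoms.append(
            generate_phantom(acq, bolus, les, noise_sd=noise_sd, seed=sub_seed)
        )
    return phantoms


def _nifti_affine(acq: AcquisitionSpec) -> np.ndarray:
    aff = np.eye(4)
    sz, sy, sx = acq.voxel_spacing
    aff[0, 0], aff[1, 1], aff[2, 2] = sx, sy, sz
    return aff


def save_phantom(phantom: Phantom4D, out_dir: str | Path, stem: str = "subject") -> dict:
    """Write volume + masks as NIfTI-1 and return a manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _nifti_affine(phantom.acq) if phantom.acq else np.eye(4)
    # NIfTI stores (x, y, z, t); our arrays are (t, z, y, x)
    vol_xyzt = np.transpose(phantom.volume, (3, 2, 1, 0))
    paths = {}
    for name, arr in (
        ("volume", vol_xyzt),
        ("brain_mask", np.transpose(phantom.brain_mask, (2, 1, 0)).astype(np.uint8)),
        ("ha_mask", np.transpose(phantom.ha_mask, (2, 1, 0)).astype(np.uint8)),
        ("na_mask", np.transpose(phantom.na_mask, (2, 1, 0)).astype(np.uint8)),
    ):
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, aff), p)
        paths[name] = str(p)
    return {
        "paths": paths,
        "seed": phantom.seed,
        "achieved_fraction": phantom.achieved_fraction,
        "noise_sd": phantom.noise_sd,
    }


def load_phantom(manifest_entry: dict) -> Phantom4D:
    """Inverse of :func:`save_phantom` (acq geometry is not round-tripped)."""
    paths = manifest_entry["paths"]
    vol = np.asarray(nib.load(paths["volume"]).dataobj)
    vol = np.transpose(vol, (3, 2, 1, 0))
    masks = {}
    for name in ("brain_mask", "ha_mask", "na_mask"):
        m = np.asarray(nib.load(paths[name]).dataobj)
        masks[name] = np.transpose(m, (2, 1, 0)).astype(bool)
    return Phantom4D(
        volume=vol, achieved_fraction=manifest_entry["achieved_fraction"],
        noise_sd=manifest_entry["noise_sd"], seed=manifest_entry["seed"],
        **masks,
    )


def save_cohort(phantoms: list[Phantom4D], out_dir: str | Path) -> Path:
    """Write a cohort and its JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    entries = [
        save_phantom(p, out_dir, stem=f"subject{i:03d}")
        for i, p in enumerate(phantoms)
    ]
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"subjects": entries}, indent=2))
    return manifest
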