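"""Lesion-proportion classification: the (S, RT) sweep.

Each phantom contributes two hemisphere samples (160 from an 80-subject
cohort).  For a slab of the middle S slices, a hemisphere is labeled
positive when its lesion fraction — hypoperfusion voxels over brain
voxels within the hemisphere slab — strictly exceeds a sliding reference
threshold RT.  For every (S, RT) cell the top-6 features are recomputed
on the slab mask, re-selected with Lasso (F'_RT_S), and scored with the
ten-model cross-validation harness.  The default grid, S in {3, 4, 5} by
RT in {0.00, 0.01, ..., 0.39}, has 120 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from perfrad.evaluate import crossval_metrics
from perfrad.features.extract import ExtractionConfig, extract_named_features
from perfrad.phantom import Phantom4D
from perfrad.preprocess import normalize_features, split_hemispheres
from perfrad.selection import SelectorConfig, FeatureSet, select_features

__all__ = [
    "DEFAULT_RT_GRID", "RTConfig", "HemisphereSample",
    "middle_slab", "proportion_label", "hemisphere_samples",
    "slab_feature_table", "sweep",
]

DEFAULT_RT_GRID = tuple(round(0.01 * i, 2) for i in range(40))


@dataclass
class HemisphereSample:
    """One hemisphere of one subject: volume plus hemisphere-limited masks."""

    sample_id: str
    volume: np.ndarray        # (t, z, y, x) full volume
    brain_mask: np.ndarray    # hemisphere-restricted brain mask
    ha_mask: np.ndarray       # lesion voxels within this hemisphere


@dataclass
class RTConfig:
    """One cell of the (S, RT) sweep."""

    S: int
    RT: float
    labels: pd.Series
    selected: FeatureSet | None = None       # F'_RT_S
    metrics: pd.DataFrame | None = None      # model x metric fold means
    cs: float | None = None
    degenerate: bool = False

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def middle_slab(mask_or_volume: np.ndarray, S: int) -> np.ndarray:
    """The middle S slices along z: [floor((Z-S)/2), floor((Z-S)/2)+S)."""
    arr = np.asarray(mask_or_volume)
    z_axis = arr.ndim - 3  # (z, y, x) -> 0; (t, z, y, x) -> 1
    Z = arr.shape[z_axis]
    if S > Z:
        raise ValueError(f"slab of {S} slices exceeds {Z} available")
    lo = (Z - S) // 2
    sl = [slice(None)] * arr.ndim
    sl[z_axis] = slice(lo, lo + S)
    return arr[tuple(sl)]


def proportion_label(ha_slab: np.ndarray, brain_slab: np.ndarray, RT: float) -> int:
    """1 iff the slab lesion fraction strictly exceeds RT."""
    brain_n = int(np.asarray(brain_slab).astype(bool).sum())
    if brain_n == 0:
        raise ValueError("empty brain slab")
    frac = int((np.asarray(ha_slab).astype(bool) & np.asarray(brain_slab).astype(bool)).sum()) / brain_n
    return int(frac > RT)


def hemisphere_samples(cohort: list[Phantom4D]) -> list[HemisphereSample]:
    """Split every phantom into its two hemisphere samples (2 per subject)."""
    out = []
    for i, ph in enumerate(cohort):
        (vol_l, left), (vol_r, right) = split_hemispheres(ph.volume, ph.brain_mask)
        for side, hemi_mask, vol in (("L", left, vol_l), ("R", right, vol_r)):
            out.append(
                HemisphereSample(
                    sample_id=f"s{i:03d}{side}",
                    volume=vol,
                    brain_mask=hemi_mask,
                    ha_mask=ph.ha_mask & hemi_mask,
                )
            )
    return out


def slab_feature_table(
    samples: list[HemisphereSample],
    feature_names: list[str],
    S: int,
    cfg: ExtractionConfig,
) -> pd.DataFrame:
    """Recompute the named features on each sample's middle-S slab mask."""
    rows = {}
    for s in samples:
        slab_vol = middle_slab(s.volume, S)
        slab_mask = middle_slab(s.brain_mask, S)
        rows[s.sample_id] = extract_named_features(
            slab_vol, slab_mask, feature_names, cfg
        )
    return pd.DataFrame(rows).T.reindex([s.sample_id for s in samples])


def _slab_labels(samples: list[HemisphereSample], S: int, RT: float) -> pd.Series:
    vals = {
        s.sample_id: proportion_label(
            middle_slab(s.ha_mask, S), middle_slab(s.brain_mask, S), RT
        )
        for s in samples
    }
    return pd.Series(vals, name="label")


def sweep(
    cohort: list[Phantom4D] | list[HemisphereSample],
    top6_features: list[str],
    S_values: tuple[int, ...] = (3, 4, 5),
    RT_grid: tuple[float, ...] = DEFAULT_RT_GRID,
    extraction_cfg: ExtractionConfig = ExtractionConfig(),
    selector_cfg: SelectorConfig = SelectorConfig(),
    seed: int = 0,
    evaluate: bool = True,
    n_splits: int = 10,
) -> list[RTConfig]:
    """Run the full (S, RT) grid.

    For each S the top-6 features are recomputed once on the slab; per RT
    the labels are rebuilt, Lasso re-selects F'_RT_S, and (when
    ``evaluate`` is set) the ten-model CV metrics and CS are stored.  The
    composite score uses the slab-level top-6 union as the coefficient
    set, mirroring the family-union role in the HA/NA stage.  Cells whose
    labels are single-class are flagged degenerate and carry no metrics.
    """
    if not top6_features:
        raise ValueError("top6 feature union is empty")
    if cohort and isinstance(cohort[0], Phantom4D):
        samples = hemisphere_samples(cohort)  # type: ignore[arg-type]
    else:
        samples = list(cohort)  # type: ignore[assignment]

    configs: list[RTConfig] = []
    for S in S_values:
        table = slab_feature_table(samples, top6_features, S, extraction_cfg)
        norm = normalize_features(table)
        for RT in RT_grid:
            labels = _slab_labels(samples, S, RT)
            cell = RTConfig(S=S, RT=float(RT), labels=labels)
            n_pos = int(labels.sum())
            if n_pos == 0 or n_pos == len(labels):
                cell.degenerate = True
                configs.append(cell)
                continue
            if evaluate:
                try:
                    fset = select_features(
                        "Lasso", norm, labels, selector_cfg, with_attributes=False
                    )
                    if not fset.members:
                        cell.degenerate = True
                        configs.append(cell)
                        continue
                    cell.selected = fset
                    cell.metrics = crossval_metrics(
                        fset, norm, labels, seed=seed, n_splits=n_splits
                    )
                    h = crossval_metrics(
                        list(norm.columns), norm, labels, seed=seed,
                        n_splits=n_splits,
                    ).to_numpy().mean()
                    cell.cs = float(h * cell.metrics.to_numpy().mean())
                except ValueError:
                    cell.degenerate = True
            configs.append(cell)
    return configs
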