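"""Per-feature two-sample T-tests and per-group p-value statistics.

After mean-centered range normalization, every feature column is tested
for a difference between hypoperfusion (label 1) and normal (label 0)
ROIs with an independent two-sample t-test; features with p < alpha are
retained.  No multiple-testing correction is applied — the retained set
feeds a second, multivariate selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from perfrad.features.naming import group_of, GROUPS

__all__ = ["SignificanceReport", "ttest_filter", "group_pvalue_stats"]


@dataclass
class SignificanceReport:
    p_values: pd.Series        # per feature
    retained: pd.Series        # boolean, p < alpha
    alpha: float

    @property
    def retained_names(self) -> list[str]:
        return self.retained.index[self.retained].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p_value": self.p_values, "retained": self.retained}
        )


def ttest_filter(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> SignificanceReport:
    """Independent two-sample t-test per column; retain p < alpha.

    ``equal_var=True`` gives the classical Student test; set False for
    Welch.  Expects a table already normalized column-wise (the test is
    invariant under per-column affine maps, so this is a convention, not
    a requirement).
    """
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    X = table.to_numpy(dtype=float)
    _, p = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=equal_var)
    p = pd.Series(p, index=table.columns, name="p_value")
    retained = p < alpha
    return SignificanceReport(p_values=p, retained=retained, alpha=alpha)


def group_pvalue_stats(
    report: SignificanceReport, grouping=group_of
) -> pd.DataFrame:
    """Count/mean/std/min/median/max of p among retained features, per group.

    Groups with no retained feature get count 0 and NaN statistics.
    """
    rows = {}
    p_ret = report.p_values[report.retained]
    groups = pd.Series(
        [grouping(n) for n in p_ret.index], index=p_ret.index, dtype=object
    )
    for g in GROUPS:
        p = p_ret[groups == g]
        if len(p):
            rows[g] = {
                "count": len(p), "mean": p.mean(), "std": p.std(ddof=1),
                "min": p.min(), "median": p.median(), "max": p.max(),
            }
        else:
            rows[g] = {
                "count": 0, "mean": np.nan, "std": np.nan,
                "min": np.nan, "median": np.nan, "max": np.nan,
            }
    out = pd.DataFrame(rows).T
    out["count"] = out["count"].astype(int)
    return out
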