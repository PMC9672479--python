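"""A 13-method feature-selection bank with shared thresholding rules.

Four method families are covered:

* information-theoretic (FI): MIM, MIFS, MRMR, JMI, CMIM — plug-in mutual
  information on equal-frequency discretized features, the multivariate
  methods ranked by greedy forward selection;
* similarity (SIF): Fisher score, Laplacian score (negated so higher is
  better), ReliefF;
* statistical (STF): F-score (FS) and t-score (TS);
* sparse learning / streaming (SSL): MCFS (spectral embedding + L1
  regression), Alpha-investing, Lasso (cross-validated).

Every method produces one finite score per feature; ``apply_threshold``
turns scores into a bounded FeatureSet: Lasso keeps coefficients with
|beta| > 0.02, every other method keeps min-max normalized scores > 0.9,
and all sets are capped at 20 members.  Ties break lexicographically by
feature name so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, lars_path
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS", "TYPE_PARTITION", "SelectorConfig", "FeatureSet",
    "mutual_information", "score_features", "apply_threshold",
    "select_features", "feature_attributes", "union_sets",
]

METHODS = (
    "CMIM", "JMI", "MIFS", "MIM", "MRMR",
    "Fisher", "Lap", "ReliefF",
    "FS", "TS",
    "MCFS", "Alpha", "Lasso",
)

#: The four method families and their members.
TYPE_PARTITION = {
    "FI": ("CMIM", "JMI", "MIFS", "MIM", "MRMR"),
    "SIF": ("Fisher", "Lap", "ReliefF"),
    "STF": ("FS", "TS"),
    "SSL": ("MCFS", "Alpha", "Lasso"),
}

METHOD_TYPE = {m: t for t, ms in TYPE_PARTITION.items() for m in ms}


@dataclass(frozen=True)
class SelectorConfig:
    max_features: int = 20
    score_threshold: float = 0.9       # on min-max normalized scores
    lasso_coef_threshold: float = 0.02
    mi_bins: int = 5                   # equal-frequency MI discretization
    mifs_beta: float = 0.5
    knn_k: int = 5                     # Laplacian-score graph
    relieff_k: int = 10
    mcfs_knn_k: int = 10               # MCFS spectral graph
    # non-trivial spectral embedding dims; K-cluster data needs K-1, and
    # this package's target is binary
    mcfs_eigvecs: int = 1
    alpha_wealth: float = 0.5          # initial alpha-investing wealth
    alpha_delta: float = 0.5           # wealth payout on selection
    lasso_cv_folds: int = 5
    rank_depth: int | None = None      # greedy ranking depth (None = all)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


@dataclass
class FeatureSet:
    """An ordered, named feature subset produced by one selection method."""

    method: str
    members: list[str]
    scores: pd.Series                       # aligned with members
    attributes: pd.DataFrame | None = None  # r_squared, p_value, gain, gain_ratio

    def __len__(self) -> int:
        return len(self.members)

    @property
    def type(self) -> str:
        return METHOD_TYPE.get(self.method, "union")


# --------------------------------------------------------------------------
# discretization and mutual information

def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Quantile-based equal-frequency binning to consecutive integer codes.

    Tie-aware: equal values always share a bin, so a binary feature yields
    exactly two codes; fully distinct values split into balanced bins.
    """
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    b = np.searchsorted(edges, x, side="right")
    _, codes = np.unique(b, return_inverse=True)
    return codes.astype(np.int64)


def _binned_matrix(table: pd.DataFrame, bins: int) -> np.ndarray:
    X = table.to_numpy(dtype=float)
    return np.stack(
        [equal_frequency_bins(X[:, j], bins) for j in range(X.shape[1])], axis=1
    )


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete sequences."""
    x = np.asarray(x).astype(np.int64)
    y = np.asarray(y).astype(np.int64)
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(
        np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz]))
    )


def _mi_columns(B: np.ndarray, v: np.ndarray, nv: int, bins: int) -> np.ndarray:
    """MI(column_j; v) for every column of binned matrix B, vectorized."""
    n, p = B.shape
    idx = B * nv + v[:, None]
    counts = np.zeros((p, bins * nv))
    np.add.at(counts, (np.broadcast_to(np.arange(p), (n, p)), idx), 1.0)
    joint = counts.reshape(p, bins, nv) / n
    px = joint.sum(axis=2)     # (p, bins)
    pv = joint.sum(axis=1)     # (p, nv)
    denom = px[:, :, None] * pv[:, None, :]
    nz = joint > 0
    out = np.zeros(p)
    ratio = np.ones_like(joint)
    ratio[nz] = joint[nz] / denom[nz]
    contrib = np.where(nz, joint * np.log2(np.where(nz, ratio, 1.0)), 0.0)
    return contrib.sum(axis=(1, 2))


def _cmi_columns(
    B: np.ndarray, y: np.ndarray, z: np.ndarray, bins: int, ny: int, nz_: int
) -> np.ndarray:
    """I(column_j; y | z) for every column of B, in bits."""
    n, p = B.shape
    idx = (B * ny + y[:, None]) * nz_ + z[:, None]
    counts = np.zeros((p, bins * ny * nz_))
    np.add.at(counts, (np.broadcast_to(np.arange(p), (n, p)), idx), 1.0)
    pxyz = counts.reshape(p, bins, ny, nz_) / n
    pxz = pxyz.sum(axis=2)            # (p, bins, nz)
    pyz = pxyz.sum(axis=1)            # (p, ny, nz)
    pz = pxyz.sum(axis=(1, 2))        # (p, nz)
    num = pxyz * pz[:, None, None, :]
    den = pxz[:, :, None, :] * pyz[:, None, :, :]
    nzm = (pxyz > 0) & (den > 0)
    contrib = np.zeros_like(pxyz)
    contrib[nzm] = pxyz[nzm] * np.log2(num[nzm] / den[nzm])
    return contrib.sum(axis=(1, 2, 3))


# --------------------------------------------------------------------------
# scorers

def _greedy_mi_ranking(
    method: str, B: np.ndarray, y: np.ndarray, cfg: SelectorConfig
) -> np.ndarray:
    """Forward-selection scores for MIFS/MRMR/JMI/CMIM.

    Selected features carry the objective value at selection time; when
    ranking stops early (``rank_depth``), the remaining candidates keep
    their current objective value.
    """
    n, p = B.shape
    bins = cfg.mi_bins
    rel = _mi_columns(B, y, 2, bins)  # I(f_i; C)
    scores = np.full(p, np.nan)
    selected = np.zeros(p, dtype=bool)
    depth = p if cfg.rank_depth is None else min(p, cfg.rank_depth)

    if method == "MIFS":
        acc = np.zeros(p)  # sum of I(fi; fs)
    elif method == "MRMR":
        acc = np.zeros(p)
    elif method == "JMI":
        acc = np.zeros(p)  # sum of I(fi; C | fs)
    elif method == "CMIM":
        acc = np.full(p, np.inf)  # running min of I(fi; C | fs)

    for step in range(depth):
        if method == "MIFS":
            obj = rel - cfg.mifs_beta * acc
        elif method == "MRMR":
            obj = rel - (acc / step if step else 0.0)
        elif method == "JMI":
            obj = (acc / step) if step else rel.copy()
        elif method == "CMIM":
            obj = np.where(np.isinf(acc), rel, np.minimum(rel, acc))
        obj = np.where(selected, -np.inf, obj)
        pick = int(np.argmax(obj))
        scores[pick] = obj[pick]
        selected[pick] = True
        if step == depth - 1:
            scores[~selected] = obj[~selected]
            break
        fs = B[:, pick]
        if method in ("MIFS", "MRMR"):
            acc += _mi_columns(B, fs, bins, bins)
        elif method == "JMI":
            acc += _cmi_columns(B, y, fs, bins, 2, bins)
        elif method == "CMIM":
            acc = np.minimum(acc, _cmi_columns(B, y, fs, bins, 2, bins))
    return scores


def _fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in (0, 1):
        Xc = X[y == c]
        num += len(Xc) * (Xc.mean(axis=0) - mu) ** 2
        den += len(Xc) * Xc.var(axis=0)
    den[den == 0] = np.finfo(float).tiny
    return num / den


def _knn_heat_graph(X: np.ndarray, k: int) -> np.ndarray:
    """Symmetric k-NN adjacency with heat-kernel weights."""
    n = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    t = d2[np.triu_indices(n, 1)].mean()
    t = t if t > 0 else 1.0
    W = np.zeros((n, n))
    order = np.argsort(d2, axis=1, kind="stable")
    for i in range(n):
        for j in order[i, 1 : k + 1]:
            w = np.exp(-d2[i, j] / t)
            W[i, j] = max(W[i, j], w)
            W[j, i] = W[i, j]
    return W


def _laplacian_scores(X: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    W = _knn_heat_graph(X, cfg.knn_k)
    d = W.sum(axis=1)
    D = np.diag(d)
    L = D - W
    one = np.ones(len(X))
    denom_d = d.sum()
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ d) / denom_d * one
        var = f_t @ (d * f_t)
        scores[j] = (f_t @ L @ f_t) / var if var > 0 else np.inf
    return -scores  # lower raw Laplacian score = better


def _relieff_scores(X: np.ndarray, y: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    n, p = X.shape
    rng_f = X.max(axis=0) - X.min(axis=0)
    rng_f[rng_f == 0] = 1.0
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    W = np.zeros(p)
    k = cfg.relieff_k
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        diff = np.flatnonzero(y != y[i])
        hits = same[np.argsort(d2[i, same], kind="stable")[:k]]
        misses = diff[np.argsort(d2[i, diff], kind="stable")[:k]]
        if len(hits) == 0 or len(misses) == 0:
            continue
        W -= np.abs(X[hits] - X[i]).sum(axis=0) / (rng_f * len(hits) * n)
        W += np.abs(X[misses] - X[i]).sum(axis=0) / (rng_f * len(misses) * n)
    return W


def _f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos, neg = X[y == 1], X[y == 0]
    mu, mp, mn = X.mean(axis=0), pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - mu) ** 2 + (mn - mu) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    den[den == 0] = np.finfo(float).tiny
    return num / den


def _t_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos, neg = X[y == 1], X[y == 0]
    se = np.sqrt(
        pos.var(axis=0, ddof=1) / len(pos) + neg.var(axis=0, ddof=1) / len(neg)
    )
    se[se == 0] = np.finfo(float).tiny
    return np.abs(pos.mean(axis=0) - neg.mean(axis=0)) / se


def _mcfs_scores(X: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    n, p = X.shape
    # standardize so L1 coefficient magnitudes are comparable across features
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    W = _knn_heat_graph(X, cfg.mcfs_knn_k)
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    Dm12 = 1.0 / np.sqrt(d)
    Lsym = np.eye(n) - (Dm12[:, None] * W * Dm12[None, :])
    vals, vecs = np.linalg.eigh(Lsym)
    # smallest non-trivial eigenvectors of the normalized Laplacian
    n_vec = min(cfg.mcfs_eigvecs, n - 1)
    Y = vecs[:, 1 : 1 + n_vec] * Dm12[:, None]
    scores = np.zeros(p)
    n_nonzero = min(cfg.max_features, p, n - 1)
    for kcol in range(Y.shape[1]):
        yk = Y[:, kcol]
        _, _, coefs = lars_path(X, yk, method="lasso", max_iter=8 * n_nonzero)
        nnz = (coefs != 0).sum(axis=0)
        valid = np.flatnonzero(nnz <= n_nonzero)
        col = valid[-1] if len(valid) else coefs.shape[1] - 1
        scores = np.maximum(scores, np.abs(coefs[:, col]))
    return scores


def _alpha_investing_scores(X: np.ndarray, y: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    """Streaming forward selection with an adaptive alpha budget.

    Features arrive in column order; each is admitted when the p-value of
    its incremental error reduction beats the current investment
    alpha_i = w_i / (2i); wealth pays out on admission.  Admitted
    features score 1 - p, others 0.
    """
    n, p = X.shape
    yf = y.astype(float)
    selected_cols: list[int] = []
    scores = np.zeros(p)
    wealth = cfg.alpha_wealth
    Xcur = np.ones((n, 1))
    resid = yf - Xcur @ np.linalg.lstsq(Xcur, yf, rcond=None)[0]
    sse = float(resid @ resid)
    for i in range(p):
        alpha_i = wealth / (2 * (i + 1))
        Xtry = np.column_stack([Xcur, X[:, i]])
        beta, *_ = np.linalg.lstsq(Xtry, yf, rcond=None)
        sse_new = float(np.sum((yf - Xtry @ beta) ** 2))
        df = n - Xtry.shape[1]
        if df <= 0 or sse_new <= 0:
            pval = 0.0
        else:
            fstat = (sse - sse_new) / (sse_new / df)
            pval = float(stats.f.sf(max(fstat, 0.0), 1, df))
        if pval < alpha_i:
            selected_cols.append(i)
            scores[i] = 1.0 - pval
            wealth += cfg.alpha_delta - alpha_i
            Xcur, sse = Xtry, sse_new
        else:
            wealth -= alpha_i / (1.0 - alpha_i)
            wealth = max(wealth, 0.0)
            if wealth == 0:
                break
    return scores


def _lasso_scores(X: np.ndarray, y: np.ndarray, cfg: SelectorConfig) -> np.ndarray:
    cv = KFold(n_splits=cfg.lasso_cv_folds, shuffle=True, random_state=cfg.seed)
    model = LassoCV(cv=cv, random_state=cfg.seed, max_iter=50_000)
    model.fit(X, y.astype(float))
    return np.abs(model.coef_)


def score_features(
    method: str,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    cfg: SelectorConfig = SelectorConfig(),
) -> pd.Series:
    """One finite score per feature for the given selection method."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    y = np.asarray(labels).astype(int)
    if not set(np.unique(y)) <= {0, 1} or len(np.unique(y)) != 2:
        raise ValueError("labels must be binary with both classes present")
    X = table.to_numpy(dtype=float)

    if method in ("MIM", "MIFS", "MRMR", "JMI", "CMIM"):
        B = _binned_matrix(table, cfg.mi_bins)
        if method == "MIM":
            scores = _mi_columns(B, y, 2, cfg.mi_bins)
        else:
            scores = _greedy_mi_ranking(method, B, y, cfg)
    elif method == "Fisher":
        scores = _fisher_scores(X, y)
    elif method == "Lap":
        scores = _laplacian_scores(X, cfg)
    elif method == "ReliefF":
        scores = _relieff_scores(X, y, cfg)
    elif method == "FS":
        scores = _f_scores(X, y)
    elif method == "TS":
        scores = _t_scores(X, y)
    elif method == "MCFS":
        scores = _mcfs_scores(X, cfg)
    elif method == "Alpha":
        scores = _alpha_investing_scores(X, y, cfg)
    elif method == "Lasso":
        scores = _lasso_scores(X, y, cfg)
    return pd.Series(np.asarray(scores, float), index=table.columns, name=method)


def apply_threshold(
    scores: pd.Series, cfg: SelectorConfig = SelectorConfig(), method: str = ""
) -> FeatureSet:
    """Turn raw scores into a bounded FeatureSet.

    Lasso keeps |beta| > ``lasso_coef_threshold``; every other method
    min-max normalizes scores to [0, 1] and keeps those >
    ``score_threshold``.  Both truncate to the ``max_features`` best,
    ties broken lexicographically by name.
    """
    if len(scores) == 0:
        raise ValueError("no candidate features")
    if method == "Lasso":
        eligible = scores[scores > cfg.lasso_coef_threshold]
        ranked = eligible
    else:
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            logger.warning("all %s scores equal; empty feature set", method or "?")
            return FeatureSet(method=method, members=[], scores=scores.iloc[:0])
        norm = (scores - lo) / (hi - lo)
        ranked = norm[norm > cfg.score_threshold]
    order = sorted(ranked.index, key=lambda n: (-ranked[n], n))
    members = order[: cfg.max_features]
    return FeatureSet(method=method, members=members, scores=scores.loc[members])


def feature_attributes(
    feature: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    bins: int = 5,
) -> dict[str, float]:
    """Label-association attributes of one feature.

    r_squared is the squared Pearson correlation with the label; p_value
    the two-sample t-test; gain the information gain H(C) - H(C|f) with
    the feature equal-frequency binned; gain_ratio divides by the binned
    feature's entropy H(f).
    """
    x = np.asarray(feature, float)
    y = np.asarray(labels).astype(int)
    if x.max() == x.min():
        raise ValueError("constant feature has no attributes")
    r, _ = stats.pearsonr(x, y)
    _, p = stats.ttest_ind(x[y == 1], x[y == 0])
    xb = equal_frequency_bins(x, bins)
    hy = _entropy(y)
    gain = mutual_information(xb, y)  # H(C) - H(C|f) == I(f; C)
    hx = _entropy(xb)
    return {
        "r_squared": float(r**2),
        "p_value": float(p),
        "gain": float(gain),
        "gain_ratio": float(gain / hx) if hx > 0 else 0.0,
        "_h_label": float(hy),
    }


def _entropy(v: np.ndarray) -> float:
    p = np.bincount(v) / len(v)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def select_features(
    method: str,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    cfg: SelectorConfig = SelectorConfig(),
    with_attributes: bool = True,
) -> FeatureSet:
    """Score, threshold, and annotate one method's feature set."""
    scores = score_features(method, table, labels, cfg)
    fset = apply_threshold(scores, cfg, method=method)
    if with_attributes and fset.members:
        rows = {
            name: {
                k: v
                for k, v in feature_attributes(table[name], labels).items()
                if not k.startswith("_")
            }
            for name in fset.members
        }
        fset.attributes = pd.DataFrame(rows).T.loc[fset.members]
    return fset


def union_sets(sets: list[FeatureSet], name: str = "union") -> FeatureSet:
    """Duplicate-free union preserving first-seen order."""
    if not sets:
        raise ValueError("need at least one input set")
    members: list[str] = []
    seen = set()
    scores = {}
    for s in sets:
        for m in s.members:
            if m not in seen:
                seen.add(m)
                members.append(m)
                scores[m] = float(s.scores[m])
    return FeatureSet(
        method=name, members=members,
        scores=pd.Series(scores).reindex(members),
    )
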