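"""Ten-model cross-validation harness and composite scoring.

Each feature set is evaluated with stratified tenfold cross-validation
on ten standard classifiers; five metrics (Acc, Pre, Auc, F1, Recall)
are averaged over folds.  A family coefficient H_type is the grand mean
of all 5 x 10 metric cells for the family's union set, and the composite
score of a feature set is

    CS(F_method) = H_type * (1 / (K*M)) * sum_{k,m} index(k, model(m, F_method))

with K = 5 metrics and M = 10 models, so CS is in [0, 1] and never
exceeds the set's own mean-metric term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from perfrad.selection import FeatureSet, METHOD_TYPE

__all__ = [
    "MODEL_IDS", "METRIC_IDS", "make_models", "crossval_metrics",
    "evaluate_grid", "h_type", "composite_score", "rank_top_k",
]

MODEL_IDS = ("SVM", "DT", "Ada", "NN", "RF", "KNN", "LR", "DA", "GBDT", "NB")
METRIC_IDS = ("Acc", "Pre", "Auc", "F1", "Recall")


def make_models(seed: int = 0) -> dict[str, object]:
    """The ten classifiers with their fixed hyperparameters."""
    return {
        "SVM": SVC(kernel="rbf", probability=True, random_state=seed),
        "DT": DecisionTreeClassifier(random_state=seed),
        "Ada": AdaBoostClassifier(random_state=seed),
        "NN": MLPClassifier(
            hidden_layer_sizes=(400, 100), alpha=0.01, max_iter=10_000,
            random_state=seed,
        ),
        "RF": RandomForestClassifier(n_estimators=200, random_state=seed),
        "KNN": KNeighborsClassifier(),
        "LR": LogisticRegressionCV(max_iter=100_000, solver="liblinear"),
        "DA": LinearDiscriminantAnalysis(),
        "GBDT": GradientBoostingClassifier(random_state=seed),
        "NB": GaussianNB(),
    }


def _fold_scores(model, Xtr, ytr, Xte, yte) -> dict[str, float]:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(Xte)[:, 1]
    else:  # pragma: no cover - all ten models expose probabilities
        score = model.decision_function(Xte)
    auc = 0.5 if len(np.unique(yte)) < 2 else roc_auc_score(yte, score)
    return {
        "Acc": accuracy_score(yte, pred),
        "Pre": precision_score(yte, pred, zero_division=0),
        "Auc": auc,
        "F1": f1_score(yte, pred, zero_division=0),
        "Recall": recall_score(yte, pred, zero_division=0),
    }


def crossval_metrics(
    feature_set: FeatureSet | list[str],
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    models: dict[str, object] | None = None,
    seed: int = 0,
    n_splits: int = 10,
) -> pd.DataFrame:
    """Stratified k-fold metric means per model for one feature set.

    Returns a (model x metric) DataFrame of fold means; positive class is
    the hypoperfusion label 1; undefined precision/recall score 0.
    """
    members = feature_set.members if isinstance(feature_set, FeatureSet) else list(feature_set)
    if not members:
        raise ValueError("empty feature set")
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_splits:
        raise ValueError(
            f"need >= {n_splits} samples per class for {n_splits}-fold "
            f"stratified CV, got {counts.tolist()}"
        )
    X = table[members].to_numpy(dtype=float)
    if models is None:
        models = make_models(seed)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    out = {}
    for mid, model in models.items():
        per_fold = [
            _fold_scores(model, X[tr], y[tr], X[te], y[te]) for tr, te in folds
        ]
        out[mid] = {k: float(np.mean([f[k] for f in per_fold])) for k in METRIC_IDS}
    return pd.DataFrame(out).T.loc[list(models)][list(METRIC_IDS)]


def evaluate_grid(
    sets: dict[str, FeatureSet],
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    n_splits: int = 10,
) -> dict[str, pd.DataFrame]:
    """Evaluate many feature sets; returns {set_name: model x metric block}."""
    return {
        name: crossval_metrics(fs, table, labels, seed=seed, n_splits=n_splits)
        for name, fs in sets.items()
        if len(fs)
    }


def h_type(grid: dict[str, pd.DataFrame], type_name: str) -> float:
    """Family coefficient: grand mean of the family union set's 50 cells."""
    key = f"F_{type_name}"
    if key not in grid:
        raise KeyError(f"grid is missing the union block {key!r}")
    block = grid[key]
    if block.isna().any().any() or block.shape != (len(MODEL_IDS), len(METRIC_IDS)):
        raise ValueError(f"incomplete metric block for {key}")
    return float(block.to_numpy().mean())


def composite_score(
    grid: dict[str, pd.DataFrame], method: str, h: float | None = None
) -> float:
    """CS = H_type * grand mean of the method's own 50 metric cells."""
    if method not in grid:
        raise KeyError(f"no metric block for {method!r}")
    if h is None:
        t = METHOD_TYPE.get(method)
        if t is None:
            raise ValueError(f"no family mapping for method {method!r}")
        h = h_type(grid, t)
    return float(h * grid[method].to_numpy().mean())


def rank_top_k(cs_values: dict[str, float], k: int = 6) -> list[str]:
    """Top-k methods by descending CS, ties lexicographic."""
    if k > len(cs_values):
        raise ValueError(f"k={k} exceeds {len(cs_values)} scored methods")
    return sorted(cs_values, key=lambda m: (-cs_values[m], m))[:k]
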