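"""The 13-method selection bank: oracles, thresholds, attributes, unions."""

import math

import numpy as np
import pandas as pd
import pytest

from perfrad.preprocess import normalize_features
from perfrad.selection import (
    METHODS, TYPE_PARTITION, SelectorConfig, FeatureSet,
    mutual_information, equal_frequency_bins, score_features,
    apply_threshold, select_features, feature_attributes, union_sets,
)


def _oracle_mi(counts: dict) -> float:
    """Hand plug-in MI summation over a joint count table."""
    n = sum(counts.values())
    px, py = {}, {}
    for (a, b), c in counts.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    mi = 0.0
    for (a, b), c in counts.items():
        p = c / n
        mi += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return mi


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        y = np.repeat([0, 1], 30)
        assert mutual_information(y, y) == pytest.approx(1.0, abs=1e-12)

    def test_contingency_table_matches_hand_summation(self):
        counts = {(0, 0): 30, (0, 1): 10, (1, 0): 10, (1, 1): 30}
        x = np.concatenate([np.zeros(40, int), np.ones(40, int)])
        y = np.concatenate(
            [np.zeros(30, int), np.ones(10, int), np.zeros(10, int), np.ones(30, int)]
        )
        assert mutual_information(x, y) == pytest.approx(
            _oracle_mi(counts), abs=1e-12
        )

    def test_independent_vanishes_with_n(self):
        rng = np.random.default_rng(0)
        small = mutual_information(
            rng.integers(0, 5, 50), rng.integers(0, 2, 50)
        )
        large = mutual_information(
            rng.integers(0, 5, 50_000), rng.integers(0, 2, 50_000)
        )
        assert small >= 0 and large >= 0
        assert large < small

    def test_equal_frequency_bins_are_balanced(self):
        x = np.random.default_rng(1).standard_normal(100)
        b = equal_frequency_bins(x, 5)
        assert np.bincount(b).tolist() == [20] * 5


def _perfect_table(n=60, seed=0):
    """A perfect predictor among weaker class-informative companions.

    The companions carry the same class structure (so even unsupervised
    graph-based scorers see clusters aligned with the label) but with
    within-class spread, leaving the noise-free copy of the label
    strictly dominant."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    data = {"target": y.astype(float)}
    for j in range(5):
        data[f"f{j}"] = y + 0.6 * rng.standard_normal(n)
    return pd.DataFrame(data), pd.Series(y)


class TestScorers:
    @pytest.mark.parametrize("method", METHODS)
    def test_perfect_predictor_ranked_first(self, method):
        table, y = _perfect_table()
        cfg = SelectorConfig(seed=0)
        scores = score_features(method, table, y, cfg)
        best = max(scores.index, key=lambda n: (scores[n], n))
        assert best == "target", f"{method} ranked {best} first"

    def test_mrmr_demotes_duplicate_feature(self):
        # f1 = near-perfect predictor, f2 = exact copy of f1, f3 =
        # independent informative feature.  (With f1 literally equal to
        # the label, I(f3;C) == I(f3;f1) identically, so the redundancy
        # penalty ties; a sliver of noise on f1 keeps the toy strict.)
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1], n // 2)
        f1 = y + 0.05 * rng.standard_normal(n)
        f3 = y + rng.standard_normal(n) * 0.8
        table = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": f3})
        cfg = SelectorConfig(seed=0)
        scores = score_features("MRMR", table, y, cfg)
        assert scores["f3"] > scores["f2"]
        # brute force: f1 picked first; f3 beats the duplicate at step 2,
        # so its score is I(f3;C) - I(f3;f1); the duplicate comes last
        # with mean redundancy over {f1, f3}
        B = {
            c: equal_frequency_bins(table[c].to_numpy(), cfg.mi_bins)
            for c in table
        }
        exp_f3 = mutual_information(B["f3"], y) - mutual_information(
            B["f3"], B["f1"]
        )
        exp_f2 = mutual_information(B["f2"], y) - 0.5 * (
            mutual_information(B["f2"], B["f1"])
            + mutual_information(B["f2"], B["f3"])
        )
        assert scores["f3"] == pytest.approx(exp_f3, abs=1e-10)
        assert scores["f2"] == pytest.approx(exp_f2, abs=1e-10)

    def test_fisher_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        f = y + rng.standard_normal(60)
        table = pd.DataFrame({"f": f, "g": 3.7 * f + 11.0})
        scores = score_features("Fisher", table, y)
        assert abs(scores["f"] - scores["g"]) < 1e-10

    @pytest.mark.parametrize("method", ["ReliefF", "MCFS", "Lasso"])
    def test_seeded_determinism(self, method, toy_table):
        table, y = toy_table
        norm = normalize_features(table)
        cfg = SelectorConfig(seed=11)
        a = select_features(method, norm, y, cfg, with_attributes=False)
        b = select_features(method, norm, y, cfg, with_attributes=False)
        assert a.members == b.members
        assert (a.scores.to_numpy() == b.scores.to_numpy()).all()

    def test_unknown_method_rejected(self):
        table, y = _perfect_table()
        with pytest.raises(ValueError):
            score_features("PCA", table, y)

    def test_nonbinary_labels_rejected(self):
        table, _ = _perfect_table()
        with pytest.raises(ValueError):
            score_features("MIM", table, np.arange(60))


class TestGreedyOracleEquivalence:
    """Brute-force evaluation of each information-theoretic objective on a
    small instance, replayed step by step against the greedy ranking."""

    @pytest.fixture(scope="class")
    def instance(self):
        rng = np.random.default_rng(7)
        n, p = 40, 8
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, p))
        X[:, 0] += 1.5 * y
        X[:, 1] += 1.0 * y
        X[:, 2] += X[:, 0] * 0.8
        table = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
        return table, y

    def _cmi(self, x, y, z, nx, ny, nz):
        cmi = 0.0
        n = len(x)
        for zv in range(nz):
            m = z == zv
            if not m.any():
                continue
            pz = m.mean()
            cmi += pz * mutual_information(x[m], y[m]) if len(set(x[m])) else 0.0
        return cmi

    @pytest.mark.parametrize("method", ["MIM", "MIFS", "MRMR", "JMI", "CMIM"])
    def test_scores_match_bruteforce_objective(self, instance, method):
        table, y = instance
        cfg = SelectorConfig(seed=0)
        bins = cfg.mi_bins
        B = {c: equal_frequency_bins(table[c].to_numpy(), bins) for c in table}
        rel = {c: mutual_information(B[c], y) for c in table}
        got = score_features(method, table, y, cfg)

        if method == "MIM":
            for c in table:
                assert got[c] == pytest.approx(rel[c], abs=1e-10)
            return

        # replay the greedy: at each step evaluate the printed objective
        # for every remaining candidate by brute force
        remaining = list(table.columns)
        selected: list[str] = []
        expected = {}
        while remaining:
            objs = {}
            for c in remaining:
                if method == "MIFS":
                    red = sum(mutual_information(B[c], B[s]) for s in selected)
                    objs[c] = rel[c] - cfg.mifs_beta * red
                elif method == "MRMR":
                    red = (
                        sum(mutual_information(B[c], B[s]) for s in selected)
                        / len(selected) if selected else 0.0
                    )
                    objs[c] = rel[c] - red
                elif method == "JMI":
                    if not selected:
                        objs[c] = rel[c]
                    else:
                        objs[c] = sum(
                            self._cmi(B[c], y, B[s], bins, 2, bins)
                            for s in selected
                        ) / len(selected)
                elif method == "CMIM":
                    if not selected:
                        objs[c] = rel[c]
                    else:
                        objs[c] = min(
                            min(
                                self._cmi(B[c], y, B[s], bins, 2, bins)
                                for s in selected
                            ),
                            rel[c],
                        )
            pick = max(remaining, key=lambda c: (objs[c], c))
            expected[pick] = objs[pick]
            selected.append(pick)
            remaining.remove(pick)
        for c in table:
            assert got[c] == pytest.approx(expected[c], abs=1e-10), (method, c)


class TestThreshold:
    def test_normalized_cutoff(self):
        scores = pd.Series({"a": 1.0, "b": 0.95, "c": 0.89, "d": 0.0})
        fset = apply_threshold(scores, SelectorConfig(), method="Fisher")
        assert fset.members == ["a", "b"]

    def test_cap_with_lexicographic_ties(self):
        scores = pd.Series({f"f{i:02d}": 1.0 for i in range(30)})
        scores["z_low"] = 0.0  # anchor so normalization is defined
        fset = apply_threshold(scores, SelectorConfig(), method="MIM")
        assert len(fset) == 20
        assert fset.members == sorted(f"f{i:02d}" for i in range(30))[:20]

    def test_lasso_strict_coefficient_rule(self):
        scores = pd.Series({"a": 0.5, "b": 0.021, "c": 0.02, "d": 0.019})
        fset = apply_threshold(scores, SelectorConfig(), method="Lasso")
        assert fset.members == ["a", "b"]

    def test_all_equal_scores_warn_empty(self, caplog):
        scores = pd.Series({"a": 1.0, "b": 1.0})
        with caplog.at_level("WARNING"):
            fset = apply_threshold(scores, SelectorConfig(), method="TS")
        assert len(fset) == 0


class TestAttributes:
    def test_perfect_feature(self):
        y = np.repeat([0, 1], 20)
        att = feature_attributes(y.astype(float), y)
        assert att["r_squared"] == pytest.approx(1.0)
        assert att["gain"] == pytest.approx(1.0)  # H(C) of balanced labels

    def test_toy_table_against_direct_formulas(self):
        # 8 samples, hand-checkable
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        att = feature_attributes(x, y, bins=2)
        r = np.corrcoef(x, y)[0, 1]
        assert att["r_squared"] == pytest.approx(r**2, abs=1e-12)
        # binned at the median, x predicts y exactly: gain = H(C) = 1 bit
        assert att["gain"] == pytest.approx(1.0, abs=1e-12)
        assert att["gain_ratio"] == pytest.approx(1.0, abs=1e-12)  # H(f)=1
        from scipy import stats
        _, p = stats.ttest_ind(x[y == 1], x[y == 0])
        assert att["p_value"] == pytest.approx(p, abs=1e-12)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            feature_attributes(np.ones(10), np.repeat([0, 1], 5))


class TestUnions:
    def test_partition_covers_all_13_once(self):
        members = [m for ms in TYPE_PARTITION.values() for m in ms]
        assert sorted(members) == sorted(METHODS)
        assert len(members) == 13

    def test_disjoint_and_identical_unions(self):
        s1 = FeatureSet("A", ["a", "b"], pd.Series({"a": 1.0, "b": 0.9}))
        s2 = FeatureSet("B", ["c", "d", "e"], pd.Series({"c": 1.0, "d": 0.5, "e": 0.4}))
        assert union_sets([s1, s2]).members == ["a", "b", "c", "d", "e"]
        assert union_sets([s1, s1]).members == s1.members

    def test_first_seen_order_preserved(self):
        s1 = FeatureSet("A", ["b", "a"], pd.Series({"b": 1.0, "a": 0.9}))
        s2 = FeatureSet("B", ["a", "c"], pd.Series({"a": 1.0, "c": 0.5}))
        assert union_sets([s1, s2]).members == ["b", "a", "c"]


# planted-feature recovery across seeds for all 13 methods is asserted
# in tests/test_acceptance.py (TestCalibrationAndRecovery)
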