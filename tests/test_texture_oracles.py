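"""Texture matrices vs independent naive-loop oracles on tiny volumes.

Each oracle below rebuilds the gray-level matrix with explicit Python
loops (no shared code with the vectorized implementation) and recomputes
a handful of representative statistics from it.
"""

import numpy as np
import pytest

from perfrad.features import bank


@pytest.fixture(scope="module")
def tiny():
    """A 4x5x5 labeled volume with 3 gray levels and an irregular mask."""
    rng = np.random.default_rng(12)
    lab = rng.integers(1, 4, size=(4, 5, 5)).astype(np.int32)
    mask = rng.random((4, 5, 5)) > 0.25
    lab[~mask] = 0
    return lab, 3


def _inb(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def _oracle_glcm(lab, Ng):
    P = np.zeros((Ng, Ng))
    for d in bank.DIRECTIONS_13:
        for z in range(lab.shape[0]):
            for y in range(lab.shape[1]):
                for x in range(lab.shape[2]):
                    a = lab[z, y, x]
                    q = (z + d[0], y + d[1], x + d[2])
                    if a > 0 and _inb(lab.shape, q):
                        b = lab[q]
                        if b > 0:
                            P[a - 1, b - 1] += 1
                            P[b - 1, a - 1] += 1
    return P / P.sum()


def _oracle_runs(lab, Ng):
    P = {}
    shape = lab.shape
    for d in bank.DIRECTIONS_13:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    v = lab[z, y, x]
                    prev = (z - d[0], y - d[1], x - d[2])
                    if v == 0 or (_inb(shape, prev) and lab[prev] == v):
                        continue  # not a run start
                    length = 1
                    cur = (z + d[0], y + d[1], x + d[2])
                    while _inb(shape, cur) and lab[cur] == v:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    P[(v, length)] = P.get((v, length), 0) + 1
    return P


def _oracle_zones(lab, Ng):
    zones = {}
    seen = np.zeros(lab.shape, bool)
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(lab.shape[0]):
        for y in range(lab.shape[1]):
            for x in range(lab.shape[2]):
                if lab[z, y, x] == 0 or seen[z, y, x]:
                    continue
                v = lab[z, y, x]
                stack, size = [(z, y, x)], 0
                seen[z, y, x] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in offs:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inb(lab.shape, q) and not seen[q] and lab[q] == v:
                            seen[q] = True
                            stack.append(q)
                zones[(v, size)] = zones.get((v, size), 0) + 1
    return zones


def _oracle_dependence(lab):
    deps = []
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(lab.shape[0]):
        for y in range(lab.shape[1]):
            for x in range(lab.shape[2]):
                v = lab[z, y, x]
                if v == 0:
                    continue
                dep = 1
                for d in offs:
                    q = (z + d[0], y + d[1], x + d[2])
                    if _inb(lab.shape, q) and lab[q] == v:
                        dep += 1
                deps.append((v, dep))
    return deps


class TestGLCM:
    def test_matches_pair_counting_oracle(self, tiny):
        lab, Ng = tiny
        P = _oracle_glcm(lab, Ng)
        i = np.arange(1, Ng + 1, dtype=float)
        I, J = np.meshgrid(i, i, indexing="ij")
        got = bank.glcm_features(lab, Ng)
        assert got["Contrast"] == pytest.approx(np.sum((I - J) ** 2 * P), abs=1e-10)
        assert got["JointEnergy"] == pytest.approx(np.sum(P**2), abs=1e-10)
        assert got["MaximumProbability"] == pytest.approx(P.max(), abs=1e-10)
        assert got["Autocorrelation"] == pytest.approx(np.sum(I * J * P), abs=1e-10)
        nzP = P[P > 0]
        assert got["JointEntropy"] == pytest.approx(
            -np.sum(nzP * np.log2(nzP)), abs=1e-10
        )

    def test_single_level_degenerate(self):
        lab = np.zeros((3, 3, 3), np.int32)
        lab[1, 1, :] = 1
        got = bank.glcm_features(lab, 1)
        assert got["Contrast"] == 0
        assert got["JointEnergy"] == 1
        assert got["MaximumProbability"] == 1


class TestGLRLM:
    def test_matches_line_scanning_oracle(self, tiny):
        lab, Ng = tiny
        runs = _oracle_runs(lab, Ng)
        Nr = sum(runs.values())
        got = bank.glrlm_features(lab, Ng)
        sre = sum(c / l**2 for (_, l), c in runs.items()) / Nr
        lre = sum(c * l**2 for (_, l), c in runs.items()) / Nr
        glnu = 0.0
        for level in range(1, Ng + 1):
            glnu += sum(c for (v, _), c in runs.items() if v == level) ** 2
        assert got["ShortRunEmphasis"] == pytest.approx(sre, abs=1e-10)
        assert got["LongRunEmphasis"] == pytest.approx(lre, abs=1e-10)
        assert got["GrayLevelNonUniformity"] == pytest.approx(glnu / Nr, abs=1e-10)
        assert got["RunPercentage"] == pytest.approx(
            Nr / ((lab > 0).sum() * 13), abs=1e-10
        )


class TestGLSZM:
    def test_matches_flood_fill_oracle(self, tiny):
        lab, Ng = tiny
        zones = _oracle_zones(lab, Ng)
        Nz = sum(zones.values())
        got = bank.glszm_features(lab, Ng)
        sae = sum(c / s**2 for (_, s), c in zones.items()) / Nz
        lae = sum(c * s**2 for (_, s), c in zones.items()) / Nz
        assert got["SmallAreaEmphasis"] == pytest.approx(sae, abs=1e-10)
        assert got["LargeAreaEmphasis"] == pytest.approx(lae, abs=1e-10)
        assert got["ZonePercentage"] == pytest.approx(
            Nz / (lab > 0).sum(), abs=1e-10
        )


class TestGLDM:
    def test_matches_neighbor_counting_oracle(self, tiny):
        lab, Ng = tiny
        deps = _oracle_dependence(lab)
        N = len(deps)
        got = bank.gldm_features(lab, Ng)
        sde = sum(1 / d**2 for _, d in deps) / N
        lde = sum(d**2 for _, d in deps) / N
        hgle = sum(v**2 for v, _ in deps) / N
        assert got["SmallDependenceEmphasis"] == pytest.approx(sde, abs=1e-10)
        assert got["LargeDependenceEmphasis"] == pytest.approx(lde, abs=1e-10)
        assert got["HighGrayLevelEmphasis"] == pytest.approx(hgle, abs=1e-10)


class TestNGTDM:
    def test_coarseness_on_handmade_volume(self):
        # a 1x3x3 plane: center 2 surrounded by 1s; only in-mask neighbors count
        lab = np.array([[[1, 1, 1], [1, 2, 1], [1, 1, 1]]], np.int32)
        got = bank.ngtdm_features(lab, 2)
        # level 2: one voxel, neighbor mean 1, s_2 = 1
        # level 1: corners see neighbors {1,1,2} (mean 4/3), edges see
        # {1,1,1,2,1} (mean 6/5)
        s1 = 4 * abs(1 - 4 / 3) + 4 * abs(1 - 6 / 5)
        s2 = 1.0
        p1, p2 = 8 / 9, 1 / 9
        assert got["Coarseness"] == pytest.approx(
            1.0 / (p1 * s1 + p2 * s2), abs=1e-10
        )


class TestFirstOrder:
    def test_against_direct_formulas(self):
        rng = np.random.default_rng(5)
        img = rng.random((4, 4, 4)) * 50
        mask = rng.random((4, 4, 4)) > 0.3
        x = img[mask]
        got = bank.first_order_features(img, mask, bin_width=5.0, voxel_volume=2.0)
        assert got["Mean"] == pytest.approx(x.mean())
        assert got["Variance"] == pytest.approx(x.var())
        assert got["Energy"] == pytest.approx((x**2).sum())
        assert got["TotalEnergy"] == pytest.approx(2.0 * (x**2).sum())
        assert got["RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()))
        assert got["Range"] == pytest.approx(x.max() - x.min())
        assert got["InterquartileRange"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25)
        )
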