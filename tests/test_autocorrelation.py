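import itertools

import numpy as np
import pytest
from scipy import stats

from arealrisk.areal_core import SpatialWeights, build_contiguity, row_standardize
from arealrisk.autocorrelation import (
    LocalGResult,
    classify_hot_cold,
    general_g,
    local_gi_star,
    morans_i,
)
from arealrisk.errors import DegenerateInputError, DomainError
from arealrisk.synthetic_data import grid_lattice


@pytest.fixture(scope="module")
def line5():
    nbrs = {"0": ["1"], "1": ["0", "2"], "2": ["1", "3"], "3": ["2", "4"],
            "4": ["3"]}
    return SpatialWeights(ids=list("01234"), neighbors=nbrs)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        lat = grid_lattice(2, 2)
        w = build_contiguity(lat, rule="rook")
        x = np.array([1.0, -1.0, -1.0, 1.0])  # row-major: perfect alternation
        res = morans_i(x, w)
        assert res.statistic == pytest.approx(-1.0)
        # independent brute-force double sum
        wm = w.matrix()
        z = x - x.mean()
        brute = 4 / wm.sum() * sum(
            wm[i, j] * z[i] * z[j] for i in range(4) for j in range(4)
        ) / (z @ z)
        assert res.statistic == pytest.approx(brute)

    @pytest.mark.parametrize("n", [4, 9, 57])
    def test_expectation_closed_form(self, n):
        side = int(np.sqrt(n)) if int(np.sqrt(n)) ** 2 == n else None
        if side:
            lat = grid_lattice(side, side)
        else:
            lat = grid_lattice(1, n)
        w = build_contiguity(lat, rule="rook")
        rng = np.random.default_rng(n)
        res = morans_i(rng.normal(size=n), w)
        assert res.expectation == pytest.approx(-1.0 / (n - 1))

    def test_constant_values_rejected(self, line5):
        with pytest.raises(DegenerateInputError):
            morans_i(np.ones(5), line5)

    def test_randomization_variance_vs_exhaustive(self, line5):
        # oracle: exhaustive permutation distribution on 5 areas
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        res = morans_i(x, line5, method="randomization")
        wm = line5.matrix()
        z = x - x.mean()
        sims = []
        for perm in itertools.permutations(z):
            v = np.array(perm)
            sims.append(5 / wm.sum() * (v @ wm @ v) / (v @ v))
        sims = np.asarray(sims)
        assert res.expectation == pytest.approx(sims.mean())
        assert res.variance == pytest.approx(sims.var(), rel=1e-10)

    def test_two_block_surface_positive(self):
        lat = grid_lattice(4, 4)
        w = row_standardize(build_contiguity(lat, rule="rook"))
        x = np.array([1.0] * 8 + [0.0] * 8)  # constant-by-half blocks
        assert morans_i(x, w).statistic > 0

    def test_permutation_p_close_to_analytic(self):
        lat = grid_lattice(1, 57)  # any 57-area lattice
        lat2 = grid_lattice(8, 8, merge_pairs=7)
        w = row_standardize(build_contiguity(lat2, rule="queen"))
        rng = np.random.default_rng(7)
        n_perm = 999
        agree = 0
        for rep in range(5):
            x = rng.normal(size=57)
            a = morans_i(x, w, method="randomization")
            p = morans_i(x, w, method="permutation", n_permutations=n_perm,
                         seed=100 + rep)
            se = np.sqrt(max(a.p * (1 - a.p), 1e-6) / n_perm)
            agree += abs(p.p - a.p) < 3 * max(se, 1.0 / n_perm) + 2.0 / n_perm
        assert agree >= 4

    def test_invariant_to_additive_constant(self, line5):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        a = morans_i(x, line5)
        b = morans_i(x + 123.4, line5)
        assert b.statistic == pytest.approx(a.statistic)
        assert b.z == pytest.approx(a.z)

    def test_permutation_p_values_on_grid(self):
        lat = grid_lattice(4, 4)
        w = build_contiguity(lat, rule="rook")
        x = np.arange(16.0)
        res = morans_i(x, w, method="permutation", n_permutations=99, seed=0)
        assert 0 < res.p <= 1
        assert round(res.p * 100) == pytest.approx(res.p * 100)  # k/(R+1) grid


class TestGeneralG:
    def test_mutual_pair_is_one(self):
        w = SpatialWeights(ids=["a", "b"], neighbors={"a": ["b"], "b": ["a"]})
        res = general_g(np.array([3.0, 4.0]), w)
        assert res.statistic == pytest.approx(1.0)

    def test_adjacent_highs_concentrate_more(self):
        lat = grid_lattice(3, 3)
        w = build_contiguity(lat, rule="rook")
        base = np.ones(9)
        adjacent = base.copy()
        adjacent[[3, 4]] = 10.0  # neighboring cells
        dispersed = base.copy()
        dispersed[[0, 8]] = 10.0  # opposite corners
        g_adj = general_g(adjacent, w).statistic
        g_dis = general_g(dispersed, w).statistic
        assert g_adj > g_dis
        # brute-force double-sum oracle for the adjacent layout
        wm = w.matrix()
        num = sum(wm[i, j] * adjacent[i] * adjacent[j]
                  for i in range(9) for j in range(9) if i != j)
        den = sum(adjacent[i] * adjacent[j]
                  for i in range(9) for j in range(9) if i != j)
        assert g_adj == pytest.approx(num / den)

    def test_complete_graph_equals_expectation(self):
        ids = list("abcde")
        nbrs = {i: [j for j in ids if j != i] for i in ids}
        w = SpatialWeights(ids=ids, neighbors=nbrs)
        res = general_g(np.array([1.0, 4.0, 2.0, 7.0, 3.0]), w)
        assert res.statistic == pytest.approx(res.expectation)

    def test_variance_vs_exhaustive(self, line5):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        res = general_g(x, line5)
        wm = line5.matrix()
        sims = []
        for perm in itertools.permutations(x):
            v = np.array(perm)
            sims.append((v @ wm @ v) / (v.sum() ** 2 - (v**2).sum()))
        sims = np.asarray(sims)
        assert res.expectation == pytest.approx(sims.mean())
        assert res.variance == pytest.approx(sims.var(), rel=1e-10)

    def test_negative_values_rejected(self, line5):
        with pytest.raises(DomainError):
            general_g(np.array([1.0, -1.0, 2.0, 3.0, 4.0]), line5)


class TestLocalGiStar:
    def test_constant_surface_all_zero(self, line5):
        res = local_gi_star(np.full(5, 7.0), line5)
        np.testing.assert_allclose(res.z, 0.0)

    def test_spike_maximizes_z_at_spike(self):
        # corner spike: its window is smallest, so brute force puts the
        # max z there (interior spikes can be outscored by smaller
        # windows of edge neighbors that still hold all the mass)
        lat = grid_lattice(4, 4)
        w = build_contiguity(lat, rule="rook")
        x = np.zeros(16)
        spike = 0
        x[spike] = 100.0
        res = local_gi_star(x, w)
        assert int(np.argmax(res.z)) == spike
        # brute-force z at the spike from the standard moments
        wm = w.matrix()
        np.fill_diagonal(wm, 1.0)
        n = 16
        xbar, s = x.mean(), x.std()
        wi = wm[spike].sum()
        s1 = (wm[spike] ** 2).sum()
        zref = (wm[spike] @ x - xbar * wi) / (
            s * np.sqrt((n * s1 - wi**2) / (n - 1))
        )
        assert res.z[spike] == pytest.approx(zref)

    def test_full_window_numerator_conserves_total(self):
        ids = list("abcd")
        nbrs = {i: [j for j in ids if j != i] for i in ids}
        w = SpatialWeights(ids=ids, neighbors=nbrs)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = local_gi_star(x, w)
        # every full-window local sum equals the global total
        np.testing.assert_allclose(res.gi_star * x.sum(), x.sum())

    def test_global_max_with_high_neighbors_peaks_there(self):
        lat = grid_lattice(5, 5)
        w = build_contiguity(lat, rule="rook")
        x = np.zeros(25)
        x[12] = 10.0  # global max at the center
        for j in (7, 11, 13, 17):
            x[j] = 5.0  # next-largest ring
        res = local_gi_star(x, w)
        assert int(np.argmax(res.z)) == 12

    def test_invariant_to_additive_constant(self, line5):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        a = local_gi_star(x, line5)
        b = local_gi_star(x + 55.0, line5)
        np.testing.assert_allclose(a.z, b.z, atol=1e-9)

    def test_p_matches_z(self, line5):
        res = local_gi_star(np.array([1.0, 2.0, 3.0, 5.0, 8.0]), line5)
        np.testing.assert_allclose(res.p, 2 * stats.norm.sf(np.abs(res.z)))


class TestClassifyHotCold:
    @pytest.mark.parametrize(
        "z, p, label",
        [
            (2.55, 0.01, "hot"),
            (-2.39, 0.02, "cold"),
            (0.4, 0.69, "not_significant"),
        ],
    )
    def test_labels(self, z, p, label):
        local = LocalGResult(
            area_ids=["a"], gi_star=np.array([0.1]),
            z=np.array([z]), p=np.array([p]),
        )
        out = classify_hot_cold(local, alpha=0.10)
        assert out.cluster_label == [label]

    def test_threshold_boundary_inclusive(self):
        local = LocalGResult(
            area_ids=["a"], gi_star=np.array([0.1]),
            z=np.array([1.9]), p=np.array([0.10]),
        )
        assert classify_hot_cold(local, alpha=0.10).cluster_label == ["hot"]
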