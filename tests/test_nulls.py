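"""Null-model families and the empirical-p / FDR machinery."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from statsmodels.stats.multitest import multipletests

import eigencoupling as ec
from eigencoupling.coupling import CouplingMap
from eigencoupling.eigenmodes import FrequencyBand
from eigencoupling.nulls import NullEnsemble, _greedy_match


def _coupling(values):
    return CouplingMap(R=np.asarray(values, dtype=float),
                       band=FrequencyBand(kind="low", K=2, mode_indices=(2,)))


class TestEmpiricalP:
    def test_hand_count_plus_one_rule(self):
        ens = NullEnsemble(kind="label_perm",
                           samples=np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0]))
        res = ec.empirical_p(7.5, ens, side="greater")  # 3 values >= 7.5
        assert res["p"] == pytest.approx(4 / 11)
        assert res["raw_proportion"] == pytest.approx(3 / 10)

    def test_extreme_observation_reports_floor(self):
        ens = NullEnsemble(kind="spin", samples=np.linspace(0, 1, 10_000))
        res = ec.empirical_p(2.0, ens, side="greater")
        assert res["raw_proportion"] == 0.0
        assert res["p"] == pytest.approx(1 / 10_001)
        assert res["floor"] == pytest.approx(1 / 10_001)

    def test_median_observation(self, rng):
        ens = NullEnsemble(kind="spin", samples=rng.standard_normal(10_001))
        res = ec.empirical_p(float(np.median(ens.samples)), ens, side="greater")
        assert res["p"] == pytest.approx(0.5, abs=0.01)

    def test_two_sided_capped(self, rng):
        ens = NullEnsemble(kind="spin", samples=rng.standard_normal(99))
        res = ec.empirical_p(0.0, ens, side="two_sided")
        assert res["p"] <= 1.0

    def test_invalid_side(self):
        ens = NullEnsemble(kind="spin", samples=np.ones(5))
        with pytest.raises(ValueError):
            ec.empirical_p(1.0, ens, side="both")


class TestFdrBH:
    def test_worked_example(self):
        adjusted, reject = ec.fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.5])
        assert list(reject) == [True, True, True, False]

    def test_all_equal(self):
        adjusted, _ = ec.fdr_bh(np.full(7, 0.2))
        np.testing.assert_allclose(adjusted, 0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_statsmodels_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=20)
        adjusted, reject = ec.fdr_bh(p, q=0.05)
        sm_reject, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
        assert np.array_equal(reject, sm_reject)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=30)
        adjusted, _ = ec.fdr_bh(p)
        assert np.all(adjusted >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ec.fdr_bh(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(1, 40),
                  elements=st.floats(0.0, 1.0, allow_nan=False)))
    def test_matches_statsmodels_on_arbitrary_inputs(self, p):
        adjusted, _ = ec.fdr_bh(p)
        _, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)


class TestEmpiricalPProperties:
    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(1, 60),
                  elements=st.floats(-5, 5, allow_nan=False)),
           st.floats(-5, 5, allow_nan=False))
    def test_counting_rule_and_bounds(self, samples, observed):
        ens = NullEnsemble(kind="spin", samples=samples)
        for side in ("greater", "less"):
            res = ec.empirical_p(observed, ens, side=side)
            count = (samples >= observed).sum() if side == "greater" \
                else (samples <= observed).sum()
            assert res["p"] == pytest.approx((1 + count) / (1 + samples.size))
            assert res["floor"] <= res["p"] <= 1.0
        two = ec.empirical_p(observed, ens, side="two_sided")
        assert 0.0 < two["p"] <= 1.0


class TestZFromNull:
    def test_at_mean_and_two_sd(self):
        samples = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ens = NullEnsemble(kind="rewire", samples=samples)
        assert ec.z_from_null(3.0, ens) == pytest.approx(0.0)
        sd = samples.std(ddof=1)
        assert ec.z_from_null(3.0 + 2 * sd, ens) == pytest.approx(2.0)

    def test_zero_variance_error(self):
        ens = NullEnsemble(kind="rewire", samples=np.ones(10))
        with pytest.raises(ValueError):
            ec.z_from_null(0.5, ens)


class TestLabelPermutationTest:
    def test_constant_coupling_degenerate(self):
        coupling = _coupling(np.full(40, 0.5))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 20
        table = ec.label_permutation_test(coupling, labels, n=200, seed=0)
        np.testing.assert_allclose(table["z"], 0.0)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_planted_network_elevated(self, rng):
        R = rng.normal(0.4, 0.02, 60)
        R[:15] += 0.3  # network "a" elevated far beyond null spread
        coupling = _coupling(np.clip(R, -1, 1))
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 30
        table = ec.label_permutation_test(coupling, labels, n=1000, seed=1,
                                          side="greater")
        assert table.loc["a", "p"] == pytest.approx(1 / 1001)
        assert table.loc["a", "raw_proportion"] == 0.0
        assert table.loc["a", "z"] > 5

    def test_empty_network_error(self):
        coupling = _coupling(np.full(4, 0.5))
        with pytest.raises(ValueError, match="n must be"):
            ec.label_permutation_test(coupling, ["a"] * 4, n=10, seed=0)

    def test_deterministic(self, rng):
        coupling = _coupling(rng.uniform(0, 1, 30))
        labels = ["a"] * 10 + ["b"] * 20
        t1 = ec.label_permutation_test(coupling, labels, n=200, seed=5)
        t2 = ec.label_permutation_test(coupling, labels, n=200, seed=5)
        assert t1.equals(t2)


class TestSpinPermutation:
    def test_identity_rotation_identity_permutation(self, sc60):
        # greedy matching of unrotated coordinates maps regions to themselves
        from scipy.spatial.distance import cdist

        unit = sc60.coordinates
        perm = _greedy_match(cdist(unit, unit))
        assert np.array_equal(perm, np.arange(60))

    def test_outputs_are_bijections(self, sc60):
        perms = ec.spin_permutation(sc60.coordinates, 20, seed=3)
        for p in perms:
            assert np.array_equal(np.sort(p), np.arange(60))

    def test_reproducible(self, sc60):
        a = ec.spin_permutation(sc60.coordinates, 5, seed=9)
        b = ec.spin_permutation(sc60.coordinates, 5, seed=9)
        assert np.array_equal(a, b)

    def test_exact_assignment_option(self, sc60):
        perms = ec.spin_permutation(sc60.coordinates, 3, seed=4, method="exact")
        for p in perms:
            assert np.array_equal(np.sort(p), np.arange(60))

    def test_collinear_coordinates_rejected(self):
        coords = np.column_stack([np.linspace(1, 2, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            ec.spin_permutation(coords, 2, seed=0)


class TestRewirePreservingDegree:
    def test_degree_sequence_exact(self, sc60):
        surrogate = ec.rewire_preserving_degree(sc60, seed=1)
        np.testing.assert_array_equal((surrogate.adjacency > 0).sum(axis=1),
                                      (sc60.adjacency > 0).sum(axis=1))

    def test_weight_multiset_and_totals_conserved(self, sc60):
        surrogate = ec.rewire_preserving_degree(sc60, seed=2)
        iu = np.triu_indices(60, k=1)
        w_orig = np.sort(sc60.adjacency[iu][sc60.adjacency[iu] > 0])
        w_new = np.sort(surrogate.adjacency[iu][surrogate.adjacency[iu] > 0])
        np.testing.assert_allclose(w_orig, w_new)
        assert surrogate.adjacency.sum() == pytest.approx(sc60.adjacency.sum())

    def test_randomization_depth(self):
        # edgewise Jaccard overlap decreases (in expectation) with swap count
        sc = ec.generate_structural_connectome(30, 0.3, seed=5)
        iu = np.triu_indices(30, k=1)
        base = sc.adjacency[iu] > 0

        def mean_jaccard(n_swaps, n_seeds=50):
            vals = []
            for s in range(n_seeds):
                surr = ec.rewire_preserving_degree(sc, n_swaps=n_swaps, seed=s)
                e = surr.adjacency[iu] > 0
                vals.append((base & e).sum() / (base | e).sum())
            return np.mean(vals)

        j = [mean_jaccard(n) for n in (2, 20, 200)]
        assert j[0] > j[1] > j[2]

    def test_too_few_edges(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[1, 2] = A[2, 1] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        sc = ec.StructuralConnectome(adjacency=A)
        # path graph: swaps exist but must not break connectivity
        surr = ec.rewire_preserving_degree(sc, n_swaps=5, seed=0)
        from eigencoupling.connectome import is_connected

        assert is_connected(surr.adjacency)


class TestDegreePreservingSpatialNull:
    def test_degrees_coordinates_weights(self, sc60):
        surrogate = ec.degree_preserving_spatial_null(sc60, seed=7)
        np.testing.assert_array_equal((surrogate.adjacency > 0).sum(axis=1),
                                      (sc60.adjacency > 0).sum(axis=1))
        assert np.array_equal(surrogate.coordinates, sc60.coordinates)
        iu = np.triu_indices(60, k=1)
        np.testing.assert_allclose(
            np.sort(surrogate.adjacency[iu][surrogate.adjacency[iu] > 0]),
            np.sort(sc60.adjacency[iu][sc60.adjacency[iu] > 0]))

    def test_spectral_decorrelation(self, sc60, basis60):
        # surrogate eigenmodes decorrelate from the originals far below the
        # aligned small-jitter benchmark
        rng = np.random.default_rng(0)
        A = sc60.adjacency * rng.lognormal(0.0, 0.01, (60, 60))
        A = np.triu(A, 1)
        A = A + A.T
        jit_basis = ec.eigendecompose(ec.build_laplacian(sc60.with_adjacency(A)))
        jit_cos = np.abs(np.sum(
            basis60.U[:, 1:] * ec.align_eigenmodes(jit_basis, basis60).U[:, 1:], axis=0))

        surr = ec.degree_preserving_spatial_null(sc60, seed=8)
        surr_basis = ec.eigendecompose(ec.build_laplacian(surr))
        surr_cos = np.abs(np.sum(
            basis60.U[:, 1:] * ec.align_eigenmodes(surr_basis, basis60).U[:, 1:], axis=0))
        assert surr_cos.mean() < jit_cos.mean()
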