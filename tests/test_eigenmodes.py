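"""Laplacian construction, decomposition, bands, alignment, pseudo-modes,
and the heat-kernel prediction."""

from __future__ import annotations

import numpy as np
import pytest
import sympy
from scipy.optimize import linear_sum_assignment

import eigencoupling as ec
from eigencoupling.connectome import StructuralConnectome
from eigencoupling.eigenmodes import EigenmodeBasis, heat_kernel_expm


def _sc_from(A, **kw):
    return StructuralConnectome(adjacency=np.asarray(A, dtype=float), **kw)


class TestBuildLaplacian:
    def test_three_node_path_closed_form(self):
        sc = _sc_from([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        basis = ec.build_laplacian(sc)
        expected_L = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        np.testing.assert_allclose(basis.L, expected_L, atol=1e-12)
        assert basis.lambda_max_raw == pytest.approx(3.0, abs=1e-10)
        basis = ec.eigendecompose(basis)
        np.testing.assert_allclose(basis.eigenvalues, [0.0, 1.0 / 3.0, 1.0], atol=1e-10)

    def test_row_sums_zero(self, sc60):
        basis = ec.build_laplacian(sc60)
        np.testing.assert_allclose(basis.L.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(basis.L @ np.ones(sc60.n_regions), 0.0, atol=1e-10)

    def test_degree_matrix(self, sc60):
        basis = ec.build_laplacian(sc60)
        np.testing.assert_allclose(np.diag(basis.D), sc60.adjacency.sum(axis=1))

    def test_eigenvalues_match_characteristic_polynomial_oracle(self, rng):
        # independent oracle: sympy characteristic polynomial, roots via numpy
        W = rng.uniform(0.5, 2.0, size=(5, 5))
        A = np.triu(W, 1)
        A = A + A.T
        sc = _sc_from(A)
        basis = ec.eigendecompose(ec.build_laplacian(sc))
        M = sympy.Matrix((basis.L_norm * 1.0).tolist())
        coeffs = [float(c) for c in M.charpoly().all_coeffs()]
        roots = np.sort(np.real(np.roots(coeffs)))
        np.testing.assert_allclose(basis.eigenvalues, roots, atol=1e-8)

    def test_rejects_asymmetric_and_negative(self):
        with pytest.raises(ValueError):
            _sc_from([[0, 1, 0], [0.5, 0, 1], [0, 1, 0]])
        with pytest.raises(ValueError):
            _sc_from([[0, -1], [-1, 0]])

    def test_rejects_disconnected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            _sc_from(A)


class TestEigendecompose:
    def test_complete_graph_spectrum(self):
        A = 1.0 - np.eye(4)
        basis = ec.eigendecompose(ec.build_laplacian(_sc_from(A)))
        assert basis.lambda_max_raw == pytest.approx(4.0, abs=1e-10)
        np.testing.assert_allclose(basis.eigenvalues, [0, 1, 1, 1], atol=1e-10)

    def test_constant_first_mode(self, basis60):
        n = basis60.n_regions
        np.testing.assert_allclose(basis60.U[:, 0], np.full(n, 1 / np.sqrt(n)), atol=1e-10)
        assert abs(basis60.eigenvalues[0]) <= 1e-10

    def test_orthonormality(self, dense200):
        _, basis = dense200
        err = np.abs(basis.U.T @ basis.U - np.eye(200)).max()
        assert err < 1e-8

    def test_eigenvalues_ascending_in_unit_interval(self, basis60):
        lam = basis60.eigenvalues
        assert np.all(np.diff(lam) >= -1e-12)
        assert lam[0] >= -1e-12 and lam[-1] <= 1.0 + 1e-12

    def test_deterministic_repeat(self, sc60):
        b1 = ec.eigendecompose(ec.build_laplacian(sc60))
        b2 = ec.eigendecompose(ec.build_laplacian(sc60))
        assert np.array_equal(b1.U, b2.U)
        assert np.array_equal(b1.eigenvalues, b2.eigenvalues)

    def test_sign_convention(self, basis60):
        anchored = basis60.U[np.argmax(np.abs(basis60.U), axis=0),
                             np.arange(basis60.n_regions)]
        assert np.all(anchored > 0)

    def test_degenerate_fit_invariance(self):
        # K4 has a triply degenerate eigenvalue; reconstruction through the
        # full basis must be exact regardless of the within-group ordering.
        A = 1.0 - np.eye(4)
        basis = ec.eigendecompose(ec.build_laplacian(_sc_from(A)))
        F = ec.FunctionalConnectome(matrix=np.array([
            [1.0, 0.3, -0.2, 0.1],
            [0.3, 1.0, 0.4, -0.1],
            [-0.2, 0.4, 1.0, 0.2],
            [0.1, -0.1, 0.2, 1.0],
        ]))
        fit = ec.whole_brain_fit(F, basis, range(1, 5))
        recon = (basis.U * fit.coefficients) @ basis.U.T
        off = ~np.eye(4, dtype=bool)
        # projection residual is orthogonal to all rank-one mode terms
        resid = F.matrix - recon
        for k in range(4):
            u = basis.U[:, k]
            assert abs(u @ resid @ u) < 1e-10
        assert np.isfinite(recon[off]).all()


@pytest.fixture(scope="module")
def basis1000():
    # only the region count matters for band selection
    return EigenmodeBasis(L=np.zeros((1000, 1000)), degrees=np.zeros(1000),
                          L_norm=np.zeros((1000, 1000)), lambda_max_raw=1.0)


class TestSelectBand:

    def test_low_default(self, basis1000):
        band = ec.select_band(basis1000, "low", 14)
        assert band.size == 13
        assert band.mode_indices == tuple(range(2, 15))

    def test_high_default(self, basis1000):
        band = ec.select_band(basis1000, "high", 434)
        assert band.size == 567
        assert band.mode_indices == tuple(range(434, 1001))

    def test_low_full_basis_exact_fit(self, basis60, rng):
        band = ec.select_band(basis60, "low", 60)
        S = rng.standard_normal((60, 60)) * 0.1
        F = ec.FunctionalConnectome(matrix=np.clip((S + S.T) / 2, -1, 1)
                                    - np.diag(np.diag((S + S.T) / 2)) + np.eye(60))
        cmap = ec.coupling_map(F, basis60, band)
        np.testing.assert_allclose(cmap.R, 1.0, atol=1e-10)

    def test_out_of_range(self, basis1000):
        with pytest.raises(ValueError):
            ec.select_band(basis1000, "low", 1)
        with pytest.raises(ValueError):
            ec.select_band(basis1000, "high", 1001)


class TestAlignEigenmodes:
    def test_identity(self, basis60):
        aligned = ec.align_eigenmodes(basis60, basis60)
        assert np.array_equal(aligned.alignment["permutation"], np.arange(60))
        assert np.all(aligned.alignment["signs"] == 1.0)

    def test_sign_flip_recovered(self, basis60):
        from dataclasses import replace
        U_flipped = basis60.U.copy()
        U_flipped[:, 5] *= -1
        flipped = replace(basis60, U=U_flipped)
        aligned = ec.align_eigenmodes(flipped, basis60)
        assert aligned.alignment["signs"][5] == -1.0
        np.testing.assert_allclose(aligned.U, basis60.U, atol=1e-12)

    def test_jittered_alignment_vs_assignment_oracle(self, rng):
        sc = ec.generate_structural_connectome(12, 0.6, seed=3)
        basis = ec.eigendecompose(ec.build_laplacian(sc))
        A = sc.adjacency * rng.lognormal(0.0, 0.01, size=(12, 12))
        A = np.triu(A, 1)
        A = A + A.T
        jittered = ec.eigendecompose(ec.build_laplacian(sc.with_adjacency(A)))

        aligned = ec.align_eigenmodes(jittered, basis, window=11)
        cos = np.abs(np.sum(basis.U * aligned.U, axis=0))
        cos_unaligned = np.abs(np.sum(basis.U * jittered.U, axis=0))
        assert cos.mean() >= cos_unaligned.mean() - 1e-12

        # exhaustive optimal assignment oracle bounds the greedy result
        sim = np.abs(basis.U.T @ jittered.U)
        rows, cols = linear_sum_assignment(-sim)
        optimal = sim[rows, cols].mean()
        assert cos.mean() <= optimal + 1e-12
        assert cos.mean() >= 0.99 * optimal

    def test_never_decreases_mean_cosine(self, basis60, rng):
        from dataclasses import replace
        perm = rng.permutation(60)
        scrambled = replace(basis60, U=basis60.U[:, perm],
                            eigenvalues=basis60.eigenvalues[perm])
        aligned = ec.align_eigenmodes(scrambled, basis60, window=60)
        before = np.abs(np.sum(basis60.U * scrambled.U, axis=0)).mean()
        after = np.abs(np.sum(basis60.U * aligned.U, axis=0)).mean()
        assert after >= before - 1e-12


class TestPseudoEigenmode:
    def test_window_one_returns_mode_itself(self, basis60):
        v = ec.pseudo_eigenmode(basis60, 10, window=1, seed=0)
        assert abs(abs(v @ basis60.U[:, 9]) - 1.0) < 1e-10

    def test_unit_norm_orthogonal_to_constant(self, basis60, rng):
        for k in (2, 17, 60):
            v = ec.pseudo_eigenmode(basis60, k, window=9, seed=rng)
            assert abs(np.linalg.norm(v) - 1.0) < 1e-10
            assert abs(v @ basis60.U[:, 0]) < 1e-10

    def test_spectral_energy_within_window(self, basis60):
        k = 30
        window = 21
        lam = basis60.eigenvalues
        rng = np.random.default_rng(5)
        lo, hi = np.inf, -np.inf
        means = []
        for _ in range(500):
            v = ec.pseudo_eigenmode(basis60, k, window=window, seed=rng)
            proj = basis60.U.T @ v
            support = np.flatnonzero(np.abs(proj) > 1e-10)
            lo = min(lo, lam[support].min())
            hi = max(hi, lam[support].max())
            means.append(proj**2 @ lam)
        dist = np.abs(lam[1:] - lam[k - 1])
        window_lams = lam[1:][np.argsort(dist, kind="stable")[:window]]
        assert lo >= window_lams.min() - 1e-12
        assert hi <= window_lams.max() + 1e-12
        assert window_lams.min() <= np.mean(means) <= window_lams.max()

    def test_boundary_truncation(self, basis60):
        v = ec.pseudo_eigenmode(basis60, 2, window=59, seed=1)
        assert abs(np.linalg.norm(v) - 1.0) < 1e-10

    def test_invalid_window(self, basis60):
        with pytest.raises(ValueError):
            ec.pseudo_eigenmode(basis60, 5, window=4, seed=0)


class TestHeatKernel:
    def test_t_zero_identity(self, basis60):
        F = ec.heat_kernel_fc(basis60, ec.DiffusionParams(beta=1.0, t_crit=0.0))
        np.testing.assert_allclose(F, np.eye(60), atol=1e-10)

    def test_long_time_limit(self, basis60):
        F = ec.heat_kernel_fc(basis60, ec.DiffusionParams(beta=1.0, t_crit=1e6))
        np.testing.assert_allclose(F, np.full((60, 60), 1 / 60), atol=1e-8)

    def test_matches_matrix_exponential_oracle(self):
        sc = ec.generate_structural_connectome(50, 0.3, seed=9)
        basis = ec.eigendecompose(ec.build_laplacian(sc))
        params = ec.DiffusionParams(beta=1.0, t_crit=0.7)
        spectral = ec.heat_kernel_fc(basis, params)
        direct = heat_kernel_expm(basis, params)
        assert np.abs(spectral - direct).max() < 1e-8

    def test_conserves_total_activity(self, basis60, rng):
        params = ec.DiffusionParams(beta=2.0, t_crit=0.4)
        K = ec.heat_kernel_fc(basis60, params)
        x = rng.standard_normal(60)
        assert abs((K @ x).sum() - x.sum()) < 1e-8

    def test_column_accessor(self, basis60):
        params = ec.DiffusionParams(beta=1.0, t_crit=0.5)
        K = ec.heat_kernel_fc(basis60, params)
        np.testing.assert_allclose(ec.heat_kernel_column(basis60, params, 7), K[:, 7],
                                   atol=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ec.DiffusionParams(beta=-1.0, t_crit=0.1)
        with pytest.raises(ValueError):
            ec.DiffusionParams(beta=1.0, t_crit=-0.1)
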