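"""Model comparison: prediction with vs. without high-frequency eigenmodes.

Subjects are repeatedly split 80-20; an L1 penalty on the high-frequency
features is tuned by nested splits strictly inside the training set; the
low-only and combined models are then evaluated on the held-out test
group's matrices. Growth curves quantify the percentage increase in
prediction accuracy as random subsets of high-frequency modes are added.

The L1 solver is a coordinate-descent implementation vectorized across
regions (every region shares the eigenmode design up to its own excluded
self-row), with per-feature penalty factors so the intercept and
low-frequency features can stay unpenalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import FunctionalConnectome, StructuralConnectome
from .coupling import pearson_r
from .eigenmodes import (
    EigenmodeBasis,
    align_eigenmodes,
    build_laplacian,
    eigendecompose,
    pseudo_eigenmode,
)
from .gradient import GradientMap, split_by_gradient
from .synthetic import SubjectSet

__all__ = [
    "ComparisonResult",
    "GrowthCurve",
    "LassoSelection",
    "split_subjects",
    "lasso_profiles",
    "nested_lasso_select",
    "compare_models",
    "growth_curve",
    "pseudo_benchmark",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# L1 solver
# ---------------------------------------------------------------------------

def lasso_profiles(
    X: np.ndarray,
    F: np.ndarray,
    lam: float,
    penalty_factor: np.ndarray,
    warm: np.ndarray | None = None,
    exclude_diagonal: bool = True,
    tol: float = 1e-6,
    max_passes: int = 100_000,
) -> np.ndarray:
    """L1-penalized profile regression for all regions at once.

    Minimizes, for each region i (column of ``F``),

        1/(2 n) * sum_{j != i} (F[j,i] - (X b)_j)^2 + lam * sum_k pf_k |b_k|

    with n the number of included observations. Regions share the design
    ``X``; the self-observation of each region is excluded by masking rather
    than row deletion, which keeps the coordinate-descent updates expressible
    as dense matrix operations over all regions simultaneously.

    Returns the coefficient matrix B of shape (p, N).
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    n_rows, p = X.shape
    n_reg = F.shape[1]
    if F.shape[0] != n_rows:
        raise ValueError("X and F disagree on observation count")
    pf = np.asarray(penalty_factor, dtype=float)
    if pf.shape != (p,):
        raise ValueError("penalty_factor must have one entry per feature")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    n_obs = n_rows - 1 if exclude_diagonal else n_rows
    B = np.zeros((p, n_reg)) if warm is None else warm.copy()
    R = F - X @ B  # residuals including the masked self-rows

    s = (X**2).sum(axis=0)  # per-feature squared norms
    if exclude_diagonal:
        # z[k, i] = ||x_k||^2 - x_{ik}^2  (self-row removed per region)
        Z = s[:, None] - (X.T**2)[:, :n_reg] if n_reg <= n_rows else None
        if Z is None:
            raise ValueError("more regions than observations is unsupported")
    else:
        Z = np.broadcast_to(s[:, None], (p, n_reg)).copy()
    if np.any(Z <= 0):
        raise ValueError("design has a zero-variance feature for some region")

    thresh = n_obs * lam * pf  # per-feature soft threshold
    for _ in range(max_passes):
        max_delta = 0.0
        diag_R = np.diagonal(R).copy() if exclude_diagonal else None
        for k in range(p):
            x = X[:, k]
            rho = x @ R
            if exclude_diagonal:
                rho = rho - x[:n_reg] * diag_R
            rho = rho + B[k] * Z[k]
            if thresh[k] > 0:
                b_new = np.sign(rho) * np.maximum(np.abs(rho) - thresh[k], 0.0) / Z[k]
            else:
                b_new = rho / Z[k]
            delta = b_new - B[k]
            nz = np.abs(delta).max()
            if nz > 0:
                R -= np.outer(x, delta)
                if exclude_diagonal:
                    diag_R = diag_R - x[:n_reg] * delta
                B[k] = b_new
                max_delta = max(max_delta, nz)
        if max_delta < tol * max(1.0, np.abs(B).max()):
            break
    else:
        logger.warning("lasso_profiles: not converged to %.0e in %d passes (lam=%.3g)",
                       tol, max_passes, lam)
    return B


def ols_profiles(X: np.ndarray, F: np.ndarray, exclude_diagonal: bool = True) -> np.ndarray:
    """Per-region ordinary least squares (self-row dropped per region)."""
    n, p = X.shape
    B = np.empty((p, F.shape[1]))
    for i in range(F.shape[1]):
        if exclude_diagonal:
            Xi = np.delete(X, i, axis=0)
            yi = np.delete(F[:, i], i)
        else:
            Xi, yi = X, F[:, i]
        B[:, i], *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    return B


def evaluate_profiles(
    B: np.ndarray, X: np.ndarray, F: np.ndarray, exclude_diagonal: bool = True
) -> np.ndarray:
    """Pearson R between predicted and empirical profiles, per region."""
    pred = X @ B
    out = np.empty(F.shape[1])
    for i in range(F.shape[1]):
        if exclude_diagonal:
            out[i] = pearson_r(np.delete(pred[:, i], i), np.delete(F[:, i], i))
        else:
            out[i] = pearson_r(pred[:, i], F[:, i])
    return out


# ---------------------------------------------------------------------------
# Split and band plumbing
# ---------------------------------------------------------------------------

def split_subjects(
    subjects: SubjectSet | int,
    frac: float = 0.8,
    n_outer: int = 100,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/test subject splits (reproducible, disjoint, exhaustive)."""
    n_subj = len(subjects) if isinstance(subjects, SubjectSet) else int(subjects)
    if n_subj < 5:
        raise ValueError("need at least 5 subjects to split")
    n_train = int(round(frac * n_subj))
    n_train = min(max(n_train, 1), n_subj - 1)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_outer):
        perm = rng.permutation(n_subj)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def band_design(basis: EigenmodeBasis, K_L: int, K_H: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Design [u1 | low modes 2..K_L | high modes K_H..N] and penalty factors.

    Returns (X, penalty_factor, n_unpenalized); the penalty factor is 0 for
    the constant and low-frequency columns, 1 for high-frequency columns.
    """
    n = basis.n_regions
    if not 2 <= K_L < K_H <= n:
        raise ValueError(f"require 2 <= K_L < K_H <= {n}, got K_L={K_L}, K_H={K_H}")
    low = list(range(2, K_L + 1))
    high = list(range(K_H, n + 1))
    X = np.column_stack([basis.modes([1]), basis.modes(low), basis.modes(high)])
    n_unpen = 1 + len(low)
    pf = np.concatenate([np.zeros(n_unpen), np.ones(len(high))])
    return X, pf, n_unpen


def _group_basis(
    subjects: SubjectSet, indices, reference: EigenmodeBasis, align_window: int = 10
) -> EigenmodeBasis:
    sc = StructuralConnectome(
        adjacency=subjects.group_average_sc(indices),
        region_ids=subjects.subjects[0][0].region_ids,
        coordinates=subjects.subjects[0][0].coordinates,
        labels=subjects.subjects[0][0].labels,
    )
    basis = eigendecompose(build_laplacian(sc))
    return align_eigenmodes(basis, reference, window=align_window)


def default_lambda_grid(X: np.ndarray, F: np.ndarray, pf: np.ndarray,
                        n_values: int = 50) -> np.ndarray:
    """Log-spaced grid spanning [1e-4, 1] times the smallest lambda that
    zeroes every penalized coefficient."""
    n_obs = X.shape[0] - 1
    penalized = pf > 0
    corr = np.abs(X[:, penalized].T @ F) / n_obs
    lam_max = float(corr.max())
    if lam_max <= 0:
        lam_max = 1.0
    return lam_max * np.logspace(-4, 0, n_values)


# ---------------------------------------------------------------------------
# Nested selection and comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LassoSelection:
    """Outcome of nested penalty tuning on a training set."""

    chosen_lambda: float
    lambda_grid: np.ndarray
    mean_validation_R: np.ndarray  # per grid value, averaged over inner splits


def nested_lasso_select(
    subjects: SubjectSet,
    train_indices,
    reference_basis: EigenmodeBasis,
    K_L: int,
    K_H: int,
    lambda_grid: np.ndarray | None = None,
    n_inner: int = 20,
    inner_frac: float = 0.8,
    seed: int | None = None,
    align_window: int = 10,
) -> LassoSelection:
    """Choose the L1 penalty by inner train/validation splits.

    Every quantity used here derives from ``train_indices`` only: inner
    80-20 splits of the training subjects, group-average matrices on each
    side, fits across the penalty grid (warm-started from large to small
    lambda), validation by mean per-region Pearson R on the inner
    validation group's matrices.
    """
    train_indices = np.asarray(train_indices, dtype=int)
    rng = np.random.default_rng(seed)
    n_train = train_indices.size
    n_inner_train = min(max(int(round(inner_frac * n_train)), 1), n_train - 1)

    scores = None
    for rep in range(n_inner):
        perm = rng.permutation(n_train)
        inner_tr = train_indices[perm[:n_inner_train]]
        inner_val = train_indices[perm[n_inner_train:]]

        basis_tr = _group_basis(subjects, inner_tr, reference_basis, align_window)
        basis_val = _group_basis(subjects, inner_val, reference_basis, align_window)
        F_tr = subjects.group_average_fc(inner_tr)
        F_val = subjects.group_average_fc(inner_val)
        X_tr, pf, _ = band_design(basis_tr, K_L, K_H)
        X_val, _, _ = band_design(basis_val, K_L, K_H)

        if lambda_grid is None:
            lambda_grid = default_lambda_grid(X_tr, F_tr, pf)
        if scores is None:
            scores = np.zeros(len(lambda_grid))

        B = None
        rep_scores = np.empty(len(lambda_grid))
        for gi in np.argsort(lambda_grid)[::-1]:  # warm start: large -> small
            B = lasso_profiles(X_tr, F_tr, lambda_grid[gi], pf, warm=B)
            rep_scores[gi] = evaluate_profiles(B, X_val, F_val).mean()
        scores += rep_scores
    if scores is None:
        raise ValueError("lambda_grid selection needs at least one inner split")
    scores /= n_inner
    best = int(np.argmax(scores))
    return LassoSelection(
        chosen_lambda=float(lambda_grid[best]),
        lambda_grid=np.asarray(lambda_grid, dtype=float),
        mean_validation_R=scores,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Low-only vs. combined model performance on held-out test sets."""

    r_low: np.ndarray          # per-region mean test R, low-only model
    r_combined: np.ndarray     # per-region mean test R, combined model
    delta: np.ndarray          # r_combined - r_low
    pct_increase: np.ndarray   # 100*delta/r_low where r_low > 0, else NaN
    transmodal_mask: np.ndarray
    per_split_r_low: np.ndarray       # (n_splits, N)
    per_split_r_combined: np.ndarray  # (n_splits, N)
    chosen_lambdas: np.ndarray
    group_tests: dict          # group -> {"t": ..., "p": ...} paired over regions
    top_decile: np.ndarray     # region indices with highest pct increase

    @property
    def group_means(self) -> dict:
        out = {}
        for name, mask in (("unimodal", ~self.transmodal_mask),
                           ("transmodal", self.transmodal_mask)):
            pct = self.pct_increase[mask]
            out[name] = {
                "mean_delta": float(self.delta[mask].mean()),
                "mean_pct_increase": float(np.nanmean(pct)),
            }
        return out


def compare_models(
    subjects: SubjectSet,
    reference_basis: EigenmodeBasis,
    K_L: int,
    K_H: int,
    gradient: GradientMap,
    splits,
    lambda_grid: np.ndarray | None = None,
    n_inner: int = 20,
    seed: int | None = None,
    align_window: int = 10,
) -> ComparisonResult:
    """Fit low-only and low+high models per split and evaluate on test data.

    The penalty is selected by :func:`nested_lasso_select` on each training
    set (never seeing test subjects); the combined model keeps the constant
    and low-frequency features unpenalized. Evaluation uses the test
    subjects' group-average SC eigenmodes (aligned to the reference) and
    the test group-average FC.
    """
    n = subjects.n_regions
    unimodal, transmodal = split_by_gradient(gradient)
    if unimodal.size == 0 or transmodal.size == 0:
        raise ValueError("gradient split produced an empty group")
    tm_mask = np.zeros(n, dtype=bool)
    tm_mask[transmodal] = True

    rng = np.random.default_rng(seed)
    n_splits = len(splits)
    r_low = np.empty((n_splits, n))
    r_comb = np.empty((n_splits, n))
    lambdas = np.empty(n_splits)

    for si, (train_idx, test_idx) in enumerate(splits):
        sel = nested_lasso_select(
            subjects, train_idx, reference_basis, K_L, K_H,
            lambda_grid=lambda_grid, n_inner=n_inner,
            seed=int(rng.integers(0, 2**31 - 1)), align_window=align_window,
        )
        lambdas[si] = sel.chosen_lambda

        basis_tr = _group_basis(subjects, train_idx, reference_basis, align_window)
        F_tr = subjects.group_average_fc(train_idx)
        X_tr, pf, n_unpen = band_design(basis_tr, K_L, K_H)

        B_comb = lasso_profiles(X_tr, F_tr, sel.chosen_lambda, pf)
        B_low = ols_profiles(X_tr[:, :n_unpen], F_tr)

        basis_te = _group_basis(subjects, test_idx, reference_basis, align_window)
        F_te = subjects.group_average_fc(test_idx)
        X_te, _, _ = band_design(basis_te, K_L, K_H)

        r_comb[si] = evaluate_profiles(B_comb, X_te, F_te)
        r_low[si] = evaluate_profiles(B_low, X_te[:, :n_unpen], F_te)

    mean_low = r_low.mean(axis=0)
    mean_comb = r_comb.mean(axis=0)
    delta = mean_comb - mean_low
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean_low > 0, 100.0 * delta / mean_low, np.nan)
    if np.any(mean_low <= 0):
        logger.warning("compare_models: %d regions have non-positive baseline R; "
                       "their percentage increase is NaN", int((mean_low <= 0).sum()))

    group_tests = {}
    for name, mask in (("unimodal", ~tm_mask), ("transmodal", tm_mask)):
        t, p = stats.ttest_rel(mean_comb[mask], mean_low[mask])
        group_tests[name] = {"t": float(t), "p": float(p)}

    k_top = int(np.ceil(0.10 * n))
    finite = np.where(np.isfinite(pct), pct, -np.inf)
    top = np.argsort(finite)[::-1][:k_top]

    return ComparisonResult(
        r_low=mean_low, r_combined=mean_comb, delta=delta, pct_increase=pct,
        transmodal_mask=tm_mask, per_split_r_low=r_low, per_split_r_combined=r_comb,
        chosen_lambdas=lambdas, group_tests=group_tests, top_decile=np.sort(top),
    )


@dataclass(frozen=True)
class GrowthCurve:
    """Percentage increase in R as high-frequency modes are added randomly."""

    proportions: np.ndarray
    mean_pct: dict   # group name -> array over grid
    sd_pct: dict     # group name -> array over grid
    n_rep: int


def growth_curve(
    fc: FunctionalConnectome,
    basis: EigenmodeBasis,
    K_L: int,
    K_H: int,
    gradient: GradientMap,
    grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_rep: int = 10,
    seed: int | None = None,
) -> GrowthCurve:
    """In-sample growth of prediction accuracy under progressive random
    addition of high-frequency modes (group-level OLS, no penalty)."""
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid proportions must lie in [0, 1]")
    n = basis.n_regions
    X, pf, n_unpen = band_design(basis, K_L, K_H)
    high_cols = np.arange(n_unpen, X.shape[1])
    F = fc.matrix
    rng = np.random.default_rng(seed)

    B_low = ols_profiles(X[:, :n_unpen], F)
    r_low = evaluate_profiles(B_low, X[:, :n_unpen], F)
    if np.any(r_low <= 0):
        raise ValueError("baseline low-only R must be positive for growth curves")

    unimodal, transmodal = split_by_gradient(gradient)
    groups = {"unimodal": unimodal, "transmodal": transmodal}
    mean_pct = {k: np.empty(grid.size) for k in groups}
    sd_pct = {k: np.empty(grid.size) for k in groups}

    for gi, prop in enumerate(grid):
        m = int(round(prop * high_cols.size))
        reps = np.empty((n_rep, n))
        for rep in range(n_rep):
            if m == 0:
                r_sel = r_low
            else:
                pick = np.sort(rng.choice(high_cols, size=m, replace=False))
                cols = np.concatenate([np.arange(n_unpen), pick])
                B = ols_profiles(X[:, cols], F)
                r_sel = evaluate_profiles(B, X[:, cols], F)
            reps[rep] = 100.0 * (r_sel - r_low) / r_low
        for name, idx in groups.items():
            vals = reps[:, idx].mean(axis=1)
            mean_pct[name][gi] = vals.mean()
            sd_pct[name][gi] = vals.std(ddof=0)
    return GrowthCurve(proportions=grid, mean_pct=mean_pct, sd_pct=sd_pct, n_rep=n_rep)


def pseudo_benchmark(
    subjects: SubjectSet,
    reference_basis: EigenmodeBasis,
    K_L: int,
    K_H: int,
    splits,
    n_rand: int = 10,
    window: int = 21,
    seed: int | None = None,
    align_window: int = 10,
):
    """Null benchmarks from frequency-matched surrogate eigenmodes.

    For each of ``n_rand`` randomizations and each subject split, fits and
    evaluates (OLS throughout, so the comparison is procedure-matched):

    * ``empirical_low``      - constant + empirical low modes
    * ``empirical_combined`` - constant + empirical low + empirical high
    * ``pseudo_low``         - constant + surrogate low modes
    * ``pseudo_high``        - constant + surrogate high modes
    * ``low_plus_pseudo_high`` - empirical low + surrogate high

    Returns a tidy DataFrame with one row per (model, randomization, split)
    holding the mean test-set R over regions.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = subjects.n_regions
    low_idx = list(range(2, K_L + 1))
    high_idx = list(range(K_H, n + 1))

    rows = []
    for rand in range(n_rand):
        pseudo_seed = int(rng.integers(0, 2**31 - 1))
        for si, (train_idx, test_idx) in enumerate(splits):
            basis_tr = _group_basis(subjects, train_idx, reference_basis, align_window)
            basis_te = _group_basis(subjects, test_idx, reference_basis, align_window)
            F_tr = subjects.group_average_fc(train_idx)
            F_te = subjects.group_average_fc(test_idx)

            prng = np.random.default_rng(pseudo_seed)
            pseudo_low = np.column_stack([
                pseudo_eigenmode(basis_tr, k, window=window, seed=prng) for k in low_idx
            ])
            pseudo_high = np.column_stack([
                pseudo_eigenmode(basis_tr, k, window=window, seed=prng) for k in high_idx
            ])

            u1_tr = basis_tr.modes([1])
            u1_te = basis_te.modes([1])
            lows_tr, lows_te = basis_tr.modes(low_idx), basis_te.modes(low_idx)
            highs_tr, highs_te = basis_tr.modes(high_idx), basis_te.modes(high_idx)

            designs = {
                "empirical_low": (
                    np.column_stack([u1_tr, lows_tr]),
                    np.column_stack([u1_te, lows_te]),
                ),
                "empirical_combined": (
                    np.column_stack([u1_tr, lows_tr, highs_tr]),
                    np.column_stack([u1_te, lows_te, highs_te]),
                ),
                "pseudo_low": (
                    np.column_stack([u1_tr, pseudo_low]),
                    np.column_stack([u1_te, pseudo_low]),
                ),
                "pseudo_high": (
                    np.column_stack([u1_tr, pseudo_high]),
                    np.column_stack([u1_te, pseudo_high]),
                ),
                "low_plus_pseudo_high": (
                    np.column_stack([u1_tr, lows_tr, pseudo_high]),
                    np.column_stack([u1_te, lows_te, pseudo_high]),
                ),
            }
            for model, (X_tr, X_te) in designs.items():
                B = ols_profiles(X_tr, F_tr)
                rows.append({
                    "model": model,
                    "randomization": rand,
                    "split": si,
                    "mean_test_R": float(evaluate_profiles(B, X_te, F_te).mean()),
                })
    return pd.DataFrame(rows)
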