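"""Per-region multilinear structure-function prediction.

For each region, its functional connectivity profile (the region's column
of FC with the self-entry excluded) is regressed on a band of eigenmodes
plus the constant mode, and coupling is summarized as the Pearson
correlation R between predicted and empirical profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import FunctionalConnectome
from .eigenmodes import EigenmodeBasis, FrequencyBand, pseudo_eigenmode

__all__ = [
    "RegionalFit",
    "CouplingMap",
    "WholeBrainFit",
    "fit_region",
    "coupling_map",
    "whole_brain_fit",
    "single_mode_z",
    "pearson_r",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


@dataclass(frozen=True)
class RegionalFit:
    """OLS fit of one region's FC profile on a frequency band."""

    region_index: int
    intercept: float  # coefficient on the constant mode u_1
    coefficients: np.ndarray  # one per band mode
    predicted_profile: np.ndarray  # length N-1 (self excluded) or N
    coupling: float  # Pearson R between predicted and empirical profile


@dataclass(frozen=True)
class CouplingMap:
    """Per-region coupling R for one frequency band."""

    R: np.ndarray
    band: FrequencyBand
    exclude_diagonal: bool = True

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 1:
            raise ValueError("R must be a 1-D array")
        if np.any(np.abs(R) > 1 + 1e-12):
            raise ValueError("coupling values must lie in [-1, 1]")
        object.__setattr__(self, "R", R)

    def __len__(self) -> int:
        return self.R.size


@dataclass(frozen=True)
class WholeBrainFit:
    """Least-squares mode loadings c_k of the whole-brain expansion."""

    mode_indices: tuple[int, ...]
    coefficients: np.ndarray
    R: float  # Pearson R over off-diagonal entries


def _design(basis: EigenmodeBasis, band: FrequencyBand) -> np.ndarray:
    """Constant mode u_1 followed by the band modes (fixed full-row design)."""
    return np.column_stack([basis.modes([1]), basis.modes(band.mode_indices)])


def fit_region(
    fc: FunctionalConnectome,
    basis: EigenmodeBasis,
    band: FrequencyBand,
    i: int,
    exclude_diagonal: bool = True,
) -> RegionalFit:
    """OLS fit of region ``i``'s FC profile on the band modes + constant.

    The design is the fixed eigenmode matrix with row ``i`` dropped (not
    re-orthogonalized), matching the whole-brain expansion restricted to one
    column. Rank deficiency from an oversized band is an error.
    """
    basis._require_decomposed()
    n = basis.n_regions
    if fc.n_regions != n:
        raise ValueError("FC and basis disagree on region count")
    if band.size == 0:
        raise ValueError("band is empty")
    n_obs = n - 1 if exclude_diagonal else n
    if band.size > n_obs - 1 + 1:
        raise ValueError(
            f"band of {band.size} modes exceeds the {n_obs} observations of a "
            "regional profile"
        )
    X = _design(basis, band)
    y = fc.matrix[:, i]
    if exclude_diagonal:
        X = np.delete(X, i, axis=0)
        y = np.delete(y, i)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    return RegionalFit(
        region_index=i,
        intercept=float(coef[0]),
        coefficients=coef[1:].copy(),
        predicted_profile=pred,
        coupling=pearson_r(pred, y),
    )


def coupling_map(
    fc: FunctionalConnectome,
    basis: EigenmodeBasis,
    band: FrequencyBand,
    exclude_diagonal: bool = True,
) -> CouplingMap:
    """Apply :func:`fit_region` to every region."""
    R = np.array([
        fit_region(fc, basis, band, i, exclude_diagonal=exclude_diagonal).coupling
        for i in range(basis.n_regions)
    ])
    return CouplingMap(R=R, band=band, exclude_diagonal=exclude_diagonal)


def _mode_outer_design(vectors: np.ndarray) -> np.ndarray:
    """Vectorized outer products v_k v_k^T as design columns."""
    n, k = vectors.shape
    cols = np.empty((n * n, k))
    for j in range(k):
        cols[:, j] = np.outer(vectors[:, j], vectors[:, j]).ravel()
    return cols


def whole_brain_fit(
    fc: FunctionalConnectome,
    basis: EigenmodeBasis,
    mode_indices,
    vectors: np.ndarray | None = None,
) -> WholeBrainFit:
    """Least-squares c_k for F-hat = sum_k c_k u_k u_k^T.

    The fit runs over all matrix entries, so with the full orthonormal basis
    the solution coincides with the spectral projection u_k^T F u_k. The
    reported R is the Pearson correlation over off-diagonal entries only
    (the unit diagonal is trivial). ``vectors`` overrides the basis columns
    (used for pseudo-eigenmode nulls).
    """
    basis._require_decomposed()
    mode_indices = tuple(int(k) for k in mode_indices)
    if not mode_indices:
        raise ValueError("mode_indices is empty")
    V = basis.modes(mode_indices) if vectors is None else np.asarray(vectors, dtype=float)
    if V.shape[0] != fc.n_regions:
        raise ValueError("mode vectors and FC disagree on region count")
    X = _mode_outer_design(V)
    y = fc.matrix.ravel()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    off = ~np.eye(fc.n_regions, dtype=bool).ravel()
    return WholeBrainFit(
        mode_indices=mode_indices,
        coefficients=coef,
        R=pearson_r(pred[off], y[off]),
    )


def single_mode_z(
    fc: FunctionalConnectome,
    basis: EigenmodeBasis,
    k: int,
    n_null: int = 1000,
    window: int = 21,
    seed: int | None = None,
) -> float:
    """z score of mode k's whole-brain prediction against pseudo-eigenmodes.

    Fits the whole-brain expansion with mode k alone (plus the constant
    mode), repeats with ``n_null`` frequency-matched surrogate modes, and
    standardizes the observed R against the null distribution.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    basis._require_decomposed()
    rng = np.random.default_rng(seed)
    u1 = basis.modes([1])

    def _fit_with(vec: np.ndarray) -> float:
        V = np.column_stack([u1, vec])
        return whole_brain_fit(fc, basis, (1, k), vectors=V).R

    r_obs = _fit_with(basis.modes([k]).ravel())
    null = np.array([
        _fit_with(pseudo_eigenmode(basis, k, window=window, seed=rng))
        for _ in range(n_null)
    ])
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("null distribution has zero variance")
    return float((r_obs - null.mean()) / sd)
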