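"""Graph Laplacian eigenmodes of the structural connectome.

The structural Laplacian ``L = D - A`` is normalized by its largest
eigenvalue so that spectra from networks of different size and density are
comparable. Its orthonormal eigenvectors, ordered by ascending eigenvalue,
are the spatial harmonics ("eigenmodes") used as predictors throughout the
package: small eigenvalues correspond to smooth, persistent diffusion
patterns, large eigenvalues to spatially complex, transient ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh, expm

from .connectome import StructuralConnectome

__all__ = [
    "EigenmodeBasis",
    "FrequencyBand",
    "DiffusionParams",
    "build_laplacian",
    "eigendecompose",
    "select_band",
    "align_eigenmodes",
    "pseudo_eigenmode",
    "heat_kernel_fc",
    "heat_kernel_column",
]

logger = logging.getLogger(__name__)

_DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class EigenmodeBasis:
    """Laplacian matrices and (optionally) their eigendecomposition.

    ``U`` holds orthonormal eigenvectors of the normalized Laplacian as
    columns, ``eigenvalues`` the matching ascending eigenvalues in [0, 1].
    Mode indices used elsewhere in the package are 1-based: mode 1 is the
    constant eigenvector of a connected graph.
    """

    L: np.ndarray
    degrees: np.ndarray
    L_norm: np.ndarray
    lambda_max_raw: float
    U: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    alignment: dict | None = field(default=None, compare=False)

    @property
    def n_regions(self) -> int:
        return self.L.shape[0]

    @property
    def D(self) -> np.ndarray:
        """Diagonal weighted-degree matrix."""
        return np.diag(self.degrees)

    def modes(self, indices_1based) -> np.ndarray:
        """Columns of U selected by 1-based mode indices."""
        self._require_decomposed()
        idx = np.asarray(indices_1based, dtype=int) - 1
        return self.U[:, idx]

    def _require_decomposed(self) -> None:
        if self.U is None or self.eigenvalues is None:
            raise ValueError("eigendecomposition not available; call eigendecompose() first")


@dataclass(frozen=True)
class FrequencyBand:
    """A contiguous set of eigenmode predictors.

    The low band collects modes 2..K (mode 1 is held out as the constant
    term); the high band collects modes K..N.
    """

    kind: str
    K: int
    mode_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("low", "high"):
            raise ValueError("band kind must be 'low' or 'high'")
        idx = tuple(int(i) for i in self.mode_indices)
        if any(i < 2 for i in idx):
            raise ValueError("band mode indices must be >= 2 (mode 1 is the constant)")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("band mode indices must be strictly increasing")
        object.__setattr__(self, "mode_indices", idx)

    @property
    def size(self) -> int:
        return len(self.mode_indices)


@dataclass(frozen=True)
class DiffusionParams:
    """Decay rate and critical time of the linear network-diffusion model."""

    beta: float
    t_crit: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.t_crit < 0:
            raise ValueError("t_crit must be nonnegative")


def build_laplacian(sc: StructuralConnectome) -> EigenmodeBasis:
    """Form L = D - A and its normalization L' = L / lambda_max(L).

    The decomposition itself is deferred to :func:`eigendecompose`.
    """
    A = sc.adjacency
    degrees = A.sum(axis=1)
    L = np.diag(degrees) - A
    lambda_max = float(eigh(L, eigvals_only=True, subset_by_index=[L.shape[0] - 1, L.shape[0] - 1])[0])
    if lambda_max <= 0:
        raise ValueError("Laplacian has no positive eigenvalue; graph has no edges")
    return EigenmodeBasis(L=L, degrees=degrees, L_norm=L / lambda_max, lambda_max_raw=lambda_max)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties are broken by the lowest region index (argmax picks the first
    maximum), making the convention deterministic across platforms.
    """
    U = U.copy()
    anchor = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[anchor, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _order_degenerate(U: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Within groups of (numerically) equal eigenvalues, order the sign-fixed
    eigenvectors lexicographically by their entries. Exact fits are invariant
    to this choice; it only pins down a reproducible ordering."""
    n = len(eigenvalues)
    order = np.arange(n)
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and eigenvalues[stop] - eigenvalues[stop - 1] <= _DEGENERACY_TOL:
            stop += 1
        if stop - start > 1:
            block = U[:, start:stop]
            # lexsort: last key is primary, so feed rows reversed
            perm = np.lexsort(block[::-1, :])
            order[start:stop] = start + perm
        start = stop
    return order


def eigendecompose(basis: EigenmodeBasis) -> EigenmodeBasis:
    """Eigendecompose the normalized Laplacian with a deterministic
    sign and degeneracy-ordering convention."""
    eigenvalues, U = eigh(basis.L_norm)
    U = _fix_signs(U)
    order = _order_degenerate(U, eigenvalues)
    eigenvalues = eigenvalues[order]
    U = U[:, order]
    # Clamp the tiny negative round-off on the zero eigenvalue.
    eigenvalues = np.where(np.abs(eigenvalues) < 1e-12, 0.0, eigenvalues)
    return replace(basis, U=U, eigenvalues=eigenvalues)


def select_band(basis: EigenmodeBasis, kind: str, K: int) -> FrequencyBand:
    """Select the low band (modes 2..K) or high band (modes K..N)."""
    n = basis.n_regions
    K = int(K)
    if kind == "low":
        if not 2 <= K <= n:
            raise ValueError(f"low-band K must be in [2, {n}], got {K}")
        indices = tuple(range(2, K + 1))
    elif kind == "high":
        if not 2 <= K <= n:
            raise ValueError(f"high-band K must be in [2, {n}], got {K}")
        indices = tuple(range(K, n + 1))
    else:
        raise ValueError("kind must be 'low' or 'high'")
    return FrequencyBand(kind=kind, K=K, mode_indices=indices)


def align_eigenmodes(
    basis: EigenmodeBasis,
    reference: EigenmodeBasis,
    window: int = 10,
) -> EigenmodeBasis:
    """Reorder and sign-flip modes to match a reference basis.

    For each reference mode index the best-matching mode of ``basis`` is
    chosen by absolute cosine similarity, restricted to indices within
    ``window`` positions (eigenvalue crossings between nearby modes are the
    realistic failure mode). Matching is greedy on descending similarity and
    one-to-one. The permutation and signs applied are stored on the returned
    basis under ``alignment``.
    """
    basis._require_decomposed()
    reference._require_decomposed()
    n = basis.n_regions
    if reference.n_regions != n:
        raise ValueError("basis and reference must have the same region count")

    cos = reference.U.T @ basis.U  # cos[r, b]
    abs_cos = np.abs(cos)
    band_mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= window
    masked = np.where(band_mask, abs_cos, -np.inf)

    assignment = np.full(n, -1, dtype=int)
    taken = np.zeros(n, dtype=bool)
    # Greedy: repeatedly take the best remaining (reference, basis) pair.
    flat_order = np.argsort(masked, axis=None)[::-1]
    assigned = 0
    for flat in flat_order:
        r, b = divmod(int(flat), n)
        if masked[r, b] == -np.inf:
            break
        if assignment[r] >= 0 or taken[b]:
            continue
        assignment[r] = b
        taken[b] = True
        assigned += 1
        if assigned == n:
            break
    if assigned < n:  # leftovers outside the window: match by index order
        free_r = np.flatnonzero(assignment < 0)
        free_b = np.flatnonzero(~taken)
        assignment[free_r] = free_b

    signs = np.sign(cos[np.arange(n), assignment])
    signs[signs == 0] = 1.0
    U = basis.U[:, assignment] * signs
    eigenvalues = basis.eigenvalues[assignment]
    mapping = {
        "permutation": assignment.copy(),
        "signs": signs.copy(),
        "window": window,
    }
    logger.debug("eigenmode alignment: %d modes moved", int((assignment != np.arange(n)).sum()))
    return replace(basis, U=U, eigenvalues=eigenvalues, alignment=mapping)


def pseudo_eigenmode(
    basis: EigenmodeBasis,
    k: int,
    window: int = 21,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Surrogate for mode ``k`` with matched spatial frequency.

    Draws a uniformly random unit vector from the span of the ``window``
    eigenmodes whose eigenvalues are nearest to ``lambda_k`` (mode 1 is
    excluded so the surrogate stays orthogonal to the constant vector).
    """
    basis._require_decomposed()
    n = basis.n_regions
    if not 2 <= k <= n:
        raise ValueError(f"mode index k must be in [2, {n}], got {k}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    candidates = np.arange(2, n + 1)
    dist = np.abs(basis.eigenvalues[candidates - 1] - basis.eigenvalues[k - 1])
    width = min(window, candidates.size)
    if width < window:
        logger.info("pseudo_eigenmode: window truncated from %d to %d modes", window, width)
    chosen = candidates[np.argsort(dist, kind="stable")[:width]]

    direction = rng.standard_normal(width)
    direction /= np.linalg.norm(direction)
    return basis.modes(chosen) @ direction


def heat_kernel_fc(basis: EigenmodeBasis, params: DiffusionParams) -> np.ndarray:
    """Predicted FC of the diffusion model: U diag(exp(-beta lambda t)) U^T.

    Equivalent to the matrix exponential ``expm(-beta * L_norm * t)``; the
    spectral form is used because the decomposition is already at hand.
    """
    basis._require_decomposed()
    weights = np.exp(-params.beta * basis.eigenvalues * params.t_crit)
    return (basis.U * weights) @ basis.U.T


def heat_kernel_column(basis: EigenmodeBasis, params: DiffusionParams, i: int) -> np.ndarray:
    """Diffusion-model prediction started from region ``i`` alone active."""
    basis._require_decomposed()
    weights = np.exp(-params.beta * basis.eigenvalues * params.t_crit)
    return (basis.U * weights) @ basis.U[i, :]


def heat_kernel_expm(basis: EigenmodeBasis, params: DiffusionParams) -> np.ndarray:
    """Direct matrix-exponential evaluation (reference path for validation)."""
    return expm(-params.beta * basis.L_norm * params.t_crit)
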