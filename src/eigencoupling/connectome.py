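"""Core connectome containers and validation.

The two matrix types used throughout the package: a weighted structural
adjacency (symmetric, nonnegative, hollow diagonal, connected) and a
functional correlation matrix (symmetric, unit diagonal, entries in [-1, 1]).
Validation is performed eagerly at construction so that downstream numerical
code can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StructuralConnectome",
    "FunctionalConnectome",
    "is_connected",
]

_SYM_TOL = 1e-10


def _as_square(matrix: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square 2-D matrix, got shape {arr.shape}")
    return arr


def is_connected(adjacency: np.ndarray) -> bool:
    """True if the graph with positive-weight edges has a single component."""
    n_comp, _ = connected_components(csr_matrix(adjacency > 0), directed=False)
    return int(n_comp) == 1


def _default_ids(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"region_{i:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class StructuralConnectome:
    """Weighted undirected structural network with optional region metadata.

    Parameters
    ----------
    adjacency
        N x N symmetric nonnegative weight matrix with zero diagonal.
    region_ids
        Region names aligned with matrix rows; generated if omitted.
    coordinates
        Optional N x 3 spatial positions (used by spatial null models).
    labels
        Optional per-region functional-system name.
    """

    adjacency: np.ndarray
    region_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    coordinates: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        A = _as_square(self.adjacency, "adjacency")
        if not np.allclose(A, A.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("adjacency must be symmetric within 1e-10")
        A = (A + A.T) / 2.0
        if np.any(A < 0):
            raise ValueError("adjacency must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be exactly zero")
        if not is_connected(A):
            raise ValueError("structural connectome graph is disconnected")
        object.__setattr__(self, "adjacency", A)

        n = A.shape[0]
        ids = self.region_ids
        if ids is None:
            ids = _default_ids(n)
        ids = tuple(str(r) for r in ids)
        if len(ids) != n:
            raise ValueError(f"expected {n} region ids, got {len(ids)}")
        object.__setattr__(self, "region_ids", ids)

        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (n, 3):
                raise ValueError(f"coordinates must have shape ({n}, 3)")
            object.__setattr__(self, "coordinates", coords)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != n:
                raise ValueError(f"expected {n} labels, got {len(labels)}")
            object.__setattr__(self, "labels", labels)

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree (row sum) per region."""
        return self.adjacency.sum(axis=1)

    def with_adjacency(self, adjacency: np.ndarray) -> "StructuralConnectome":
        """Same metadata, new weights (used by null-model generators)."""
        return StructuralConnectome(
            adjacency=adjacency,
            region_ids=self.region_ids,
            coordinates=self.coordinates,
            labels=self.labels,
        )


@dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric correlation matrix between regional activity signals."""

    matrix: np.ndarray
    region_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        F = _as_square(self.matrix, "matrix")
        if not np.allclose(F, F.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("functional matrix must be symmetric within 1e-10")
        F = (F + F.T) / 2.0
        off = F[~np.eye(F.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
            raise ValueError("off-diagonal functional connectivity must lie in [-1, 1]")
        object.__setattr__(self, "matrix", F)

        ids = self.region_ids
        if ids is None:
            ids = _default_ids(F.shape[0])
        ids = tuple(str(r) for r in ids)
        if len(ids) != F.shape[0]:
            raise ValueError(f"expected {F.shape[0]} region ids, got {len(ids)}")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def profile(self, i: int, exclude_self: bool = True) -> np.ndarray:
        """Connectivity profile of region ``i`` (column of the matrix)."""
        col = self.matrix[:, i]
        if exclude_self:
            return np.delete(col, i)
        return col.copy()
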