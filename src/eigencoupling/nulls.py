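"""Hypothesis-testing null models and empirical-p machinery.

Three surrogate families are provided: permutation of regions' network
labels, spatial rotation of spherical coordinates with re-matching ("spin"
permutations), and structural rewiring that preserves the binary degree
sequence (edge swaps carrying weights, or a fresh degree-matched topology
with the weight multiset reassigned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .connectome import StructuralConnectome, is_connected
from .coupling import CouplingMap

__all__ = [
    "NullEnsemble",
    "label_permutation_test",
    "spin_permutation",
    "rewire_preserving_degree",
    "degree_preserving_spatial_null",
    "empirical_p",
    "fdr_bh",
    "z_from_null",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullEnsemble:
    """Replicate statistic values from one null-model family."""

    kind: str
    samples: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.size < 1:
            raise ValueError("null ensemble needs at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("null samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.shape[0]


def empirical_p(observed: float, ensemble: NullEnsemble, side: str = "greater") -> dict:
    """Permutation p-value with the +1 small-sample correction.

    ``p = (1 + #{null at least as extreme}) / (1 + n)``; the raw proportion
    (without the correction) is also returned so that results can be stated
    in the "P < 1/n" style when no null sample reaches the observed value.
    Two-sided p doubles the smaller tail, capped at 1.
    """
    samples = ensemble.samples
    n = ensemble.n
    n_ge = int(np.sum(samples >= observed))
    n_le = int(np.sum(samples <= observed))
    if side == "greater":
        count = n_ge
    elif side == "less":
        count = n_le
    elif side == "two_sided":
        p_g = (1 + n_ge) / (1 + n)
        p_l = (1 + n_le) / (1 + n)
        return {
            "p": min(1.0, 2.0 * min(p_g, p_l)),
            "raw_proportion": min(n_ge, n_le) / n * 2.0,
            "floor": 1.0 / (1 + n),
            "n": n,
        }
    else:
        raise ValueError("side must be 'greater', 'less', or 'two_sided'")
    return {
        "p": (1 + count) / (1 + n),
        "raw_proportion": count / n,
        "floor": 1.0 / (1 + n),
        "n": n,
    }


def z_from_null(observed: float, ensemble: NullEnsemble) -> float:
    """Standardize an observed statistic against its null distribution."""
    sd = ensemble.samples.std(ddof=1) if ensemble.n > 1 else 0.0
    if sd == 0:
        raise ValueError("null distribution has zero variance")
    return float((observed - ensemble.samples.mean()) / sd)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection mask.

    Kept as an explicit implementation (the step-up with cumulative-minimum
    monotonicity) so it can be cross-checked against library routines.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def label_permutation_test(
    coupling: CouplingMap,
    labels,
    n: int = 10000,
    seed: int | None = None,
    side: str = "two_sided",
    q: float = 0.05,
):
    """Network-specific mean coupling against label-shuffling nulls.

    Permutes regions' network assignments ``n`` times, recomputing each
    network's mean R per permutation. Returns a table (one row per network)
    of observed mean, empirical p (side as requested), z score, and
    FDR-adjusted p across networks.
    """
    import pandas as pd

    if n < 100:
        raise ValueError("n must be >= 100")
    labels = np.asarray([str(x) for x in labels])
    R = coupling.R
    if labels.size != R.size:
        raise ValueError("labels and coupling map lengths differ")
    networks = sorted(set(labels))
    members = {net: np.flatnonzero(labels == net) for net in networks}
    for net, idx in members.items():
        if idx.size == 0:
            raise ValueError(f"network {net!r} has no members")

    rng = np.random.default_rng(seed)
    observed = {net: R[idx].mean() for net, idx in members.items()}
    null = {net: np.empty(n) for net in networks}
    for rep in range(n):
        perm = rng.permutation(R.size)
        Rp = R[perm]
        for net, idx in members.items():
            null[net][rep] = Rp[idx].mean()

    rows = []
    for net in networks:
        ens = NullEnsemble(kind="label_perm", samples=null[net], seed=seed)
        res = empirical_p(observed[net], ens, side=side)
        sd = null[net].std(ddof=1)
        z = (observed[net] - null[net].mean()) / sd if sd > 0 else 0.0
        rows.append({
            "network": net,
            "n_members": members[net].size,
            "mean_R": observed[net],
            "p": res["p"],
            "raw_proportion": res["raw_proportion"],
            "z": z,
        })
    table = pd.DataFrame(rows).set_index("network")
    adjusted, reject = fdr_bh(table["p"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table["reject"] = reject
    return table


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation from the QR decomposition of a Gaussian matrix."""
    M = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _greedy_match(dist: np.ndarray) -> np.ndarray:
    """Row-sequential greedy nearest-neighbor one-to-one matching."""
    n = dist.shape[0]
    perm = np.empty(n, dtype=int)
    available = np.ones(n, dtype=bool)
    work = dist.copy()
    for i in range(n):
        masked = np.where(available, work[i], np.inf)
        j = int(np.argmin(masked))
        perm[i] = j
        available[j] = False
    return perm


def spin_permutation(
    coordinates: np.ndarray,
    n: int,
    seed: int | None = None,
    method: str = "greedy",
) -> np.ndarray:
    """Spatial-autocorrelation-preserving permutations by random rotation.

    Each replicate draws a uniform 3-D rotation of the (sphere-projected)
    coordinates and reassigns every original region to its nearest rotated
    region one-to-one. ``method='exact'`` solves the optimal assignment
    instead of greedy matching (intended for N <= 500).

    Returns an ``n x N`` array; row r is a permutation p such that
    ``map[p]`` is the r-th surrogate of a regional map.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be N x 3")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        raise ValueError("coordinates contain the origin; cannot project to sphere")
    if np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    unit = coords / norms[:, None]

    rng = np.random.default_rng(seed)
    perms = np.empty((n, coords.shape[0]), dtype=int)
    for r in range(n):
        rot = unit @ _random_rotation(rng).T
        dist = cdist(unit, rot)
        if method == "greedy":
            perms[r] = _greedy_match(dist)
        elif method == "exact":
            _, perms[r] = linear_sum_assignment(dist)
        else:
            raise ValueError("method must be 'greedy' or 'exact'")
    return perms


def _edge_list(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(A.shape[0], k=1)
    mask = A[iu] > 0
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    weights = A[iu][mask]
    return edges, weights


def _adjacency_from_edges(n: int, edges: np.ndarray, weights: np.ndarray) -> np.ndarray:
    A = np.zeros((n, n))
    A[edges[:, 0], edges[:, 1]] = weights
    return A + A.T


def rewire_preserving_degree(
    sc: StructuralConnectome,
    n_swaps: int | None = None,
    seed: int | None = None,
    max_attempts_factor: int = 10,
    max_connect_retries: int = 20,
) -> StructuralConnectome:
    """Maslov-Sneppen double-edge swaps carrying weights with the edges.

    Binary degree sequence, edge count, and the weight multiset are
    conserved exactly; swaps creating self-loops or multi-edges are
    rejected. If the result is disconnected the whole rewiring is resampled
    (up to ``max_connect_retries`` times, logged).
    """
    edges0, weights0 = _edge_list(sc.adjacency)
    n_edges = edges0.shape[0]
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = max_attempts_factor * n_edges
    rng = np.random.default_rng(seed)
    n = sc.n_regions

    for retry in range(max_connect_retries):
        edges = edges0.copy()
        present = set(map(tuple, edges))
        swaps_done = 0
        attempts = 0
        max_attempts = max_attempts_factor * max(n_swaps, n_edges)
        while swaps_done < n_swaps and attempts < max_attempts:
            attempts += 1
            e1, e2 = rng.choice(n_edges, size=2, replace=False)
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.random() < 0.5:
                c, d = d, c
            # propose (a,d) and (c,b)
            if len({a, b, c, d}) < 4:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in present or new2 in present:
                continue
            present.discard((min(a, b), max(a, b)))
            present.discard(tuple(sorted((edges[e2][0], edges[e2][1]))))
            present.add(new1)
            present.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps_done += 1
        A = _adjacency_from_edges(n, edges, weights0)
        if is_connected(A):
            if retry:
                logger.info("rewire_preserving_degree: connected after %d resamples", retry)
            return sc.with_adjacency(A)
    raise ValueError(
        f"swap budget exhausted without a connected result after "
        f"{max_connect_retries} resamples"
    )


def degree_preserving_spatial_null(
    sc: StructuralConnectome,
    seed: int | None = None,
    max_connect_retries: int = 20,
) -> StructuralConnectome:
    """Surrogate keeping only the degree sequence and spatial embedding.

    A fresh binary topology matching the degree sequence is constructed
    (graphical realization followed by seeded double-edge-swap
    randomization), the original weight multiset is randomly reassigned to
    the new edges, and the original coordinates are retained.
    """
    A = sc.adjacency
    degree_seq = (A > 0).sum(axis=1).astype(int).tolist()
    if not nx.is_graphical(degree_seq):
        raise ValueError("degree sequence is not graphical")
    _, weights0 = _edge_list(A)
    n = sc.n_regions
    n_edges = weights0.size
    rng = np.random.default_rng(seed)

    for retry in range(max_connect_retries):
        G = nx.havel_hakimi_graph(degree_seq)
        nswap = 10 * n_edges
        try:
            nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap,
                                seed=int(rng.integers(0, 2**31 - 1)))
        except nx.NetworkXError:
            pass  # fewer swaps than requested: topology is still degree-matched
        if nx.is_connected(G):
            edges = np.array(sorted(tuple(sorted(e)) for e in G.edges()))
            weights = rng.permutation(weights0)
            return sc.with_adjacency(_adjacency_from_edges(n, edges, weights))
    raise ValueError("could not realize a connected degree-matched topology")
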