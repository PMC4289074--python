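"""Nonparametric uniform-kernel mode clustering.

Each day is a point in the standardized fire-weather space.  The density
at a point is proportional to the number of points (including itself)
inside a Euclidean ball of radius ``R``.  Every point follows a pointer
to its densest strictly-denser neighbour within ``R``; points with no
such neighbour are density modes, and each mode's basin of attraction is
a cluster.  Clusters smaller than the minimum cluster size ``CK`` are
dissolved (smallest first) and their members reassigned to the cluster
of the nearest remaining labeled point.

All tie-breaks use the lowest row index, so the procedure is fully
deterministic.  Distances are computed on the standardized variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_CHUNK = 512  # rows per block when scanning the pairwise distance matrix


@dataclass
class ClusterModel:
    """Result of one mode-clustering run.

    labels : per-day cluster id in 1..k, or 0 = unassigned
    modes  : cluster id -> row index of the mode day
    """

    R: float
    CK: int
    labels: np.ndarray
    densities: np.ndarray
    modes: dict[int, int]
    k: int
    dissolved: int


def pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    """Full squared Euclidean distance matrix (symmetric, zero diagonal).

    Computed once per feature matrix and shared across a radius sweep.
    """
    X = np.asarray(X, float)
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def _ball_volume(d: int, R: float) -> float:
    return math.pi ** (d / 2) / math.gamma(d / 2 + 1) * R**d


def uniform_kernel_density(
    X: np.ndarray, R: float, d2: np.ndarray | None = None
) -> np.ndarray:
    """Uniform-kernel density estimate: m(i) / (n · V_R) with m(i) the
    neighbour count within radius R, the point itself included."""
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if R <= 0:
        raise ValueError("R must be > 0")
    n, d = X.shape
    if d2 is None:
        d2 = pairwise_sq_dists(X)
    m = np.count_nonzero(d2 <= R * R, axis=1)
    return m / (n * _ball_volume(d, R))


def assign_modes(
    X: np.ndarray,
    densities: np.ndarray,
    R: float,
    d2: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Point each observation at the neighbour within R that ascends the
    density estimate, and label the basins.

    A neighbour j qualifies when its density strictly exceeds i's, or
    equals it with j at a lower row index (the plateau rule: equal-count
    neighbourhoods chain to one representative instead of each becoming
    a mode).  Among qualifying neighbours the one with maximal density
    wins, ties by lowest row index.  Chains are finite because
    (density, -row index) strictly increases along them.

    Returns ``(labels, modes)`` with labels 1..k and modes keyed by
    cluster id, ids assigned by ascending mode row index.
    """
    X = np.asarray(X, float)
    dens = np.asarray(densities, float)
    n = X.shape[0]
    if d2 is None:
        d2 = pairwise_sq_dists(X)
    R2 = R * R
    idx = np.arange(n)

    parent = np.full(n, -1, dtype=np.int64)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        block = d2[lo:hi]
        own = dens[lo:hi, None]
        qualifies = (block <= R2) & (
            (dens[None, :] > own)
            | ((dens[None, :] == own) & (idx[None, :] < idx[lo:hi, None]))
        )
        cand = np.where(qualifies, dens[None, :], -np.inf)
        best = cand.argmax(axis=1)  # first occurrence = lowest index
        has = cand[np.arange(hi - lo), best] > -np.inf
        parent[lo:hi] = np.where(has, best, -1)

    # resolve chains to roots by pointer jumping (chains are finite:
    # density strictly increases along them; modes are self-loops)
    final = np.where(parent >= 0, parent, np.arange(n))
    while True:
        nxt = final[final]
        if np.array_equal(nxt, final):
            break
        final = nxt

    mode_rows = np.unique(final)
    modes = {cid: int(r) for cid, r in enumerate(np.sort(mode_rows), start=1)}
    row_to_id = {r: cid for cid, r in modes.items()}
    labels = np.array([row_to_id[r] for r in final], dtype=np.int64)
    return labels, modes


def enforce_min_cluster_size(
    X: np.ndarray,
    labels: np.ndarray,
    modes: dict[int, int],
    CK: int,
    d2: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[int, int], int]:
    """Dissolve clusters with fewer than CK members, smallest first
    (ties by lower mode row index); members join the cluster of their
    nearest remaining labeled point, or become unassigned (0) if no
    other cluster exists.  Iterates until all retained clusters have
    >= CK members or none remain.

    Returns ``(labels, modes, n_dissolved)`` with ids renumbered 1..k
    by ascending mode row index.
    """
    X = np.asarray(X, float)
    if d2 is None:
        d2 = pairwise_sq_dists(X)
    labels = labels.copy()
    modes = dict(modes)
    dissolved = 0

    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = [(c, i) for i, c in zip(ids, counts) if c < CK]
        if not small or len(ids) == 0:
            break
        # smallest first; ties by lower mode row index
        victim = min(small, key=lambda t: (t[0], modes[int(t[1])]))[1]
        victim = int(victim)
        members = np.flatnonzero(labels == victim)
        others = np.flatnonzero((labels > 0) & (labels != victim))
        if others.size == 0:
            labels[members] = 0
        else:
            nearest = others[d2[np.ix_(members, others)].argmin(axis=1)]
            labels[members] = labels[nearest]
        modes.pop(victim)
        dissolved += 1

    keep = sorted(modes, key=lambda c: modes[c])
    remap = {old: new for new, old in enumerate(keep, start=1)}
    new_labels = np.array([remap.get(int(l), 0) for l in labels], dtype=np.int64)
    new_modes = {remap[c]: modes[c] for c in keep}
    return new_labels, new_modes, dissolved


def cluster(
    X: np.ndarray, R: float, CK: int = 50, d2: np.ndarray | None = None
) -> ClusterModel:
    """Full mode-clustering run: density estimate, mode assignment, and
    minimum-cluster-size enforcement.  Deterministic for fixed input."""
    X = np.asarray(X, float)
    if d2 is None:
        d2 = pairwise_sq_dists(X)
    dens = uniform_kernel_density(X, R, d2=d2)
    labels, modes = assign_modes(X, dens, R, d2=d2)
    labels, modes, dissolved = enforce_min_cluster_size(X, labels, modes, CK, d2=d2)
    return ClusterModel(
        R=float(R),
        CK=int(CK),
        labels=labels,
        densities=dens,
        modes=modes,
        k=len(modes),
        dissolved=dissolved,
    )
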