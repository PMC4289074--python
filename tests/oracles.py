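"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain loops from the definitions, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def brute_density(X: np.ndarray, R: float) -> np.ndarray:
    """O(n²) uniform-kernel density from the definition."""
    n, d = X.shape
    vol = math.pi ** (d / 2) / math.gamma(d / 2 + 1) * R**d
    out = np.empty(n)
    for i in range(n):
        m = 0
        for j in range(n):
            if np.linalg.norm(X[i] - X[j]) <= R:
                m += 1
        out[i] = m / (n * vol)
    return out


def brute_mode_labels(X: np.ndarray, dens: np.ndarray, R: float):
    """Density-ascent hill climbing with the plateau rule, pure python:
    follow the maximal-density neighbour that is strictly denser or
    equally dense at a lower row index; ties by lowest row index."""
    n = X.shape[0]
    parent = [-1] * n
    for i in range(n):
        candidates = [
            j for j in range(n)
            if j != i
            and np.linalg.norm(X[i] - X[j]) <= R
            and (dens[j] > dens[i] or (dens[j] == dens[i] and j < i))
        ]
        if candidates:
            parent[i] = min(candidates, key=lambda j: (-dens[j], j))
    roots = []
    for i in range(n):
        cur = i
        while parent[cur] != -1:
            cur = parent[cur]
        roots.append(cur)
    mode_rows = sorted(set(roots))
    ids = {r: c for c, r in enumerate(mode_rows, start=1)}
    return np.array([ids[r] for r in roots]), {c: r for r, c in ids.items()}


def brute_enforce_ck(X: np.ndarray, labels: np.ndarray, modes: dict, CK: int):
    """Smallest-first dissolution with nearest-labeled-neighbour
    reassignment, pure python."""
    labels = labels.copy()
    modes = dict(modes)
    while True:
        sizes = {c: int((labels == c).sum()) for c in modes}
        small = [c for c, s in sizes.items() if s < CK]
        if not small or not modes:
            break
        victim = min(small, key=lambda c: (sizes[c], modes[c]))
        members = np.flatnonzero(labels == victim)
        others = np.flatnonzero((labels > 0) & (labels != victim))
        for i in members:
            if others.size == 0:
                labels[i] = 0
            else:
                best = min(others, key=lambda j: np.linalg.norm(X[i] - X[j]))
                labels[i] = labels[best]
        del modes[victim]
    keep = sorted(modes, key=lambda c: modes[c])
    remap = {old: new for new, old in enumerate(keep, start=1)}
    return (
        np.array([remap.get(int(l), 0) for l in labels]),
        {remap[c]: modes[c] for c in keep},
    )


def brute_cluster(X: np.ndarray, R: float, CK: int):
    dens = brute_density(X, R)
    labels, modes = brute_mode_labels(X, dens, R)
    return brute_enforce_ck(X, labels, modes, CK)


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition up to label renaming (0 = unassigned matches 0)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == 0, b == 0):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == 0:
            continue
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
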