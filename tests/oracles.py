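"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, normal
equations, literal step-up rule) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def exhaustive_shortest_path(W: np.ndarray, i: int, j: int) -> float:
    """Minimum 1/w path length over every simple path from i to j."""
    n = W.shape[0]
    best = np.inf
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            length = 0.0
            for a, b in zip(path, path[1:]):
                if W[a, b] <= 0:
                    length = np.inf
                    break
                length += 1.0 / W[a, b]
            best = min(best, length)
    return best


def exhaustive_global_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = exhaustive_shortest_path(W, i, j)
            if np.isfinite(d) and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def exhaustive_local_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nb = [k for k in range(n) if W[i, k] > 0]
        if len(nb) < 2:
            continue
        total += exhaustive_global_efficiency(W[np.ix_(nb, nb)])
    return total / n if n else 0.0


def exhaustive_node_strength(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i:
                out[i] += W[i, j]
    return out


def stepup_bh(pvals, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg: largest k with p_(k) <= k*q/m is the cut."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def normal_equation_residuals(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS residuals through the explicit pseudo-inverse."""
    return Y - X @ (np.linalg.pinv(X.T @ X) @ X.T @ Y)


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 6) -> np.ndarray:
    """Random symmetric nonnegative adjacency with ~50% edge density."""
    n = int(rng.integers(2, max_nodes + 1))
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < 0.5
    W[iu[mask], ju[mask]] = rng.uniform(0.05, 1.0, int(mask.sum()))
    W += W.T
    return W
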