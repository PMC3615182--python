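"""Interregional correlation matrices and cost-thresholded weighted networks.

Structural connectivity between two regions is the Pearson correlation of
their residualized volumes across the subjects of a group.  A correlation
matrix is converted to a weighted undirected graph by a cost threshold
``t`` in (0, 1): the ``round(t * N(N-1)/2)`` strongest pairs by ``|r|`` are
kept as edges with weight ``|r|``, which fixes the same wiring cost for every
network regardless of group or scan.  Thresholds are nested: the edges at
cost ``t`` are a subset of those at any larger cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import region_labels


def correlation_matrix(corrected: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Pearson correlation between region columns of a cRGMV matrix.

    Requires >= 3 rows (subjects) and no constant column; the error for a
    constant column names the region.
    """
    X = np.asarray(corrected, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError(f"need a 2-D matrix with >= 3 subjects, got shape {X.shape}")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        j = int(np.argmax(constant))
        name = labels[j] if labels else f"column {j}"
        raise ValueError(f"constant region {name}: correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    return r


def n_edges_at_cost(n_nodes: int, t: float) -> int:
    """Edge count at cost ``t``: round(t * n(n-1)/2), half rounded up."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"cost threshold must be in (0, 1), got {t}")
    k = int(np.floor(t * n_nodes * (n_nodes - 1) / 2 + 0.5))
    if k < 1:
        raise ValueError(f"cost {t} yields zero edges on {n_nodes} nodes")
    return k


def _pair_order(r: np.ndarray):
    """Upper-triangle pairs ranked by |r| descending, ties by (i, j) ascending."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = np.abs(r[iu, ju])
    order = np.lexsort((ju, iu, -weights))
    return iu, ju, weights, order


@dataclass
class WeightedNetwork:
    """Cost-thresholded weighted undirected graph over the atlas regions."""

    cost: float
    r_threshold: float  # smallest retained |r|
    adjacency: np.ndarray  # symmetric, zero diagonal, weights = |r|
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


def threshold_by_cost(
    r: np.ndarray, t: float, labels: list[str] | None = None
) -> WeightedNetwork:
    """Keep the top ``round(t*N(N-1)/2)`` pairs by ``|r|`` as edges of weight ``|r|``."""
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if r.shape != (n, n) or not np.allclose(r, r.T, atol=1e-12):
        raise ValueError("correlation matrix must be square and symmetric")
    k = n_edges_at_cost(n, t)
    iu, ju, weights, order = _pair_order(r)
    kept = order[:k]
    adj = np.zeros((n, n))
    adj[iu[kept], ju[kept]] = weights[kept]
    adj += adj.T
    if labels is None:
        labels = region_labels(n) if n % 2 == 0 and n <= 90 else [str(i) for i in range(n)]
    return WeightedNetwork(
        cost=float(t),
        r_threshold=float(weights[kept[-1]]),
        adjacency=adj,
        labels=list(labels),
    )


def edge_table(net: WeightedNetwork, min_costs: np.ndarray | None = None) -> pd.DataFrame:
    """Edge list (node labels + weight); optional per-edge smallest grid cost."""
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    df = pd.DataFrame(
        {
            "node_i": [net.labels[i] for i in iu],
            "node_j": [net.labels[j] for j in ju],
            "weight": net.adjacency[iu, ju],
        }
    )
    if min_costs is not None:
        df["min_cost"] = min_costs
    return df.sort_values(["node_i", "node_j"], kind="mergesort").reset_index(drop=True)


def write_correlation_matrix(r: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(r, index=labels, columns=labels).to_csv(path)
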