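"""Degree- and weight-distribution-preserving null networks.

The null model rewires the binary topology by double-edge swaps
(Maslov-Sneppen; default 10 attempts per edge, rejecting swaps that would
create self-loops or multi-edges) and then randomly permutes the original
weight multiset onto the rewired edges.  The degree sequence and the weight
multiset are therefore preserved exactly; node strength is not.

An ensemble of such nulls supports the economical small-world assessment: a
network qualifies when its local efficiency is clearly above the null mean
while its global efficiency stays close to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metrics import global_efficiency, local_efficiency
from .network import WeightedNetwork

logger = logging.getLogger(__name__)


def _as_rng(rng=None, seed=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def rewire_random(
    net: WeightedNetwork | np.ndarray,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> WeightedNetwork | np.ndarray:
    """Topology-randomized copy preserving degrees and the weight multiset."""
    rng = _as_rng(rng, seed)
    is_net = isinstance(net, WeightedNetwork)
    W = net.adjacency if is_net else np.asarray(net, dtype=float)
    n = W.shape[0]
    iu, ju = np.nonzero(np.triu(W, k=1))
    m = iu.size
    if m < 2:
        raise ValueError(f"need at least 2 edges to rewire, got {m}")
    weights = W[iu, ju]
    edges = np.column_stack([iu, ju])
    present = W > 0

    attempts = n_swaps_per_edge * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    successes = 0
    for (e1, e2), fl in zip(pick, flip):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if fl:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if present[a, d] or present[c, b]:
            continue
        present[a, b] = present[b, a] = False
        present[c, d] = present[d, c] = False
        present[a, d] = present[d, a] = True
        present[c, b] = present[b, c] = True
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        successes += 1
    if successes == 0:
        logger.warning("no valid double-edge swap found; returning weight-permuted copy")

    new_w = rng.permutation(weights)
    out = np.zeros((n, n))
    out[edges[:, 0], edges[:, 1]] = new_w
    out += out.T
    if is_net:
        return WeightedNetwork(
            cost=net.cost, r_threshold=float("nan"), adjacency=out, labels=list(net.labels)
        )
    return out


@dataclass
class NullEnsemble:
    """Per-null GE/LE of rewired surrogates of one source network."""

    source_id: str
    n_null: int
    ge: np.ndarray
    le: np.ndarray

    @property
    def ge_mean(self) -> float:
        return float(self.ge.mean())

    @property
    def ge_sd(self) -> float:
        return float(self.ge.std(ddof=1)) if self.n_null > 1 else 0.0

    @property
    def le_mean(self) -> float:
        return float(self.le.mean())

    @property
    def le_sd(self) -> float:
        return float(self.le.std(ddof=1)) if self.n_null > 1 else 0.0


def null_ensemble(
    net: WeightedNetwork | np.ndarray,
    n_null: int = 1000,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    source_id: str = "",
) -> NullEnsemble:
    """GE/LE over ``n_null`` independent rewired surrogates (seed-reproducible)."""
    if n_null < 1:
        raise ValueError(f"n_null must be positive, got {n_null}")
    rng = _as_rng(rng, seed)
    ge = np.empty(n_null)
    le = np.empty(n_null)
    for k in range(n_null):
        surrogate = rewire_random(net, n_swaps_per_edge=n_swaps_per_edge, rng=rng)
        ge[k] = global_efficiency(surrogate)
        le[k] = local_efficiency(surrogate)
    return NullEnsemble(source_id=source_id, n_null=n_null, ge=ge, le=le)


@dataclass
class SmallWorldResult:
    ge_ratio: float  # GE_real / mean GE_null
    le_ratio: float  # LE_real / mean LE_null
    is_small_world: bool


def small_world_assessment(
    net: WeightedNetwork | np.ndarray,
    ensemble: NullEnsemble,
    margin_le: float = 0.1,
    margin_ge: float = 0.2,
) -> SmallWorldResult:
    """Economical small-world verdict against a matched null ensemble.

    True iff ``LE_real/LE_null > 1 + margin_le`` (much higher local efficiency)
    and ``GE_real/GE_null`` within ``1 +/- margin_ge`` (similar global
    efficiency).  The margins are reporting conventions, not fitted
    quantities.
    """
    if ensemble.n_null < 1:
        raise ValueError("empty null ensemble")
    if ensemble.ge_mean == 0 or ensemble.le_mean == 0:
        raise ValueError("null ensemble with zero mean efficiency: ratios undefined")
    ge_ratio = global_efficiency(net) / ensemble.ge_mean
    le_ratio = local_efficiency(net) / ensemble.le_mean
    verdict = (le_ratio > 1 + margin_le) and (1 - margin_ge <= ge_ratio <= 1 + margin_ge)
    return SmallWorldResult(ge_ratio=float(ge_ratio), le_ratio=float(le_ratio),
                            is_small_world=bool(verdict))
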