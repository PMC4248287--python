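"""Synthetic weighted networks with known planted structure.

Every analysis path in this package is testable without external data:

* :func:`er_weighted` -- Erdős–Rényi topology with i.i.d. link weights,
  the structureless baseline on which nothing should be detected;
* :func:`plant_topological_club` -- a designated node set linked among
  itself at an elevated probability, weights blind to membership: a
  club built purely by link placement;
* :func:`plant_weighted_club` -- a fixed Erdős–Rényi topology whose
  highest-degree nodes have their mutual link weights multiplied by a
  boost factor: a club built purely by weight allocation.

The two planting mechanisms dissociate what the two control families
measure: weighted planting should move only the curve normalized by
topology-preserving controls, topological planting the curve normalized
by degree-preserving controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .graph import WeightedNetwork, degree_array

__all__ = [
    "Uniform",
    "LogNormal",
    "Constant",
    "WeightLaw",
    "PlantSpec",
    "er_weighted",
    "plant_topological_club",
    "plant_weighted_club",
]


@dataclass(frozen=True)
class Uniform:
    """Weights uniform on ``(low, high)``; defaults to (0, 1)."""

    low: float = 0.0
    high: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if not self.high > self.low >= 0:
            raise ValueError("need 0 <= low < high")
        w = rng.uniform(self.low, self.high, size)
        # weights must be strictly positive; the boundary has measure 0
        # but resample defensively
        while np.any(w <= 0):
            w[w <= 0] = rng.uniform(self.low, self.high, int(np.sum(w <= 0)))
        return w


@dataclass(frozen=True)
class LogNormal:
    """Heavy-tailed weights, log-normal with log-mean ``mu`` and log-sd ``sigma``."""

    mu: float = 0.0
    sigma: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        return rng.lognormal(self.mu, self.sigma, size)


@dataclass(frozen=True)
class Constant:
    """Every link carries weight ``value`` (1 gives an unweighted network)."""

    value: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.value <= 0:
            raise ValueError("constant weight must be positive")
        return np.full(size, float(self.value))


WeightLaw = Union[Uniform, LogNormal, Constant]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters for planted-club generation.

    ``baseline_p`` is the background link probability, ``club_p`` the
    intra-club link probability used by topological planting, ``boost``
    the multiplicative intra-club weight factor used by weighted
    planting.
    """

    n_nodes: int = 100
    club_size: int = 10
    baseline_p: float = 0.1
    club_p: float = 0.6
    weight_law: WeightLaw = field(default_factory=Uniform)
    boost: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.club_size <= self.n_nodes:
            raise ValueError("need 0 < club_size <= n_nodes")
        if not (0 < self.baseline_p <= 1 and 0 < self.club_p <= 1):
            raise ValueError("probabilities must be in (0, 1]")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")


def _node_labels(n: int) -> tuple[str, ...]:
    return tuple(f"v{i}" for i in range(n))


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def er_weighted(
    n_nodes: int, p: float, weight_law: WeightLaw | None = None, seed: int = 0
) -> WeightedNetwork:
    """Erdős–Rényi G(n, p) with i.i.d. link weights.

    Each unordered pair is linked independently with probability ``p``;
    linked pairs draw weights from ``weight_law`` (uniform(0, 1) by
    default).  Deterministic under ``seed``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if weight_law is None:
        weight_law = Uniform()
    rng = np.random.default_rng(int(seed))
    iu, ju = _pair_indices(n_nodes)
    mask = rng.random(iu.size) < p
    edges = np.column_stack([iu[mask], ju[mask]])
    w = weight_law.sample(rng, int(mask.sum()))
    return WeightedNetwork(_node_labels(n_nodes), edges, w)


def plant_topological_club(spec: PlantSpec) -> tuple[WeightedNetwork, frozenset[str]]:
    """ER backbone with extra intra-club links; weights blind to the club.

    The first ``club_size`` nodes are the planted set; pairs inside it
    are linked with probability ``club_p``, all other pairs with
    ``baseline_p``.  Weights are drawn i.i.d. regardless of membership,
    so any detectable club is purely topological.  Returns the network
    and the planted node set.
    """
    rng = np.random.default_rng(int(spec.seed))
    n, k = spec.n_nodes, spec.club_size
    iu, ju = _pair_indices(n)
    p_pair = np.where((iu < k) & (ju < k), spec.club_p, spec.baseline_p)
    mask = rng.random(iu.size) < p_pair
    edges = np.column_stack([iu[mask], ju[mask]])
    w = spec.weight_law.sample(rng, int(mask.sum()))
    labels = _node_labels(n)
    return WeightedNetwork(labels, edges, w), frozenset(labels[:k])


def plant_weighted_club(spec: PlantSpec) -> tuple[WeightedNetwork, frozenset[str]]:
    """Boost intra-club weights on a fixed ER topology.

    A single ER topology is drawn at ``baseline_p``; the club is the
    ``club_size`` highest-degree nodes of that topology (ties broken by
    node index), so that degree-based richness can find it.  Weights of
    links between club members are multiplied by ``boost``; the link
    set is untouched, so any detectable club is purely weighted.
    """
    base = er_weighted(spec.n_nodes, spec.baseline_p, spec.weight_law, spec.seed)
    deg = degree_array(base)
    order = np.argsort(-deg, kind="stable")
    club_idx = order[: spec.club_size]
    if np.any(deg[club_idx] == 0):
        raise ValueError(
            "fewer connected nodes than club_size; cannot anchor the club "
            "to high-degree nodes"
        )
    in_club = np.zeros(spec.n_nodes, dtype=bool)
    in_club[club_idx] = True
    intra = in_club[base.edges[:, 0]] & in_club[base.edges[:, 1]]
    w = base.weights.copy()
    w[intra] *= spec.boost
    planted = frozenset(base.nodes[i] for i in club_idx)
    return base.with_weights(w), planted
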