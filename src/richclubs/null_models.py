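"""Randomized control networks and null ensembles.

Three families of controls, each preserving a different structure of
the observed network:

``topological``
    Degree-preserving rewiring of the topology; weights discarded (set
    to 1).  Detects clubs built by preferential *link placement*.
``weighted``
    Exact topology, weights replaced by decorrelated values that
    closely preserve each node's strength.  Detects clubs built by
    preferential *weight allocation* on a fixed topology.
``mixed``
    Both: rewired topology carrying decorrelated weights rescaled
    toward the original strength sequence.  Conflates the two effects
    by construction, which is sometimes exactly what is wanted.

Degree-preserving rewiring is delegated to igraph's C implementation of
Maslov-Sneppen double-edge swaps (10 x link-count swap attempts,
rejecting swaps that would create self-loops or duplicate links).
Starting from the observed network guarantees the degree sequence is
realizable and preserved exactly.

The weighted control permutes the weight multiset over the fixed link
set and then applies symmetric iterative proportional fitting: each
weight is repeatedly multiplied by the geometric mean of its two
endpoints' target/current strength ratios until every node's strength
is within a relative tolerance of its original value.  A positive
solution always exists on the original topology (the original weights
are one), so convergence failures only signal pathological inputs.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import igraph as ig
import numpy as np

from .graph import RichnessSpec, WeightedNetwork, richness_array, strength_array

__all__ = [
    "ControlKind",
    "CONTROL_KINDS",
    "NullEnsemble",
    "ConvergenceError",
    "topological_control",
    "weighted_control",
    "mixed_control",
    "directed_weight_shuffle",
    "build_ensemble",
    "child_seeds",
]

ControlKind = Literal["topological", "weighted", "mixed"]
CONTROL_KINDS: tuple[str, ...] = ("topological", "weighted", "mixed")

#: swap attempts per link for degree-preserving rewiring
SWAPS_PER_LINK = 10
#: default relative tolerance on per-node strength preservation
DEFAULT_TOL = 1e-3
#: iteration cap for the strength-rescaling fixed point
MAX_IPF_ITER = 10_000


class ConvergenceError(RuntimeError):
    """Strength rescaling failed to reach tolerance within the iteration cap."""


@dataclass(frozen=True)
class NullEnsemble:
    """C_rand samples from repeated randomized controls.

    ``c_samples`` has shape ``(n_rand, n_thresholds)``: one weighted
    connectedness value per control per richness threshold.
    """

    kind: str
    n_rand: int
    thresholds: np.ndarray
    c_samples: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in CONTROL_KINDS:
            raise ValueError(f"kind must be one of {CONTROL_KINDS}")
        c = np.asarray(self.c_samples, dtype=np.float64)
        t = np.asarray(self.thresholds, dtype=np.float64)
        if c.shape != (self.n_rand, t.size):
            raise ValueError("c_samples must be (n_rand, n_thresholds)")
        if c.size and c.min() < 0:
            raise ValueError("C_rand values must be nonnegative")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "c_samples", c)

    def c_rand_mean(self) -> np.ndarray:
        return self.c_samples.mean(axis=0)


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a parent seed.

    Uses numpy's SeedSequence mixing so ensembles are reproducible and
    child streams are statistically independent.
    """
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


def topological_control(
    net: WeightedNetwork, seed: int, swaps_per_link: int = SWAPS_PER_LINK
) -> WeightedNetwork:
    """Degree-preserving rewiring; all weights set to 1.

    The degree sequence of the output equals the input's exactly.  The
    complete graph (and any other unique realization of its degree
    sequence) is returned unchanged up to link order.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring requires at least 2 links")
    g = ig.Graph(n=net.n_nodes, edges=[tuple(e) for e in net.edges])
    ig.set_random_number_generator(_random.Random(int(seed)))
    g.rewire(n=swaps_per_link * net.n_edges, mode="simple")
    edges = np.array(g.get_edgelist(), dtype=np.int64)
    return WeightedNetwork(net.nodes, edges, np.ones(net.n_edges))


def _fit_strengths(
    edges: np.ndarray,
    n_nodes: int,
    init_w: np.ndarray,
    target: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Symmetric IPF: rescale weights until strengths match ``target``."""
    w = init_w.astype(np.float64).copy()
    idx = edges.ravel(order="F")
    active = target > 0
    for _ in range(max_iter):
        s = np.bincount(idx, weights=np.concatenate([w, w]), minlength=n_nodes)
        dev = np.abs(s[active] - target[active]) / target[active]
        if dev.size == 0 or dev.max() <= tol:
            return w
        ratio = np.ones(n_nodes)
        ok = active & (s > 0)
        ratio[ok] = target[ok] / s[ok]
        w *= np.sqrt(ratio[edges[:, 0]] * ratio[edges[:, 1]])
    s = np.bincount(idx, weights=np.concatenate([w, w]), minlength=n_nodes)
    worst = float(np.max(np.abs(s[active] - target[active]) / target[active]))
    raise ConvergenceError(
        f"strength rescaling did not reach tol={tol} in {max_iter} iterations "
        f"(worst relative deviation {worst:.3g})"
    )


def weighted_control(
    net: WeightedNetwork,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_IPF_ITER,
) -> WeightedNetwork:
    """Topology-preserving weight decorrelation.

    The link set is untouched.  Weights start as a uniformly random
    permutation of the original weight multiset and are then rescaled so
    that every node's strength returns to within relative ``tol`` of
    its original value (total weight is preserved to the same order).
    Rescaled weights are real-valued even for integer inputs; no
    re-rounding is applied.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if net.n_edges == 0:
        return net
    rng = np.random.default_rng(int(seed))
    w0 = net.weights[rng.permutation(net.n_edges)]
    target = strength_array(net)
    w = _fit_strengths(net.edges, net.n_nodes, w0, target, tol, max_iter)
    return net.with_weights(w)


def mixed_control(
    net: WeightedNetwork,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_IPF_ITER,
) -> WeightedNetwork:
    """Rewired topology + decorrelated weights.

    The topology comes from :func:`topological_control`; the original
    weight multiset is permuted onto the new links and rescaled toward
    the original strength sequence.
    """
    s_topo, s_wt = child_seeds(seed, 2)
    topo = topological_control(net, int(s_topo))
    rng = np.random.default_rng(int(s_wt))
    w0 = net.weights[rng.permutation(net.n_edges)]
    target = strength_array(net)
    w = _fit_strengths(topo.edges, net.n_nodes, w0, target, tol, max_iter)
    return topo.with_weights(w)


def directed_weight_shuffle(
    net: WeightedNetwork,
    orientation: Iterable[tuple[str, str]],
    mode: Literal["outgoing", "incoming"] = "outgoing",
    seed: int = 0,
) -> WeightedNetwork:
    """Per-node permutation of outgoing (or incoming) link weights.

    ``orientation`` assigns a direction to every link as ``(source,
    target)`` pairs.  Topology is unchanged; for each node the weights
    of its outgoing (mode ``"outgoing"``) or incoming (``"incoming"``)
    links are permuted among themselves, so every node's out-strength
    (respectively in-strength) -- and the global weight multiset -- are
    preserved exactly.
    """
    if mode not in ("outgoing", "incoming"):
        raise ValueError("mode must be 'outgoing' or 'incoming'")
    index = net.node_index
    # map canonical link -> row position
    row_of = {(int(u), int(v)): k for k, (u, v) in enumerate(net.edges)}
    anchor = np.full(net.n_edges, -1, dtype=np.int64)
    for su, sv in orientation:
        if su not in index or sv not in index:
            raise KeyError(f"orientation names unknown node in ({su!r}, {sv!r})")
        i, j = index[su], index[sv]
        key = (i, j) if i < j else (j, i)
        if key not in row_of:
            raise KeyError(f"orientation names non-existent link ({su!r}, {sv!r})")
        k = row_of[key]
        if anchor[k] != -1:
            raise ValueError(f"link ({su!r}, {sv!r}) oriented more than once")
        anchor[k] = i if mode == "outgoing" else j
    missing = np.nonzero(anchor == -1)[0]
    if missing.size:
        u, v = net.edges[missing[0]]
        raise ValueError(
            f"missing orientation for link ({net.nodes[u]!r}, {net.nodes[v]!r})"
        )
    rng = np.random.default_rng(int(seed))
    w = net.weights.copy()
    for node in range(net.n_nodes):
        rows = np.nonzero(anchor == node)[0]
        if rows.size > 1:
            w[rows] = w[rows[rng.permutation(rows.size)]]
    return net.with_weights(w)


def _club_c_series(
    richness: np.ndarray,
    edges: np.ndarray,
    weights: np.ndarray,
    thresholds: np.ndarray,
) -> np.ndarray:
    """C at each threshold: sum of weights of links with both endpoint
    richness strictly above the threshold (vectorized over thresholds)."""
    if edges.shape[0] == 0:
        return np.zeros(thresholds.size)
    emin = np.minimum(richness[edges[:, 0]], richness[edges[:, 1]])
    order = np.argsort(emin, kind="stable")
    emin_s = emin[order]
    suffix = np.concatenate([np.cumsum(weights[order][::-1])[::-1], [0.0]])
    return suffix[np.searchsorted(emin_s, thresholds, side="right")]


def build_ensemble(
    net: WeightedNetwork,
    kind: str,
    thresholds: Sequence[float],
    spec: RichnessSpec,
    n_rand: int,
    seed: int,
    tol: float = DEFAULT_TOL,
) -> NullEnsemble:
    """Generate ``n_rand`` controls and record C_rand at every threshold.

    Club membership is recomputed from each control's own richness
    values.  For sequence-preserved richness (degree under any control
    here, strength under the weighted control up to ``tol``) this
    yields clubs of the same size as the observed network at every
    threshold, matching the premise that N is constant across controls;
    for other richness parameters recomputation is the only faithful
    reading.

    Note: topological controls carry unit weights, so their C_rand is a
    link count; compare it against the unit-weighted observed network
    (as :func:`richclubs.curves.phi_norm_curve` does).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if kind not in CONTROL_KINDS:
        raise ValueError(f"kind must be one of {CONTROL_KINDS}")
    t = np.asarray(thresholds, dtype=np.float64)
    seeds = child_seeds(seed, n_rand)
    c = np.empty((n_rand, t.size))
    for i, s in enumerate(seeds):
        if kind == "topological":
            ctl = topological_control(net, int(s))
        elif kind == "weighted":
            ctl = weighted_control(net, int(s), tol=tol)
        else:
            ctl = mixed_control(net, int(s), tol=tol)
        r = richness_array(ctl, spec)
        c[i] = _club_c_series(r, ctl.edges, ctl.weights, t)
    return NullEnsemble(kind=kind, n_rand=n_rand, thresholds=t, c_samples=c, seed=int(seed))
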