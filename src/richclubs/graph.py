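"""Weighted undirected networks and node-level richness.

The central container is :class:`WeightedNetwork`: a simple undirected
graph with strictly positive, finite link weights.  Node identifiers are
opaque strings; a dense integer index (the position of a node in
``nodes``) is maintained internally so that all downstream computations
can run on numpy arrays.

Node "richness" is any property by which all nodes can be ranked.  Two
richness parameters are built in -- degree (number of incident links)
and strength (sum of incident link weights) -- and arbitrary custom
values may be supplied via :class:`RichnessSpec`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "RichnessSpec",
    "degree",
    "strength",
    "richness",
    "degree_array",
    "strength_array",
    "richness_array",
]


class NetworkError(ValueError):
    """Raised when input data violates the simple-weighted-graph contract."""


def _canonical_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class WeightedNetwork:
    """Simple undirected graph with positive link weights.

    Parameters
    ----------
    nodes
        Ordered node identifiers.  Position in this tuple is the node's
        dense integer index.
    edges
        Integer array of shape ``(m, 2)`` of node indices, one row per
        undirected link.  Rows are canonicalized to ``u < v`` and sorted
        lexicographically.
    weights
        Float array of shape ``(m,)`` of strictly positive, finite link
        weights, aligned with ``edges``.

    Invariants (enforced at construction): no self-loops, no duplicate
    links, every endpoint a valid index, every weight positive and
    finite.
    """

    nodes: tuple[str, ...]
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        if len(set(nodes)) != len(nodes):
            raise NetworkError("duplicate node identifiers")
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if edges.shape[0] != weights.shape[0]:
            raise NetworkError(
                f"{edges.shape[0]} links but {weights.shape[0]} weights"
            )
        n = len(nodes)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                raise NetworkError("link endpoint outside node range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise NetworkError("self-loops are not allowed")
            # canonicalize: u < v, rows sorted, duplicates rejected
            edges = np.sort(edges, axis=1)
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            weights = weights[order]
            dup = np.all(edges[1:] == edges[:-1], axis=1)
            if np.any(dup):
                i, j = edges[1:][dup][0]
                raise NetworkError(
                    f"duplicate link between {nodes[i]!r} and {nodes[j]!r}"
                )
        if weights.size and not (
            np.all(np.isfinite(weights)) and np.all(weights > 0)
        ):
            raise NetworkError("weights must be strictly positive and finite")
        edges.setflags(write=False)
        weights.setflags(write=False)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "weights", weights)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        records: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        """Build from ``(u, v, weight)`` records.

        Node order is first appearance in the records, followed by any
        ``extra_nodes`` (which lets isolated nodes be represented even
        though they carry no links).
        """
        index: dict[str, int] = {}
        pairs: list[tuple[int, int]] = []
        ws: list[float] = []
        for u, v, w in records:
            for lab in (str(u), str(v)):
                if lab not in index:
                    index[lab] = len(index)
            pairs.append((index[str(u)], index[str(v)]))
            ws.append(float(w))
        for lab in extra_nodes:
            index.setdefault(str(lab), len(index))
        nodes = tuple(index)
        edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
        return cls(nodes, edges, np.asarray(ws, dtype=np.float64))

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        weight: float = 1.0,
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        """Build an unweighted network (every link carries ``weight``)."""
        return cls.from_edges(
            ((u, v, weight) for u, v in pairs), extra_nodes=extra_nodes
        )

    # -- basic queries ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def node_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.nodes)}

    def with_unit_weights(self) -> "WeightedNetwork":
        """Same topology, every weight set to 1 (topology-only view)."""
        return WeightedNetwork(self.nodes, self.edges, np.ones(self.n_edges))

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Same topology with a replacement weight vector."""
        return WeightedNetwork(self.nodes, self.edges, weights)

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self.edges]


@dataclass(frozen=True)
class RichnessSpec:
    """Choice of the richness parameter *r* used to rank nodes.

    ``parameter`` is one of ``"degree"``, ``"strength"`` or ``"custom"``;
    a custom spec must supply a value for every node of the network it
    is applied to.
    """

    parameter: str = "degree"
    custom_values: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.parameter not in ("degree", "strength", "custom"):
            raise ValueError(f"unknown richness parameter {self.parameter!r}")
        if self.parameter == "custom" and self.custom_values is None:
            raise ValueError("custom richness requires custom_values")
        if self.parameter != "custom" and self.custom_values is not None:
            raise ValueError("custom_values only valid with parameter='custom'")


def degree_array(net: WeightedNetwork) -> np.ndarray:
    """Per-node link count, aligned with ``net.nodes``."""
    return np.bincount(net.edges.ravel(), minlength=net.n_nodes).astype(np.int64)


def strength_array(net: WeightedNetwork) -> np.ndarray:
    """Per-node sum of incident link weights, aligned with ``net.nodes``."""
    w2 = np.concatenate([net.weights, net.weights])
    return np.bincount(net.edges.ravel(order="F"), weights=w2, minlength=net.n_nodes)


def richness_array(net: WeightedNetwork, spec: RichnessSpec) -> np.ndarray:
    """Richness values as a float array aligned with ``net.nodes``."""
    if spec.parameter == "degree":
        return degree_array(net).astype(np.float64)
    if spec.parameter == "strength":
        return strength_array(net)
    assert spec.custom_values is not None
    out = np.empty(net.n_nodes)
    for i, lab in enumerate(net.nodes):
        if lab not in spec.custom_values:
            raise KeyError(f"custom richness missing node {lab!r}")
        val = float(spec.custom_values[lab])
        if not np.isfinite(val):
            raise ValueError(f"non-finite richness for node {lab!r}")
        out[i] = val
    return out


def degree(net: WeightedNetwork) -> dict[str, int]:
    """Node -> degree mapping (isolated nodes map to 0)."""
    return dict(zip(net.nodes, (int(d) for d in degree_array(net))))


def strength(net: WeightedNetwork) -> dict[str, float]:
    """Node -> strength mapping."""
    return dict(zip(net.nodes, (float(s) for s in strength_array(net))))


def richness(net: WeightedNetwork, spec: RichnessSpec) -> dict[str, float]:
    """Node -> richness mapping for the chosen richness parameter."""
    return dict(zip(net.nodes, (float(r) for r in richness_array(net, spec))))
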