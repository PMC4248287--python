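"""Club identification and rich-club coefficient algebra.

A rich club at threshold *t* is the set of nodes whose richness is
strictly greater than *t*.  For that club we record

* ``N`` -- club size,
* ``E`` -- number of links between club members,
* ``P`` -- the topological ceiling ``N (N - 1) / 2``,
* ``C`` -- weighted connectedness, the sum of intra-club link weights.

The topological coefficient is ``phi = 2 E / (N (N - 1))``.  Weighted
coefficients take the form ``phi = C / F`` where *F* is the maximal
weighted connectedness the club could attain under domain-specific
assumptions.  Nine definitions of *F* are supported, indexed by a link
budget (how many links could carry weight into the club) and a weight
source (where those weights come from); see :class:`FVariant`.

Coefficients that are undefined (club smaller than two nodes, or
``F == 0``) are represented by ``nan`` so they propagate visibly through
curves instead of being silently zero-filled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet

import numpy as np

from .graph import RichnessSpec, WeightedNetwork, richness_array

__all__ = [
    "ClubSnapshot",
    "FVariant",
    "UNDEFINED",
    "identify_club",
    "club_snapshot",
    "topological_phi",
    "maximal_connectedness",
    "phi_ratio",
    "LINK_BUDGETS",
    "WEIGHT_SOURCES",
]

#: Marker for coefficients that are undefined (e.g. clubs with N < 2).
UNDEFINED: float = math.nan

LINK_BUDGETS = ("P", "E", "all")
WEIGHT_SOURCES = ("capped", "global", "local")


@dataclass(frozen=True)
class ClubSnapshot:
    """One club's statistics at a single richness threshold."""

    threshold: float
    members: FrozenSet[str]
    N: int
    E: int
    P: int
    C: float

    def __post_init__(self) -> None:
        if not (0 <= self.E <= self.P):
            raise ValueError(f"E={self.E} outside [0, P={self.P}]")
        if self.P != self.N * (self.N - 1) // 2:
            raise ValueError("P must equal N(N-1)/2")
        if self.C < 0:
            raise ValueError("C must be nonnegative")


@dataclass(frozen=True)
class FVariant:
    """One of the nine definitions of maximal weighted connectedness.

    ``link_budget``
        ``"P"``  -- links may be added inside the club up to the
        topological ceiling P;
        ``"E"``  -- the intra-club link count is fixed at E;
        ``"all"`` -- weights may be redistributed over the network's
        existing links.
    ``weight_source``
        ``"capped"`` -- any link could carry weight up to ``w_max``
        (e.g. correlation networks capped at 1);
        ``"global"`` -- weights are tied to links and the strongest
        links anywhere in the network could be placed inside the club;
        ``"local"`` -- only links already attached to a club member can
        be rewired to serve intra-club connectivity.

    ``w_max`` is required exactly when ``weight_source == "capped"``.
    """

    link_budget: str
    weight_source: str
    w_max: float | None = None

    def __post_init__(self) -> None:
        if self.link_budget not in LINK_BUDGETS:
            raise ValueError(f"link_budget must be one of {LINK_BUDGETS}")
        if self.weight_source not in WEIGHT_SOURCES:
            raise ValueError(f"weight_source must be one of {WEIGHT_SOURCES}")
        if self.weight_source == "capped":
            if self.w_max is None or not (self.w_max > 0 and math.isfinite(self.w_max)):
                raise ValueError("capped variants require a positive finite w_max")
        elif self.w_max is not None:
            raise ValueError("w_max is only meaningful for capped variants")


def identify_club(
    net: WeightedNetwork, spec: RichnessSpec, threshold: float
) -> frozenset[str]:
    """Nodes whose richness is *strictly* greater than ``threshold``.

    Ties at the boundary are excluded together; the empty set is a valid
    club.
    """
    r = richness_array(net, spec)
    return frozenset(np.asarray(net.nodes, dtype=object)[r > threshold])


def club_snapshot(
    net: WeightedNetwork, members: frozenset[str] | set[str], threshold: float = math.nan
) -> ClubSnapshot:
    """Compute N, E, P, C on the subgraph induced by ``members``."""
    index = net.node_index
    for lab in members:
        if lab not in index:
            raise KeyError(f"club member {lab!r} not in network")
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[[index[lab] for lab in members]] = True
    n = int(mask.sum())
    if net.n_edges:
        intra = mask[net.edges[:, 0]] & mask[net.edges[:, 1]]
        e = int(intra.sum())
        c = float(net.weights[intra].sum())
    else:
        e, c = 0, 0.0
    return ClubSnapshot(
        threshold=float(threshold),
        members=frozenset(members),
        N=n,
        E=e,
        P=n * (n - 1) // 2,
        C=c,
    )


def topological_phi(snap: ClubSnapshot) -> float:
    """Density of intra-club links, ``2E / (N(N-1))``; ``nan`` for N < 2."""
    if snap.N < 2:
        return UNDEFINED
    return 2.0 * snap.E / (snap.N * (snap.N - 1))


def maximal_connectedness(
    net: WeightedNetwork, snap: ClubSnapshot, variant: FVariant
) -> float:
    """Maximal weighted connectedness *F* of the club under ``variant``.

    The nine cases (link budget x weight source):

    ==========  ============================================================
    (P, capped)   ``P * w_max``
    (P, global)   sum of the ``min(P, L)`` largest weights in the network
    (P, local)    sum of the ``min(P, L_local)`` largest weights among links
                  with at least one endpoint in the club
    (E, capped)   ``E * w_max``
    (E, global)   sum of the E largest weights in the network
    (E, local)    sum of the E largest weights among club-incident links
    (all, capped) ``min(L, P) * w_max`` -- every existing link could carry
                  ``w_max``, but a club holds at most P links
    (all, global) total weight of the network
    (all, local)  total weight of links with at least one endpoint in the
                  club
    ==========  ============================================================

    Links wholly inside the club count among the local candidates (they
    are incident to rich nodes), which guarantees ``C <= F``.
    """
    w_sorted = np.sort(net.weights)[::-1]
    L = net.n_edges
    if variant.weight_source == "capped":
        assert variant.w_max is not None
        budget = {"P": snap.P, "E": snap.E, "all": min(L, snap.P)}[variant.link_budget]
        return float(budget * variant.w_max)
    if variant.weight_source == "global":
        if variant.link_budget == "all":
            return net.total_weight
        budget = min(snap.P, L) if variant.link_budget == "P" else snap.E
        return float(w_sorted[:budget].sum())
    # local: links with >= 1 endpoint in the club
    index = net.node_index
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[[index[lab] for lab in snap.members]] = True
    if L:
        touch = mask[net.edges[:, 0]] | mask[net.edges[:, 1]]
        cand = np.sort(net.weights[touch])[::-1]
    else:
        cand = np.empty(0)
    if variant.link_budget == "all":
        return float(cand.sum())
    budget = min(snap.P, len(cand)) if variant.link_budget == "P" else snap.E
    return float(cand[:budget].sum())


def phi_ratio(snap: ClubSnapshot, F: float) -> float:
    """Weighted rich-club coefficient ``C / F``; ``nan`` when ``F == 0``."""
    if F < 0:
        raise ValueError(f"maximal connectedness F={F} is negative")
    if F == 0:
        return UNDEFINED
    return snap.C / F
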