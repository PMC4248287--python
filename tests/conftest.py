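"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the package's vectorized
code paths: they work on label dictionaries and sorted lists so that
agreement with the package is a genuine dual-route check.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from richclubs import WeightedNetwork, er_weighted

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def chain_net() -> WeightedNetwork:
    """a-b-c-d chain with weights 2, 3, 9 (degrees 1,2,2,1)."""
    return WeightedNetwork.from_edges(
        [("a", "b", 2.0), ("b", "c", 3.0), ("c", "d", 9.0)]
    )


@pytest.fixture
def kite_net() -> WeightedNetwork:
    """Triangle a-b-c plus pendant d (degrees a:2 b:2 c:3 d:1)."""
    return WeightedNetwork.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0), ("c", "d", 1.0)]
    )


def random_net(seed: int, n: int = 12, p: float = 0.4) -> WeightedNetwork:
    """Small random weighted network for property tests."""
    return er_weighted(n, p, seed=seed)


# ---------------------------------------------------------------- oracles

def edge_dict(net: WeightedNetwork) -> dict[tuple[str, str], float]:
    return {
        tuple(sorted((u, v))): float(w)
        for (u, v), w in zip(net.edge_labels(), net.weights)
    }


def brute_degree(nodes, edges) -> dict[str, int]:
    return {
        n: sum(1 for e in edges if n in e) for n in nodes
    }


def brute_club_stats(nodes, edges, members):
    """E, P, C of the induced subgraph by pairwise enumeration."""
    members = set(members)
    e = c = 0
    for u, v in itertools.combinations(sorted(members), 2):
        key = tuple(sorted((u, v)))
        if key in edges:
            e += 1
            c += edges[key]
    n = len(members)
    return e, n * (n - 1) // 2, float(c)


def brute_F(edges, members, budget: str, source: str, w_max=None) -> float:
    """Independent implementation of the nine maximal-connectedness variants."""
    members = set(members)
    n = len(members)
    P = n * (n - 1) // 2
    E = sum(1 for (u, v) in edges if u in members and v in members)
    L = len(edges)
    all_w = sorted(edges.values(), reverse=True)
    local_w = sorted(
        (w for (u, v), w in edges.items() if u in members or v in members),
        reverse=True,
    )
    if source == "capped":
        count = {"P": P, "E": E, "all": min(L, P)}[budget]
        return count * w_max
    pool = all_w if source == "global" else local_w
    if budget == "all":
        return float(sum(pool)) if source == "local" else float(sum(all_w))
    k = min(P, len(pool)) if budget == "P" else E
    return float(sum(pool[:k]))
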