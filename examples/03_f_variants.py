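"""The nine definitions of maximal weighted connectedness F.

Builds a small hand-checkable network, takes the club of nodes with
degree > 2, and prints phi = C/F under every combination of link budget
(P links addable / E links fixed / all network links) and weight source
(capped at w_max / strongest anywhere / strongest touching the club).
Different assumptions about how links and weights could be rearranged
give different coefficients for the same club -- which is why the
normalized framework replaces F with randomized controls.
"""
from richclubs import (
    FVariant,
    RichnessSpec,
    WeightedNetwork,
    club_snapshot,
    identify_club,
    maximal_connectedness,
    phi_ratio,
)

net = WeightedNetwork.from_edges([
    ("a", "b", 5.0), ("a", "c", 4.0), ("a", "d", 3.0),
    ("b", "c", 2.0), ("b", "d", 1.0), ("d", "e", 1.0),
])
spec = RichnessSpec("degree")
members = identify_club(net, spec, 2)
snap = club_snapshot(net, members, 2)
print(f"club (degree > 2): {sorted(members)}  N={snap.N} E={snap.E} P={snap.P} C={snap.C}")
print()
print(f"{'link budget':12s} {'weight source':14s} {'F':>7s} {'phi = C/F':>10s}")
w_max = float(net.weights.max())
for budget in ("P", "E", "all"):
    for source in ("capped", "global", "local"):
        var = FVariant(budget, source, w_max if source == "capped" else None)
        F = maximal_connectedness(net, snap, var)
        phi = phi_ratio(snap, F)
        print(f"{budget:12s} {source:14s} {F:7.2f} {phi:10.3f}")
print(
    f"\n(capped variants use w_max = {w_max}; every phi <= 1, and stricter"
    " assumptions about rearrangement give larger F, hence smaller phi)"
)
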