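"""The central dissociation: topology- vs weight-driven rich clubs.

Plants a weighted rich club (intra-club weights of the ten
highest-degree nodes boosted 5x on a fixed random topology) and
measures it with all three control families.  Only the
topology-preserving (weighted) control should flag it: the link
placement is random, so the degree-preserving (topological) control
sees nothing, while the mixed control blends both answers.
"""
import numpy as np

from richclubs import PlantSpec, RichnessSpec, phi_norm_curve, plant_weighted_club

spec = RichnessSpec("degree")
net, planted = plant_weighted_club(
    PlantSpec(n_nodes=100, club_size=10, baseline_p=0.1, boost=5.0, seed=11)
)
print(f"planted club ({len(planted)} highest-degree nodes): {sorted(planted)}\n")

for kind in ("topological", "weighted", "mixed"):
    curve = phi_norm_curve(net, spec, kind=kind, n_rand=500, seed=3)
    sig = [
        (int(t), round(float(ph), 2))
        for t, s, ph in zip(curve.thresholds, curve.significant, curve.phi_norm)
        if s
    ]
    top = curve.defined.nonzero()[0][-1]
    print(
        f"{kind:12s} control: phi_norm at highest defined threshold"
        f" (t={curve.thresholds[top]:.0f}, N={curve.N[top]}):"
        f" {curve.phi_norm[top]:5.2f};"
        f" significant (threshold, phi_norm): {sig if sig else 'none'}"
    )

print(
    "\nThe weighted control flags phi_norm >> 1 at high thresholds (the"
    " boosted club) and the topological control stays quiet (the link"
    " placement is random).  The mixed control also fires, but it cannot"
    " say whether topology or weights are responsible -- the conflation"
    " that motivates choosing controls deliberately."
)
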