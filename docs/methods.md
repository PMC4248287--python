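# Methods

## The model

A **rich club** at richness threshold *t* is the set of nodes whose
richness *r* is strictly greater than *t*. Richness is any node property
that ranks all nodes; built-in choices are degree *k* (incident link
count) and strength *s* (sum of incident link weights), with arbitrary
custom values supported. Ties at the boundary are excluded together —
"richer than *t*" is a strict inequality, and no tie-breaking is
applied.

For a club of *N* nodes with *E* intra-club links, *P* = *N*(*N*−1)/2
possible links, and weighted connectedness *C* (the sum of intra-club
link weights), the classical topological coefficient is

    phi(t) = 2E / (N(N-1)),

and weighted generalizations take the form

    phi(t) = C / F,

where *F* is the maximal weighted connectedness the club could attain
under domain-specific assumptions. Nine definitions of *F* are
implemented, indexed by a **link budget** — links may be added inside
the club up to *P*; the intra-club link count is fixed at *E*; or
weights may be redistributed over all existing network links — and a
**weight source** — any link may carry weight up to a cap `w_max`
(correlation-style networks); the strongest links from anywhere in the
network may be moved into the club; or only links already attached to a
club member may be rewired inward. Links wholly inside the club count
among the "local" candidates, which guarantees *C* ≤ *F*. Two
combinations need a convention: (all links, capped) is *F* =
min(*L*, *P*)·`w_max` (every existing link could carry the cap, but a
club holds at most *P* links), and when the budget exceeds the
candidate pool, all candidates are used.

The coefficient that the package actually promotes is the **normalized**
one,

    phi_norm(t) = C(t) / mean(C_rand(t)),

the observed weighted connectedness over its average in an ensemble of
randomized controls. Whenever a control preserves *F*, normalizing any
*C*/*F* coefficient by its own null average cancels *F* exactly, so
every variant collapses to this one ratio — *F* never needs to be
computed for detection, only the controls need to be chosen. This
cancellation is asserted to machine precision in the test suite for
control/variant pairs where the invariance is exact, and a
counter-example test shows that a mismatched pair (an *E*-links *F*
against a topology-shuffling control) does not cancel — the conflation
of topological and weighted structure that motivates the framework.

## Randomized controls

* **Topological** (degree-preserving): double-edge-swap randomization
  starting from the observed network, 10 × (link count) swap attempts,
  rejecting swaps that would create self-loops or duplicate links;
  executed by igraph's C rewiring engine under a dedicated seeded RNG.
  Starting from a realization means the degree sequence is preserved
  exactly by construction. Weights are discarded (set to 1) — and the
  observed network is unit-weighted too when curves are computed against
  this control, so the curve is the classical unweighted normalization.
* **Weighted** (topology-preserving): the link set is untouched; the
  weight multiset is randomly permuted over it, then symmetric iterative
  proportional fitting multiplies each weight by the geometric mean of
  its endpoints' target/current strength ratios until every node's
  strength is within relative tolerance `tol` (default 1e-3, cap 10,000
  iterations; failure raises with the worst deviation). A positive
  solution always exists on the original support (the original weights),
  so convergence failure signals pathological input. Rescaled weights
  are real-valued even for integer inputs; no re-rounding, since only
  sums enter *C*.
* **Mixed**: rewired topology carrying the permuted weight multiset
  rescaled toward the original strength sequence.
* **Directed weight shuffle**: for networks with a declared link
  orientation, the weights of each node's outgoing (or incoming) links
  are permuted among themselves, preserving each node's out-(in-)
  strength and the global weight multiset exactly.

Club membership in each control is recomputed from the control's own
richness values. For degree richness this yields clubs of identical size
at every threshold (the degree sequence is conserved by every control);
for strength or custom richness, recomputation is the only faithful
choice.

Ensembles derive per-control seeds from a parent seed through numpy's
`SeedSequence` (31-bit children), so runs are reproducible and control
streams statistically independent.

## Curves and significance

Thresholds are every unique richness value in the network (the maximum
included; its club is empty and the coefficient undefined). Undefined
coefficients — club smaller than two nodes, or mean *C*_rand = 0 — are
`nan` and propagate visibly; they are never zero-filled, and a mean
*C*_rand of 0 against a positive *C* additionally logs a warning rather
than producing infinity.

Significance per threshold is a two-sided empirical p-value with
add-one correction,

    p = min(1, 2 * min(r+, r-) / (n_rand + 1)),

where r± are one plus the counts of null samples at least/most as
extreme as the observation. Two-sided because weight allocations
*below* chance are a finding in their own right (phi_norm significantly
under 1 is reported behavior for real systems, e.g. weight-depleted
hub links). The default ensemble size is 1,000 controls and the default
level α = 0.05. No multiple-testing correction is applied across
thresholds by default; a Benjamini–Hochberg option (`fdr=True`) uses
scipy's FDR control. Under the null the empirical p is exact for
continuous *C* and conservative (super-uniform) when ties occur — which
is routine for the unit-weight topological control, where *C* is an
integer link count.

## Synthetic generators

The generators exist so that every analysis path is testable with known
ground truth:

* `er_weighted(n, p, law, seed)` — Erdős–Rényi topology, i.i.d. weights
  (uniform(0,1) default; log-normal and constant laws available).
* `plant_topological_club` — pairs inside a designated club linked with
  probability `club_p` (default 0.6), all other pairs with `baseline_p`
  (default 0.05 in the recovery studies); weights blind to membership.
  A club built purely by link placement.
* `plant_weighted_club` — a fixed ER topology (`baseline_p` = 0.1 in the
  studies); the club is its `club_size` (10) highest-degree nodes, whose
  mutual link weights are multiplied by `boost` (5). The link set is
  untouched: a club built purely by weight allocation, anchored to
  high-degree nodes so that degree-based richness can find it.

These defaults are the study conditions used throughout the acceptance
suite (networks of 100 nodes, clubs of 10). What the generators do *not*
emulate: spatial embedding, modular or hierarchical structure, degree–
weight correlations of real transport or connectome data, and integer
weight quantization. Passing the recovery tests therefore shows the
estimator separates the two planting mechanisms under clean conditions,
not that it would resolve them in arbitrarily confounded real data.

## Calibration studies and numerical choices

The **null self-consistency study** draws replicate networks *from* a
control ensemble and normalizes each against fresh controls of the same
kind (50 replicates × 200 controls on an ER(100, 0.1) base). Per
threshold, the mean of phi_norm is 1 within Monte-Carlo error; pooled
across thresholds the estimate for the degree-preserving kind is
unbiased (integer *C*), while for continuous-*C* kinds the ratio
estimator *C*/mean(*C*_rand) carries a small positive Jensen bias
concentrated at sparse high thresholds (variance of the denominator),
so only a bound is asserted there. At thresholds below the minimum
degree the club is the entire network and phi_norm deviates from 1 by
the deterministic IPF tolerance rather than by sampling noise. The
rejection rate matches α for continuous *C* and sits at or below α for
tied, discrete *C*.

The **planted recovery study** (50 seeds, 1,000 controls each) assesses
detection over the club-isolating threshold region — thresholds whose
club has Jaccard overlap ≥ 0.3 with the planted set and at least two
members — because noise in the degree ranking shifts the exact
threshold at which the planted set surfaces. Detected means phi_norm >
1 with p < α somewhere in that region; the non-matching control is
"quiet" if significant nowhere in it. Weighted planting is recovered in
every seed with the topology-preserving control while the
degree-preserving control stays quiet in the large majority; the
reverse experiment recovers topological planting in most but not quite
all seeds (the intra-club density signal sits 1–2 null standard
deviations out in occasional draws at these effect sizes), a known
limitation of the two-sided α = .05 test at this effect size rather
than of the estimator.

Other numerical conventions: edge rows are canonicalized (u < v,
lexicographic) at construction; weights must be strictly positive and
finite (zero weights are rejected at load time — topology and weights
are distinct concepts and a zero weight conflates them); duplicate node
pairs are an error, never silently summed; curve files format floats
with 17 significant digits so read-back is bit-exact; undefined entries
serialize as the literal string `NA`.

## Known limitations

* Swap-based rewiring approximates, but is not exactly, the uniform
  distribution over graphs with the given degree sequence.
* "Uncorrelated weights" has no unique operational definition; the
  permutation + strength-rescaling realization used here preserves the
  strength sequence only to tolerance and restores some weight–degree
  association through that very constraint. The decorrelation test is
  correspondingly loose.
* The mixed control requires the original strength targets to be
  feasible on the rewired topology; on very small or degenerate graphs
  IPF may fail to converge (raised as an error, never silent).
* Directed analysis is limited to the per-node weight shuffle; the core
  coefficients are undirected.
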