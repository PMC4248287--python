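"""Normalized rich-club curves and empirical significance.

The normalized coefficient at a threshold is

    phi_norm = C / mean(C_rand)

where C is the observed weighted connectedness of the club and the mean
runs over an ensemble of randomized controls.  Whenever the control
preserves the maximal weighted connectedness F of the club, any of the
C/F coefficients divided by its own null average cancels F and reduces
to exactly this ratio -- which is why the curve never needs F at all.

Thresholds are taken at every unique richness value present in the
network (strict-inequality cutoffs), so the highest threshold always
yields an empty club and an undefined coefficient.

Significance is assessed per threshold with a two-sided empirical
p-value (add-one corrected) against the same ensemble: departures of
phi_norm above *and* below 1 both count, since weights concentrated
away from rich links ("less weight than expected by chance") are as
much a finding as a rich club.  No multiple-testing correction is
applied across thresholds by default; a Benjamini-Hochberg option is
available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .graph import RichnessSpec, WeightedNetwork, richness_array
from .null_models import DEFAULT_TOL, NullEnsemble, _club_c_series, build_ensemble

__all__ = [
    "RichClubCurve",
    "threshold_grid",
    "phi_norm_curve",
    "empirical_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RichClubCurve:
    """Per-threshold normalized rich-club coefficients and significance.

    Arrays are aligned with ``thresholds`` (strictly increasing).
    ``phi_norm`` and ``p_value`` are ``nan`` where the coefficient is
    undefined (club smaller than 2 nodes, or mean C_rand of 0);
    ``significant`` is ``False`` there.
    """

    thresholds: np.ndarray
    N: np.ndarray
    E: np.ndarray
    C: np.ndarray
    c_rand_mean: np.ndarray
    phi_norm: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    kind: str
    n_rand: int
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=np.float64)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.phi_norm)


def threshold_grid(net: WeightedNetwork, spec: RichnessSpec) -> np.ndarray:
    """Sorted unique richness values, used as strict-inequality cutoffs.

    The maximum richness is included; its club is empty and yields an
    undefined coefficient, which keeps the curve's domain explicit.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot build a threshold grid for an empty network")
    return np.unique(richness_array(net, spec))


def empirical_pvalue(c_obs: float, c_samples: np.ndarray) -> float:
    """Two-sided empirical p-value with add-one correction.

    ``p = min(1, 2 * min(r_plus, r_minus) / (n + 1))`` where ``r_plus``
    is one plus the number of samples >= the observation and
    ``r_minus`` one plus the number <= it.  Always in ``(0, 1]``; under
    the null the distribution is super-uniform.
    """
    s = np.asarray(c_samples, dtype=np.float64)
    if s.size == 0:
        raise ValueError("c_samples must be nonempty")
    r_plus = 1 + int(np.count_nonzero(s >= c_obs))
    r_minus = 1 + int(np.count_nonzero(s <= c_obs))
    return min(1.0, 2.0 * min(r_plus, r_minus) / (s.size + 1))


def phi_norm_curve(
    net: WeightedNetwork,
    spec: RichnessSpec | None = None,
    kind: str = "weighted",
    n_rand: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tol: float = DEFAULT_TOL,
    fdr: bool = False,
    ensemble: NullEnsemble | None = None,
) -> RichClubCurve:
    """Normalized rich-club curve against a randomized-control ensemble.

    Parameters
    ----------
    net
        Observed weighted network.
    spec
        Richness parameter (default: degree).
    kind
        ``"topological"``, ``"weighted"`` or ``"mixed"``.  For the
        topological control, weights are ignored (set to 1) in *both*
        the observed C and the controls, so the curve is the classical
        unweighted normalization.
    n_rand
        Ensemble size (1000 controls by default).
    alpha
        Per-threshold significance level for the two-sided empirical
        test (default 0.05).
    fdr
        Apply Benjamini-Hochberg across defined thresholds before
        flagging significance (off by default).
    ensemble
        Pre-built :class:`NullEnsemble` on the same threshold grid; if
        given, ``kind``/``n_rand``/``seed``/``tol`` describe it and no
        new controls are generated.
    """
    if spec is None:
        spec = RichnessSpec("degree")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    work = net.with_unit_weights() if kind == "topological" else net
    thresholds = threshold_grid(work, spec)
    r = richness_array(work, spec)

    r_sorted = np.sort(r)
    N = r.size - np.searchsorted(r_sorted, thresholds, side="right")
    if work.n_edges:
        emin = np.minimum(r[work.edges[:, 0]], r[work.edges[:, 1]])
        emin_s = np.sort(emin)
        E = work.n_edges - np.searchsorted(emin_s, thresholds, side="right")
    else:
        E = np.zeros(thresholds.size, dtype=np.int64)
    C = _club_c_series(r, work.edges, work.weights, thresholds)

    if ensemble is None:
        ensemble = build_ensemble(work, kind, thresholds, spec, n_rand, seed, tol=tol)
    else:
        if ensemble.kind != kind or not np.array_equal(ensemble.thresholds, thresholds):
            raise ValueError("supplied ensemble does not match this curve")
        n_rand = ensemble.n_rand
    c_mean = ensemble.c_rand_mean()

    defined = (N >= 2) & (c_mean > 0)
    starved = (N >= 2) & (c_mean == 0) & (C > 0)
    if np.any(starved):
        logger.warning(
            "mean C_rand is 0 at %d threshold(s) where C > 0; "
            "phi_norm left undefined there",
            int(starved.sum()),
        )
    phi = np.full(thresholds.size, np.nan)
    phi[defined] = C[defined] / c_mean[defined]

    p = np.full(thresholds.size, np.nan)
    for j in np.nonzero(defined)[0]:
        p[j] = empirical_pvalue(C[j], ensemble.c_samples[:, j])
    p_flag = p.copy()
    if fdr and np.any(defined):
        p_flag[defined] = _sstats.false_discovery_control(p[defined], method="bh")
    significant = np.zeros(thresholds.size, dtype=bool)
    significant[defined] = p_flag[defined] < alpha

    return RichClubCurve(
        thresholds=thresholds,
        N=N.astype(np.int64),
        E=np.asarray(E, dtype=np.int64),
        C=C,
        c_rand_mean=c_mean,
        phi_norm=phi,
        p_value=p,
        significant=significant,
        alpha=alpha,
        kind=kind,
        n_rand=n_rand,
        seed=int(seed),
    )
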