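"""Joint maximum-likelihood estimation of the gene-conversion initiation
rate (gamma) and mean tract length (L_GC) under the geometric tract model.

The data are (i) observed GC events, each summarized by the span of its
outermost converted markers (L_min) and the marker distances to the nearest
uninvolved flanking markers (gap_left, gap_right), and (ii) the
adjacent-marker gaps not involved in any event, which are informative
because a tract initiating in a gap went undetected only if it failed to
reach the gap's right marker.

Event term
----------
A tract ``(start, n)`` explains an event iff it covers both outermost
converted markers and neither flanking marker.  Summing
``gamma * (1-phi) * phi**(n-1)`` over all admissible placements factorizes
over the left/right extensions and collapses to::

    lik(event) = gamma * phi**(L_min - 1) * (1 - phi**g_L) * (1 - phi**g_R) / (1 - phi)

with ``g_L``/``g_R`` the flanking marker distances.  The module's tests
verify this against exhaustive (start, length) enumeration.

Interval term
-------------
Attributing every detectable tract to the marker gap containing its start
position counts each tract exactly once, so the per-meiosis probability
that no detectable tract initiates in a gap of width ``m`` is::

    exp(-gamma * (1 - phi**m) / (1 - phi))

and the product over all gaps is exactly the probability of observing no
GC anywhere.  Tracts that initiate and terminate strictly between two
markers are permitted — they are undetectable, which is precisely why
uninvolved markers are informative about tract length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .core import GCParams, RecEvent

_LOG_TINY = -745.0  # log of the smallest positive double


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GCObservation:
    """One observed GC event: converted-run span and flanking gaps (bp)."""

    L_min: int
    gap_left: int
    gap_right: int

    def __post_init__(self) -> None:
        if self.L_min < 1:
            raise ValueError("L_min must be >= 1")
        if self.gap_left < 1 or self.gap_right < 1:
            raise ValueError("flanking gaps of 0 are geometrically impossible")

    @property
    def m_gc(self) -> float:
        return 0.5 * (self.gap_left + self.gap_right)

    @property
    def L_max(self) -> float:
        return self.L_min + 2.0 * self.m_gc


@dataclass
class UninvolvedInterval:
    """Adjacent-marker gap not involved in any GC event.

    ``multiplicity`` counts interval-meiosis occurrences (it may carry
    equivalent-meioses weights and is therefore real-valued).
    """

    m: int
    multiplicity: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("interval width must be >= 1")
        if self.multiplicity <= 0:
            raise ValueError("multiplicity must be positive")


@dataclass
class GCLikelihoodData:
    """Events plus uninvolved intervals for one region/dataset."""

    events: Sequence[GCObservation]
    intervals: Sequence[UninvolvedInterval]
    n_meioses: float = 1.0

    @property
    def k(self) -> int:
        return len(self.events)

    def arrays(self):
        if self.events:
            ev = np.array([[e.L_min, e.gap_left, e.gap_right] for e in self.events],
                          dtype=float)
        else:
            ev = np.empty((0, 3))
        if self.intervals:
            iv = np.array([[i.m, i.multiplicity] for i in self.intervals], dtype=float)
        else:
            iv = np.empty((0, 2))
        return ev, iv


@dataclass
class GCFit:
    gamma_hat: float
    phi_hat: float
    max_loglik: float
    converged: bool
    n_events: int
    data: GCLikelihoodData = field(repr=False)
    use_mgc: bool = False
    confidence_region: Optional[np.ndarray] = None

    @property
    def L_GC_hat(self) -> float:
        return 1.0 / (1.0 - self.phi_hat)


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------

def tract_length_pmf(n, phi: float):
    """P(N = n) = (1 - phi) * phi**(n-1), support n >= 1."""
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("tract length must be >= 1")
    if not (0.0 <= phi < 1.0):
        raise ValueError("phi must lie in [0, 1)")
    return (1.0 - phi) * phi ** (n - 1)


def tract_length_survival(n, phi: float):
    """P(N >= n) = phi**(n-1)."""
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("tract length must be >= 1")
    return phi ** (n - 1)


def _log1m_pow(log_phi: float, g):
    """log(1 - phi**g), stable for phi near 0 and 1."""
    x = g * log_phi
    return np.log(-np.expm1(np.minimum(x, -1e-300)))


def event_loglik(obs: GCObservation, params: GCParams,
                 use_mgc: bool = False) -> float:
    """Log-likelihood of one observed GC event (closed form).

    Equals ``log(gamma * sum_n P(N=n) * A(n))`` where ``A(n)`` counts
    initiation placements whose tract covers both outermost converted
    markers and neither flanking marker.  With ``use_mgc`` the averaged gap
    ``m_gc`` replaces the exact per-side gaps (fallback for imported data).
    """
    if params.gamma == 0.0:
        return _LOG_TINY
    phi = params.phi
    gl, gr = obs.gap_left, obs.gap_right
    if use_mgc:
        gl = gr = obs.m_gc
    if phi == 0.0:
        # all tracts have length 1: only an L_min = 1 event is possible
        return float(np.log(params.gamma)) if obs.L_min == 1 else _LOG_TINY
    log_phi = np.log(phi)
    return float(np.log(params.gamma) + (obs.L_min - 1) * log_phi
                 + _log1m_pow(log_phi, gl) + _log1m_pow(log_phi, gr)
                 - _log1m_pow(log_phi, 1))


def interval_loglik(iv: UninvolvedInterval, params: GCParams) -> float:
    """Log-probability that no detectable tract initiates in the gap.

    Per meiosis this is ``-gamma * (1 - phi**m) / (1 - phi)``; the total is
    scaled by the interval's multiplicity (meioses observed).
    """
    if params.gamma == 0.0:
        return 0.0
    phi = params.phi
    if phi == 0.0:
        u = 1.0  # (1 - 0**m) / (1 - 0): only a start on the marker itself hits
    else:
        u = np.expm1(iv.m * np.log(phi)) / np.expm1(np.log(phi))
    return float(-params.gamma * u * iv.multiplicity)


def _neg_loglik(theta: np.ndarray, ev: np.ndarray, iv: np.ndarray,
                use_mgc: bool) -> float:
    """Negative total log-likelihood in (log gamma, logit phi) coordinates."""
    log_gamma, logit_phi = theta
    phi = 1.0 / (1.0 + np.exp(-logit_phi))
    phi = min(max(phi, 1e-12), 1.0 - 1e-12)
    log_phi = np.log(phi)
    k = ev.shape[0]
    ll = k * log_gamma
    if k:
        lmin, gl, gr = ev[:, 0], ev[:, 1], ev[:, 2]
        if use_mgc:
            gl = gr = 0.5 * (ev[:, 1] + ev[:, 2])
        ll += np.sum((lmin - 1) * log_phi
                     + _log1m_pow(log_phi, gl) + _log1m_pow(log_phi, gr)
                     - _log1m_pow(log_phi, 1))
    if iv.shape[0]:
        u = np.expm1(iv[:, 0] * log_phi) / np.expm1(log_phi)
        ll -= np.exp(log_gamma) * np.sum(u * iv[:, 1])
    return -float(ll)


def dataset_loglik(data: GCLikelihoodData, params: GCParams,
                   use_mgc: bool = False) -> float:
    """Total log-likelihood of a dataset at the given parameters."""
    ev, iv = data.arrays()
    phi = min(max(params.phi, 1e-12), 1 - 1e-12)
    gamma = max(params.gamma, 1e-300)
    theta = np.array([np.log(gamma), np.log(phi) - np.log1p(-phi)])
    return -_neg_loglik(theta, ev, iv, use_mgc)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_gc_mle(data: GCLikelihoodData, use_mgc: bool = False,
               n_starts: int = 5, seed: int = 0,
               tol: float = 1e-8) -> GCFit:
    """Joint MLE of (gamma, L_GC) by multistart quasi-Newton optimization.

    Optimization runs in transformed coordinates (log gamma, logit phi)
    from ``n_starts`` deterministic starting points.  Zero observed events
    with positive exposure drives gamma to its lower boundary (reported as
    0 with ``converged`` set).
    """
    ev, iv = data.arrays()
    if ev.shape[0] == 0 and iv.shape[0] == 0:
        raise ValueError("no events and no intervals: nothing to fit")
    if ev.shape[0] == 0:
        return GCFit(gamma_hat=0.0, phi_hat=0.0, max_loglik=0.0, converged=True,
                     n_events=0, data=data, use_mgc=use_mgc)
    if iv.shape[0] == 0:
        raise ValueError("events without uninvolved intervals leave gamma unbounded")

    # moment-flavored start: detected events per exposure-bp
    exposure_bp = float(np.sum(iv[:, 0] * iv[:, 1]))
    gamma0 = max(ev.shape[0] / max(exposure_bp, 1.0), 1e-12)
    l0 = max(float(np.mean(ev[:, 0])) * 2.0, 2.0)
    phi0 = 1.0 - 1.0 / l0
    rng = np.random.default_rng(seed)
    starts = [np.array([np.log(gamma0), np.log(phi0 / (1 - phi0))])]
    for _ in range(n_starts - 1):
        starts.append(starts[0] + rng.normal(0, 1.5, size=2))

    best = None
    for x0 in starts:
        res = optimize.minimize(_neg_loglik, x0, args=(ev, iv, use_mgc),
                                method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    log_gamma, logit_phi = best.x
    gamma_hat = float(np.exp(log_gamma))
    phi_hat = float(1.0 / (1.0 + np.exp(-logit_phi)))
    # local optimality check: +-1% single-parameter perturbations
    f0 = best.fun
    converged = bool(best.success)
    for i in range(2):
        for sgn in (-1, 1):
            x = best.x.copy()
            x[i] += sgn * np.log(1.01) if i == 0 else sgn * 0.01
            if _neg_loglik(x, ev, iv, use_mgc) < f0 - 1e-9 * abs(f0):
                converged = False
    return GCFit(gamma_hat=gamma_hat, phi_hat=phi_hat, max_loglik=-f0,
                 converged=converged, n_events=ev.shape[0], data=data,
                 use_mgc=use_mgc)


def lr_statistic(fit: GCFit, gamma: float, l_gc: float) -> float:
    """2 * (max log-lik - log-lik at (gamma, L_GC))."""
    params = GCParams.from_mean_length(gamma=gamma, l_gc=l_gc)
    return 2.0 * (fit.max_loglik - dataset_loglik(fit.data, params, fit.use_mgc))


def in_confidence_region(fit: GCFit, gamma: float, l_gc: float,
                         level: float = 0.95) -> bool:
    """Whether (gamma, L_GC) lies inside the joint likelihood-ratio region."""
    if not fit.converged:
        raise ValueError("confidence region requires a converged fit")
    return lr_statistic(fit, gamma, l_gc) <= stats.chi2.ppf(level, df=2)


def confidence_region(fit: GCFit, level: float = 0.95,
                      n_grid: int = 60, span: float = 6.0) -> np.ndarray:
    """Joint confidence contour of (gamma, L_GC) at the given level.

    Evaluates the likelihood-ratio statistic on a log-spaced grid around the
    MLE and extracts the ``chi2(2)`` level-set polygon.  Returns an array of
    (gamma, L_GC) vertices.
    """
    if not fit.converged:
        raise ValueError("confidence region requires a converged fit")
    import contourpy

    q = stats.chi2.ppf(level, df=2)
    gammas = fit.gamma_hat * np.exp(np.linspace(-np.log(span), np.log(span), n_grid))
    lgcs = fit.L_GC_hat * np.exp(np.linspace(-np.log(span), np.log(span), n_grid))
    lgcs = np.maximum(lgcs, 1.0 + 1e-9)
    z = np.empty((n_grid, n_grid))
    for i, l in enumerate(lgcs):
        for j, g in enumerate(gammas):
            z[i, j] = lr_statistic(fit, g, l)
    gen = contourpy.contour_generator(x=gammas, y=lgcs, z=z)
    lines = gen.lines(q)
    if not lines:
        raise RuntimeError("confidence contour not closed within the grid span")
    poly = max(lines, key=len)
    return np.asarray(poly)


# ---------------------------------------------------------------------------
# building likelihood data from detection output
# ---------------------------------------------------------------------------

def build_likelihood_data(haps_events: Iterable[Tuple["np.ndarray", List[RecEvent]]],
                          n_meioses: Optional[float] = None,
                          weights: Optional[Sequence[float]] = None) -> GCLikelihoodData:
    """Assemble events and uninvolved intervals from detected haplotypes.

    ``haps_events`` yields ``(marker_positions, events)`` pairs, one per
    haplotype.  Marker gaps strictly inside or flanking a GC event's
    converted run are excluded from the uninvolved set; everything else
    contributes an interval occurrence (optionally weighted by the
    haplotype's equivalent meioses).
    """
    events: List[GCObservation] = []
    gap_counts: dict = {}
    total_w = 0.0
    for idx, (positions, evs) in enumerate(haps_events):
        w = 1.0 if weights is None else float(weights[idx])
        total_w += w
        positions = np.asarray(positions)
        involved = np.zeros(positions.size - 1, dtype=bool)
        for e in evs:
            if e.kind != "GC":
                continue
            events.append(GCObservation(L_min=e.L_min, gap_left=e.gap_left,
                                        gap_right=e.gap_right))
            i = np.searchsorted(positions, e.left_flank_pos)
            j = np.searchsorted(positions, e.right_flank_pos)
            involved[i:j] = True
        gaps = np.diff(positions)[~involved]
        for m in gaps:
            gap_counts[int(m)] = gap_counts.get(int(m), 0.0) + w
    intervals = [UninvolvedInterval(m=m, multiplicity=c)
                 for m, c in sorted(gap_counts.items())]
    return GCLikelihoodData(events=events, intervals=intervals,
                            n_meioses=total_w if n_meioses is None else n_meioses)


def likelihood_data_from_arrays(events: np.ndarray, intervals: np.ndarray,
                                n_meioses: float = 1.0) -> GCLikelihoodData:
    """Wrap ``simulate_gc_observations`` output into GCLikelihoodData."""
    evs = [GCObservation(int(l), int(gl), int(gr)) for l, gl, gr in events]
    ivs = [UninvolvedInterval(int(m), float(c)) for m, c in intervals if c > 0]
    return GCLikelihoodData(events=evs, intervals=ivs, n_meioses=n_meioses)
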