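"""Time-to-onset analysis of adverse reactions with a Weibull hazard profile.

The latency from a patient's first prescription of a drug to the onset of
the event is computed per qualifying report (an exposed case with fully
specified start and onset dates), with the convention that onset on the
start day counts as 1 day, and analyzed within a 365-day window.  The
retained durations are summarized empirically (median, quartiles, fraction
within 30 days, histogram) and fitted with a two-parameter Weibull
distribution, whose shape β profiles the hazard over time without needing a
reference population: β > 1 with its 95% CI excluding 1 means an
early-increasing hazard, β < 1 with CI excluding 1 a decreasing (early
onset) hazard, otherwise the hazard is compatible with constant.

The Weibull MLE follows the standard profile reduction: the scale has a
closed form given the shape, and the shape solves a one-dimensional score
equation by Newton iteration; CIs are Wald intervals on the log-parameter
scale from the observed information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .dates import parse_partial_date
from .disproportionality import DEFAULT_ROLE_FILTER, Z_95
from .report_store import ReportSet

DEFAULT_WINDOW_DAYS = 365
#: minimum sample size for a Weibull fit
MIN_FIT_N = 10


@dataclass(frozen=True)
class DurationSample:
    """Retained onset latencies (days) plus exclusion tallies."""

    durations: np.ndarray
    n_excluded_incomplete: int
    n_excluded_negative: int
    n_excluded_beyond_window: int
    window_days: int = DEFAULT_WINDOW_DAYS

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class WeibullFit:
    scale_alpha: float
    shape_beta: float
    alpha_ci_low: float
    alpha_ci_high: float
    beta_ci_low: float
    beta_ci_high: float
    loglik: float
    hazard_class: str  # increasing / constant / decreasing
    n: int


@dataclass(frozen=True)
class OnsetSummary:
    median: float
    q1: float
    q3: float
    frac_within_30: float
    n: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def compute_durations(
    report_set: ReportSet,
    drug_code: str,
    case_indicator,
    event_terms: Optional[Iterable[str]] = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
    include_same_day: bool = True,
) -> DurationSample:
    """Onset latency per qualifying report.

    For each case report exposed to ``drug_code``: start is the earliest
    fully specified (YMD) start date among that drug's exposures, onset the
    earliest fully specified onset date among event-matching reactions (all
    reactions when ``event_terms`` is None); duration = onset − start + 1
    day.  Reports are excluded — and counted — when either date is
    incomplete or absent, when onset precedes start, or when the duration
    exceeds the window.
    """
    case = np.asarray(case_indicator, dtype=bool)
    roles = frozenset(role_filter)
    d = report_set.drugs
    drug_rows = d[(d["drug_code"] == drug_code) & d["role"].isin(roles)]
    exposed_ids = set(drug_rows["primary_id"])
    case_ids = set(report_set.reports.loc[case, "primary_id"])
    qualifying = exposed_ids & case_ids

    starts: dict = {}
    for pid, raw in zip(drug_rows["primary_id"], drug_rows["start_date"]):
        if pid not in qualifying:
            continue
        pdate = parse_partial_date(raw)
        if pdate is None or not pdate.is_complete:
            continue
        day = pdate.to_date()
        if pid not in starts or day < starts[pid]:
            starts[pid] = day

    terms = None if event_terms is None else frozenset(event_terms)
    r = report_set.reactions
    reac_rows = r[r["primary_id"].isin(qualifying)]
    if terms is not None:
        reac_rows = reac_rows[reac_rows["pt_code"].isin(terms)]
    onsets: dict = {}
    for pid, raw in zip(reac_rows["primary_id"], reac_rows["onset_date"]):
        pdate = parse_partial_date(raw)
        if pdate is None or not pdate.is_complete:
            continue
        day = pdate.to_date()
        if pid not in onsets or day < onsets[pid]:
            onsets[pid] = day

    durations = []
    n_incomplete = n_negative = n_beyond = 0
    for pid in qualifying:
        if pid not in starts or pid not in onsets:
            n_incomplete += 1
            continue
        delta = (onsets[pid] - starts[pid]).days
        if delta < 0 or (delta == 0 and not include_same_day):
            n_negative += 1
            continue
        duration = delta + 1
        if duration > window_days:
            n_beyond += 1
            continue
        durations.append(float(duration))
    return DurationSample(
        durations=np.asarray(sorted(durations), dtype=float),
        n_excluded_incomplete=n_incomplete,
        n_excluded_negative=n_negative,
        n_excluded_beyond_window=n_beyond,
        window_days=window_days,
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------

def _profile_score(beta: float, t: np.ndarray, logt: np.ndarray, mean_logt: float) -> Tuple[float, float]:
    """Score g(β) of the profile log-likelihood and its derivative.

    g(β) = 1/β + mean(log t) − Σ t^β log t / Σ t^β ;  the MLE shape solves
    g(β) = 0, after which α̂ = (mean t^β)^(1/β).
    """
    tb = np.power(t, beta)
    s0 = tb.sum()
    s1 = (tb * logt).sum()
    s2 = (tb * logt * logt).sum()
    g = 1.0 / beta + mean_logt - s1 / s0
    gprime = -1.0 / beta**2 - (s2 * s0 - s1 * s1) / s0**2
    return g, gprime


def weibull_loglik(t: np.ndarray, alpha: float, beta: float) -> float:
    """Log-likelihood of a two-parameter Weibull(scale α, shape β) sample."""
    n = len(t)
    z = t / alpha
    return float(
        n * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.log(t).sum()
        - np.power(z, beta).sum()
    )


def weibull_mle(
    duration_sample,
    z: float = Z_95,
    min_n: int = MIN_FIT_N,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> WeibullFit:
    """Two-parameter Weibull MLE with Wald CIs on the log-parameter scale.

    Accepts a :class:`DurationSample` or a bare array of positive
    durations.  The shape solves the profile score equation by safeguarded
    Newton iteration; the scale follows in closed form.  The hazard class
    is 'increasing' when the β CI lies above 1, 'decreasing' when below,
    else 'constant'.
    """
    t = np.asarray(
        duration_sample.durations
        if isinstance(duration_sample, DurationSample)
        else duration_sample,
        dtype=float,
    )
    n = len(t)
    if n < min_n:
        raise ValueError(f"Weibull fit needs at least {min_n} durations, got {n}")
    if (t <= 0).any():
        raise ValueError("durations must be positive")
    if np.unique(t).size < 2:
        raise ValueError("all durations identical: shape estimate diverges")

    logt = np.log(t)
    mean_logt = float(logt.mean())
    # Menon-style moment start for the shape
    sd_logt = float(logt.std())
    beta = (math.pi / math.sqrt(6.0)) / sd_logt if sd_logt > 0 else 1.0
    beta = min(max(beta, 1e-3), 1e3)
    lo, hi = 1e-6, 1e6
    for _ in range(max_iter):
        g, gp = _profile_score(beta, t, logt, mean_logt)
        # maintain a bracket: g is decreasing in beta
        if g > 0:
            lo = max(lo, beta)
        else:
            hi = min(hi, beta)
        step = -g / gp if gp != 0 else 0.0
        new_beta = beta + step
        if not lo < new_beta < hi:
            new_beta = 0.5 * (lo + hi)
        if abs(new_beta - beta) < tol * (abs(beta) + tol):
            beta = new_beta
            break
        beta = new_beta
    alpha = float(np.power(np.power(t, beta).mean(), 1.0 / beta))

    # observed information for (log alpha, log beta) by central differences
    la, lb = math.log(alpha), math.log(beta)

    def ll(la_, lb_):
        return weibull_loglik(t, math.exp(la_), math.exp(lb_))

    h = 1e-5
    H = np.empty((2, 2))
    f0 = ll(la, lb)
    H[0, 0] = (ll(la + h, lb) - 2 * f0 + ll(la - h, lb)) / h**2
    H[1, 1] = (ll(la, lb + h) - 2 * f0 + ll(la, lb - h)) / h**2
    H[0, 1] = H[1, 0] = (
        ll(la + h, lb + h) - ll(la + h, lb - h) - ll(la - h, lb + h) + ll(la - h, lb - h)
    ) / (4 * h**2)
    cov = np.linalg.inv(-H)
    se_la, se_lb = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
    alpha_ci = (math.exp(la - z * se_la), math.exp(la + z * se_la))
    beta_ci = (math.exp(lb - z * se_lb), math.exp(lb + z * se_lb))
    if beta_ci[0] > 1.0:
        hazard = "increasing"
    elif beta_ci[1] < 1.0:
        hazard = "decreasing"
    else:
        hazard = "constant"
    return WeibullFit(
        scale_alpha=alpha,
        shape_beta=float(beta),
        alpha_ci_low=alpha_ci[0],
        alpha_ci_high=alpha_ci[1],
        beta_ci_low=beta_ci[0],
        beta_ci_high=beta_ci[1],
        loglik=f0,
        hazard_class=hazard,
        n=n,
    )


def classify_hazard(beta_ci_low: float, beta_ci_high: float) -> str:
    """Hazard class from the shape CI alone (pure function of the bounds)."""
    if beta_ci_low > 1.0:
        return "increasing"
    if beta_ci_high < 1.0:
        return "decreasing"
    return "constant"


def summarize_onset(
    duration_sample,
    bin_width: float = 30.0,
    window_days: Optional[int] = None,
) -> OnsetSummary:
    """Empirical onset summary: median, quartiles (linear interpolation),
    fraction within 30 days, and a histogram (default 30-day bins)."""
    t = np.asarray(
        duration_sample.durations
        if isinstance(duration_sample, DurationSample)
        else duration_sample,
        dtype=float,
    )
    if len(t) == 0:
        raise ValueError("cannot summarize an empty duration sample")
    if window_days is None:
        window_days = (
            duration_sample.window_days
            if isinstance(duration_sample, DurationSample)
            else DEFAULT_WINDOW_DAYS
        )
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    edges = np.arange(0.0, window_days + bin_width, bin_width)
    counts, edges = np.histogram(t, bins=edges)
    return OnsetSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        frac_within_30=float((t <= 30).mean()),
        n=len(t),
        bin_edges=edges,
        bin_counts=counts,
    )


def onset_table(results: dict, event_name: str) -> pd.DataFrame:
    """Tidy per-drug time-to-onset results.

    ``results`` maps drug_code -> (DurationSample, OnsetSummary or None,
    WeibullFit or None).
    """
    rows = []
    for drug, (sample, summary, fit) in results.items():
        row = {
            "event": event_name,
            "drug": drug,
            "n": sample.n,
            "n_excluded_incomplete": sample.n_excluded_incomplete,
            "n_excluded_negative": sample.n_excluded_negative,
            "n_excluded_beyond_window": sample.n_excluded_beyond_window,
            "median": summary.median if summary else None,
            "q1": summary.q1 if summary else None,
            "q3": summary.q3 if summary else None,
            "frac_within_30": summary.frac_within_30 if summary else None,
            "alpha": fit.scale_alpha if fit else None,
            "alpha_ci_low": fit.alpha_ci_low if fit else None,
            "alpha_ci_high": fit.alpha_ci_high if fit else None,
            "beta": fit.shape_beta if fit else None,
            "beta_ci_low": fit.beta_ci_low if fit else None,
            "beta_ci_high": fit.beta_ci_high if fit else None,
            "hazard_class": fit.hazard_class if fit else None,
            "fitted_median": (
                fit.scale_alpha * math.log(2.0) ** (1.0 / fit.shape_beta) if fit else None
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
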