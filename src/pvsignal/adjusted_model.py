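"""Covariate-adjusted reporting odds ratios via multiple logistic regression.

Case status (did the report mention the event?) is modelled as

    logit P(case) = b0 + bY·Y + bA·A + bS·S + Σ bD·D + interaction terms

with Y the reporting year (continuous, mean-centered), A an indicator of
age ≥ 60 years (the 0–59 group is the reference), S an indicator of female
sex, and one 0/1 indicator per study drug.  Candidate interactions are the
pairwise products of the age and sex indicators with each other and with
the drug indicators.  Terms are chosen by forward/backward stepwise
selection with likelihood-ratio tests at a 5% significance level; under
weak heredity an interaction is a candidate only while both its parents are
in the model.  The adjusted ROR for a term is the exponentiated
coefficient, with a Wald 95% CI on the odds-ratio scale and a
likelihood-ratio p-value from dropping the term.

The maximum-likelihood fit is iteratively reweighted least squares with
step halving; quasi-separation is detected by a diverging coefficient and
flagged rather than reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import DEFAULT_ROLE_FILTER, Z_95, exposure_indicator
from .report_store import ReportSet

#: IRLS convergence: max |score| below this, or
SCORE_TOL = 1e-8
#: ... relative log-likelihood change below this.
LOGLIK_RTOL = 1e-10
MAX_ITER = 100
#: |coefficient| beyond this flags complete/quasi-separation.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Candidate terms and stepwise tuning for the adjusted-ROR model."""

    drugs: Tuple[str, ...]
    include_year: bool = True
    include_age: bool = True
    include_sex: bool = True
    age_sex_interaction: bool = True
    age_drug_interactions: bool = True
    sex_drug_interactions: bool = True
    year_drug_interactions: bool = False
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    hierarchy: bool = True
    age_cutoff: float = 60.0

    def __post_init__(self):
        if not 0.0 <= self.alpha_enter <= 1.0 or not 0.0 <= self.alpha_remove <= 1.0:
            raise ValueError("alpha levels must lie in [0, 1]")

    def main_terms(self) -> List[str]:
        terms = []
        if self.include_year:
            terms.append("year")
        if self.include_age:
            terms.append("age60")
        if self.include_sex:
            terms.append("female")
        terms += [f"drug[{d}]" for d in self.drugs]
        return terms

    def interaction_terms(self) -> List[str]:
        terms = []
        if self.age_sex_interaction and self.include_age and self.include_sex:
            terms.append("age60:female")
        if self.age_drug_interactions and self.include_age:
            terms += [f"age60:drug[{d}]" for d in self.drugs]
        if self.sex_drug_interactions and self.include_sex:
            terms += [f"female:drug[{d}]" for d in self.drugs]
        if self.year_drug_interactions and self.include_year:
            terms += [f"year:drug[{d}]" for d in self.drugs]
        return terms

    def candidate_terms(self) -> List[str]:
        return self.main_terms() + self.interaction_terms()


def parents_of(term: str) -> Tuple[str, ...]:
    """Main-effect parents of an interaction term ('a:b' -> ('a','b'))."""
    return tuple(term.split(":")) if ":" in term else ()


@dataclass
class LogisticFit:
    """A converged (or flagged) maximum-likelihood logistic fit."""

    terms: List[str]  # column names, first is "intercept"
    coefficients: np.ndarray
    covariance: np.ndarray
    minus2_loglik: float
    converged: bool
    n_obs: int
    n_iter: int = 0
    diagnostic: str = ""
    # design kept for term-dropping likelihood-ratio refits
    _X: Optional[np.ndarray] = field(default=None, repr=False)
    _y: Optional[np.ndarray] = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(math.sqrt(self.covariance[i, i]))


@dataclass(frozen=True)
class AdjustedROR:
    term: str
    point: float
    ci_low: float
    ci_high: float
    p_lrt: float


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def build_design(
    report_set: ReportSet,
    model_spec: ModelSpec,
    event_indicator: pd.Series,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
    drop_constant: bool = True,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (with intercept) and binary response for the model.

    The year column is centered at its sample mean; age/sex/drug terms are
    0/1 indicators; interaction columns are elementwise products.  Expects a
    report set already filtered to complete year/age/sex.  Zero-variance
    columns are dropped with a warning.
    """
    rep = report_set.reports
    for fname in ("report_year", "age_years", "sex"):
        if rep[fname].isna().any():
            raise ValueError(
                f"design requires complete {fname}; run filter_complete first"
            )
    n = len(rep)
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(n)}
    year = rep["report_year"].to_numpy(dtype=float)
    cols["year"] = year - year.mean()
    cols["age60"] = (rep["age_years"].to_numpy(dtype=float) >= model_spec.age_cutoff).astype(float)
    cols["female"] = (rep["sex"].to_numpy() == "F").astype(float)
    for d in model_spec.drugs:
        cols[f"drug[{d}]"] = exposure_indicator(report_set, d, role_filter).to_numpy(dtype=float)
    for term in model_spec.interaction_terms():
        p1, p2 = parents_of(term)
        cols[term] = cols[p1] * cols[p2]
    wanted = ["intercept"] + model_spec.candidate_terms()
    X = pd.DataFrame({k: cols[k] for k in wanted})
    if drop_constant:
        for name in list(X.columns):
            if name != "intercept" and X[name].nunique() <= 1:
                warnings.warn(f"dropping zero-variance design column {name!r}")
                X = X.drop(columns=name)
    y = np.asarray(event_indicator, dtype=float)
    if len(y) != n:
        raise ValueError("event_indicator not aligned with report_set")
    return X, y


def _neg2_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(2.0 * (np.logaddexp(0.0, eta).sum() - y @ eta))


def fit_logistic(design, response) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS (Newton–Raphson).

    Converges when the largest score component falls below 1e-8 or the
    relative change in log-likelihood falls below 1e-10 (at most 100
    iterations, with step halving).  The covariance is the inverse observed
    information at the optimum.  A coefficient diverging past ±15 flags
    complete/quasi-separation and the fit is returned not-converged; a
    singular information matrix is a fatal error naming the columns.
    """
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_obs={n} must exceed number of columns={p}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    beta = np.zeros(p)
    m2ll = _neg2_loglik(X, y, beta)
    converged = False
    diagnostic = ""
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            bad = [terms[i] for i in range(p) if info[i, i] <= 1e-12]
            raise np.linalg.LinAlgError(
                f"singular information matrix; offending columns: {bad or terms}"
            )
        # step halving if the step does not improve the likelihood
        new_beta = beta + step
        new_m2ll = _neg2_loglik(X, y, new_beta)
        halvings = 0
        while new_m2ll > m2ll + 1e-10 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_m2ll = _neg2_loglik(X, y, new_beta)
            halvings += 1
        beta, prev_m2ll, m2ll = new_beta, m2ll, new_m2ll
        if np.abs(beta).max() > SEPARATION_BOUND:
            diagnostic = (
                "separation suspected: |coefficient| > "
                f"{SEPARATION_BOUND} for {terms[int(np.abs(beta).argmax())]!r}"
            )
            break
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        if abs(prev_m2ll - m2ll) < LOGLIK_RTOL * (abs(prev_m2ll) + 1.0):
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        if converged:
            converged, diagnostic = False, "singular information at optimum"
    return LogisticFit(
        terms=terms,
        coefficients=beta,
        covariance=cov,
        minus2_loglik=m2ll,
        converged=converged,
        n_obs=n,
        n_iter=it,
        diagnostic=diagnostic,
        _X=X,
        _y=y,
    )


def likelihood_ratio_test(fit_full: LogisticFit, fit_reduced: LogisticFit) -> LRTResult:
    """LRT of nested logistic fits: the difference in −2·log-likelihood is
    chi-square with df = difference in term count."""
    extra = set(fit_reduced.terms) - set(fit_full.terms)
    if extra or fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("models are not nested on the same observations")
    df = len(fit_full.terms) - len(fit_reduced.terms)
    statistic = fit_reduced.minus2_loglik - fit_full.minus2_loglik
    if statistic < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({statistic:.3g}): non-nested or non-converged fits"
        )
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return LRTResult(statistic=statistic, df=df, p_value=p)


def _fit_subset(X: pd.DataFrame, y: np.ndarray, terms: Sequence[str]) -> LogisticFit:
    return fit_logistic(X[["intercept"] + list(terms)], y)


def stepwise_select(
    report_set: ReportSet,
    model_spec: ModelSpec,
    event_indicator: pd.Series,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
) -> Tuple[LogisticFit, List[dict]]:
    """Forward/backward stepwise term selection by likelihood-ratio tests.

    Forward: among eligible candidates, add the one with the smallest LRT
    p-value if p ≤ alpha_enter.  Backward: among included terms, remove the
    one with the largest p if p > alpha_remove.  Alternate until stable.
    Under weak heredity an interaction becomes eligible only when both its
    parents are included, and a parent is not removable while one of its
    interactions is in the model.  Returns the final fit and the full
    selection trace.
    """
    X, y = build_design(report_set, model_spec, event_indicator, role_filter)
    available = [t for t in model_spec.candidate_terms() if t in X.columns]
    included: List[str] = []
    trace: List[dict] = []
    current = _fit_subset(X, y, included)
    max_steps = max(2 * len(available), 4)
    step_no = 0
    changed = True
    while changed:
        changed = False
        # forward
        eligible = [
            t
            for t in available
            if t not in included
            and (
                not model_spec.hierarchy
                or all(p in included for p in parents_of(t))
            )
        ]
        best_term, best_p, best_fit = None, None, None
        for t in eligible:
            cand = _fit_subset(X, y, included + [t])
            p = likelihood_ratio_test(cand, current).p_value
            if best_p is None or p < best_p:
                best_term, best_p, best_fit = t, p, cand
        if best_term is not None and best_p <= model_spec.alpha_enter:
            included.append(best_term)
            current = best_fit
            trace.append({"step": step_no, "action": "add", "term": best_term, "p": best_p})
            step_no += 1
            changed = True
        # backward
        removable = [
            t
            for t in included
            if not model_spec.hierarchy
            or not any(t in parents_of(other) for other in included)
        ]
        worst_term, worst_p, worst_fit = None, None, None
        for t in removable:
            reduced = _fit_subset(X, y, [u for u in included if u != t])
            p = likelihood_ratio_test(current, reduced).p_value
            if worst_p is None or p > worst_p:
                worst_term, worst_p, worst_fit = t, p, reduced
        if worst_term is not None and worst_p > model_spec.alpha_remove:
            included.remove(worst_term)
            current = worst_fit
            trace.append({"step": step_no, "action": "remove", "term": worst_term, "p": worst_p})
            step_no += 1
            changed = True
        if step_no > max_steps:
            raise RuntimeError(f"stepwise selection oscillating; trace: {trace}")
    return current, trace


def adjusted_rors(fit: LogisticFit, z: float = Z_95) -> List[AdjustedROR]:
    """Adjusted ROR per non-intercept term of a converged fit.

    The point estimate is exp(coefficient) with a Wald CI on the odds-ratio
    scale; the p-value is the single-term likelihood-ratio test from
    dropping the term.
    """
    if not fit.converged:
        raise ValueError(f"fit not converged: {fit.diagnostic or 'no diagnostic'}")
    if fit._X is None:
        raise ValueError("fit lacks its design matrix; refit with fit_logistic")
    out = []
    Xdf = pd.DataFrame(fit._X, columns=fit.terms)
    for i, term in enumerate(fit.terms):
        if term == "intercept":
            continue
        coef = float(fit.coefficients[i])
        se = float(math.sqrt(fit.covariance[i, i]))
        reduced = fit_logistic(Xdf[[t for t in fit.terms if t != term]], fit._y)
        p = likelihood_ratio_test(fit, reduced).p_value
        out.append(
            AdjustedROR(
                term=term,
                point=math.exp(coef),
                ci_low=math.exp(coef - z * se),
                ci_high=math.exp(coef + z * se),
                p_lrt=p,
            )
        )
    return out


def adjusted_ror_table(rors: Sequence[AdjustedROR], event_name: str) -> pd.DataFrame:
    """Tidy adjusted-ROR results, one row per selected model term."""
    return pd.DataFrame(
        {
            "event": event_name,
            "term": [r.term for r in rors],
            "adjusted_ror": [r.point for r in rors],
            "ci_low": [r.ci_low for r in rors],
            "ci_high": [r.ci_high for r in rors],
            "p_lrt": [r.p_lrt for r in rors],
        }
    )
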