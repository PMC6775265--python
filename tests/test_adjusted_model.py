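"""Adjusted-ROR logistic model: design coding, IRLS fit, LRT, stepwise."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pvsignal as pv
from pvsignal.adjusted_model import LRTResult, fit_logistic, likelihood_ratio_test

from conftest import toy_report_set


def table_to_rows(a, b, c, d):
    """Expand a 2×2 table into per-report exposure/response rows."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    X = pd.DataFrame({"intercept": np.ones_like(x), "drug": x})
    return X, y


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_design_coding():
    """Year centered; A=1 iff age>=60; S=1 iff female; drug and product cols."""
    rset = toy_report_set(
        [("1", "C1", 2012, 70, "F"), ("2", "C2", 2014, 59, "M")],
        drugs=[("1", "rivaroxaban", "suspect_primary", np.nan)],
    )
    spec = pv.ModelSpec(drugs=("rivaroxaban",))
    X, y = pv.build_design(rset, spec, pd.Series([True, False]))
    row = X.iloc[0]
    assert row["year"] == pytest.approx(-1.0)  # centered at mean 2013
    assert row["age60"] == 1 and row["female"] == 1
    assert row["drug[rivaroxaban]"] == 1
    assert row["female:drug[rivaroxaban]"] == 1
    boundary = X.iloc[1]
    assert boundary["age60"] == 0  # age 59 is in the reference group
    assert list(y) == [1.0, 0.0]


def test_design_requires_complete_covariates():
    rset = toy_report_set([("1", "C1", 2012, np.nan, "F")])
    with pytest.raises(ValueError, match="filter_complete"):
        pv.build_design(rset, pv.ModelSpec(drugs=()), pd.Series([True]))


def test_design_matches_generator_covariates(paper_like_deduped, event_def):
    cfg, deduped, ledger = paper_like_deduped
    complete = pv.filter_complete(deduped, ["report_year", "age_years", "sex"])
    cases = pv.flag_cases(complete, event_def)
    X, y = pv.build_design(complete, pv.ModelSpec(drugs=tuple(cfg.drug_codes)), cases)
    truth = ledger.per_report.set_index("final_primary_id").reindex(
        complete.reports["primary_id"]
    )
    assert np.array_equal(X["age60"].to_numpy(), (truth["age_years"] >= 60).to_numpy())
    assert np.array_equal(X["female"].to_numpy(), (truth["sex"] == "F").to_numpy())
    for d in cfg.drug_codes:
        assert np.array_equal(
            X[f"drug[{d}]"].to_numpy().astype(bool), truth[f"exposed[{d}]"].to_numpy()
        )
    assert np.array_equal(y.astype(bool), truth["event"].to_numpy())


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------

def test_saturated_2x2_equals_crude_ror():
    X, y = table_to_rows(10, 90, 100, 9900)
    fit = fit_logistic(X, y)
    assert fit.converged
    assert math.exp(fit.coef("drug")) == pytest.approx(11.0, rel=1e-6)


def test_logistic_matches_statsmodels():
    """Cross-check coefficients, covariance and -2logLik on a random design."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    n = 2000
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.random(n) < 0.3,
        },
        dtype=float,
    )
    eta = -1.0 + 0.8 * X["x1"] - 0.5 * X["x2"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    ours = fit_logistic(X, y)
    ref = sm.Logit(y, X.to_numpy()).fit(disp=0)
    np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-6)
    np.testing.assert_allclose(ours.minus2_loglik, -2 * ref.llf, rtol=1e-8)
    np.testing.assert_allclose(ours.covariance, ref.cov_params(), rtol=1e-4)


def test_separation_is_flagged():
    X = pd.DataFrame({"intercept": np.ones(50)})
    fit = fit_logistic(X, np.zeros(50))
    assert not fit.converged and "separation" in fit.diagnostic


def test_parameter_recovery_single_drug():
    """True drug log-odds ln 10: exp(coef) CI covers 10."""
    cfg = pv.GeneratorConfig(
        n_reports=50_000,
        drugs=(pv.DrugSpec("drugx", 0.05),),
        event_model=pv.EventModel(
            intercept=math.log(0.05 / 0.95), drug_effects=(("drugx", math.log(10.0)),)
        ),
        missingness=(),
        seed=13,
    )
    rset, _ = pv.generate(cfg)
    d = pv.EventDefinition("ev", pv.TermSet("s", frozenset(cfg.event_terms)),
                           pv.TermSet("s", frozenset(cfg.event_terms)))
    cases = pv.flag_cases(rset, d)
    X, y = pv.build_design(rset, pv.ModelSpec(drugs=("drugx",)), cases)
    fit = fit_logistic(X, y)
    rors = {r.term: r for r in pv.adjusted_rors(fit)}
    r = rors["drug[drugx]"]
    assert r.ci_low < 10.0 < r.ci_high


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

def test_lrt_identity_and_chi2_oracle():
    X, y = table_to_rows(10, 90, 100, 9900)
    full = fit_logistic(X, y)
    assert likelihood_ratio_test(full, full).p_value == 1.0
    reduced = fit_logistic(X[["intercept"]], y)
    res = likelihood_ratio_test(full, reduced)
    assert res.df == 1
    assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))
    # the canonical 5% point of chi-square(1)
    assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)


def test_lrt_rejects_non_nested():
    X, y = table_to_rows(10, 90, 100, 9900)
    f1 = fit_logistic(X[["intercept"]], y)
    f2 = fit_logistic(X, y)
    with pytest.raises(ValueError, match="nested"):
        likelihood_ratio_test(f1, f2)  # reduced has extra term vs "full"


def test_lrt_invariant_to_year_rescaling(paper_like_deduped, event_def):
    cfg, deduped, _ = paper_like_deduped
    complete = pv.filter_complete(deduped, ["report_year", "age_years", "sex"])
    cases = pv.flag_cases(complete, event_def)
    spec = pv.ModelSpec(drugs=tuple(cfg.drug_codes))
    X, y = pv.build_design(complete, spec, cases)

    def lrt_for(Xd):
        full = fit_logistic(Xd, y)
        reduced = fit_logistic(Xd.drop(columns="year"), y)
        return likelihood_ratio_test(full, reduced).statistic

    X2 = X.copy()
    X2["year"] = 10.0 * X2["year"] + 3.0
    assert lrt_for(X) == pytest.approx(lrt_for(X2), rel=1e-6)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _small_set(seed=21, n=20_000):
    cfg = pv.get_preset("paper_like", n_reports=n, seed=seed)
    rset, ledger = pv.generate(cfg)
    deduped = pv.deduplicate(rset)
    complete = pv.filter_complete(deduped, ["report_year", "age_years", "sex"])
    terms = frozenset(cfg.event_terms)
    d = pv.EventDefinition("ev", pv.TermSet("s", terms), pv.TermSet("s", terms))
    return cfg, complete, pv.flag_cases(complete, d)


def test_stepwise_alpha_extremes():
    cfg, complete, cases = _small_set()
    spec_all = pv.ModelSpec(drugs=tuple(cfg.drug_codes), alpha_enter=1.0, alpha_remove=1.0)
    fit_all, _ = pv.stepwise_select(complete, spec_all, cases)
    assert set(fit_all.terms) == set(["intercept"] + spec_all.candidate_terms())
    spec_none = pv.ModelSpec(drugs=tuple(cfg.drug_codes), alpha_enter=0.0)
    fit_none, trace = pv.stepwise_select(complete, spec_none, cases)
    assert fit_none.terms == ["intercept"] and trace == []


def test_stepwise_selects_true_drug_among_nulls():
    """One real effect (ln 10) among three null drugs: the true drug is kept."""
    cfg = pv.GeneratorConfig(
        n_reports=50_000,
        drugs=tuple(pv.DrugSpec(c, 0.03) for c in ("true_drug", "null1", "null2", "null3")),
        event_model=pv.EventModel(
            intercept=math.log(0.05 / 0.95), drug_effects=(("true_drug", math.log(10.0)),)
        ),
        missingness=(),
        seed=29,
    )
    rset, _ = pv.generate(cfg)
    terms = frozenset(cfg.event_terms)
    d = pv.EventDefinition("ev", pv.TermSet("s", terms), pv.TermSet("s", terms))
    cases = pv.flag_cases(rset, d)
    fit, trace = pv.stepwise_select(rset, pv.ModelSpec(drugs=tuple(cfg.drug_codes)), cases)
    assert "drug[true_drug]" in fit.terms
    assert trace[0]["term"] == "drug[true_drug]"  # strongest signal enters first


def test_stepwise_hierarchy_gates_interactions():
    """Interactions enter only after both parents; the trace records steps."""
    cfg, complete, cases = _small_set()
    fit, trace = pv.stepwise_select(complete, pv.ModelSpec(drugs=tuple(cfg.drug_codes)), cases)
    included = ["intercept"]
    for step in trace:
        if step["action"] == "add":
            for parent in step["term"].split(":") if ":" in step["term"] else []:
                assert parent in included
            included.append(step["term"])
        else:
            included.remove(step["term"])
    assert set(included) == set(fit.terms)


# ---------------------------------------------------------------------------
# adjusted RORs
# ---------------------------------------------------------------------------

def test_adjusted_ror_wald_interval():
    """coef 0, se 0.1 -> point 1.0, CI (0.822, 1.217)."""
    X, y = table_to_rows(50, 50, 50, 50)
    fit = fit_logistic(X, y)
    fit.coefficients = np.array([0.0, 0.0])
    fit.covariance = np.array([[0.01, 0.0], [0.0, 0.01]])
    r = {a.term: a for a in pv.adjusted_rors(fit)}["drug"]
    assert r.point == pytest.approx(1.0)
    assert (r.ci_low, r.ci_high) == pytest.approx((0.822, 1.217), abs=5e-4)


def test_adjusted_ror_contract():
    X, y = table_to_rows(10, 90, 100, 9900)
    fit = fit_logistic(X, y)
    rors = pv.adjusted_rors(fit)
    assert all(r.term != "intercept" for r in rors)
    assert all(r.ci_low <= r.point <= r.ci_high for r in rors)
    bad = fit_logistic(pd.DataFrame({"intercept": np.ones(50)}), np.zeros(50))
    with pytest.raises(ValueError, match="not converged"):
        pv.adjusted_rors(bad)
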