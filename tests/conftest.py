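import numpy as np
import pandas as pd
import pytest

import pvsignal as pv


@pytest.fixture(scope="session")
def paper_like():
    """A medium synthetic snapshot with ground truth, shared across tests."""
    cfg = pv.get_preset("paper_like", n_reports=30_000, seed=11)
    report_set, ledger = pv.generate(cfg)
    return cfg, report_set, ledger


@pytest.fixture(scope="session")
def paper_like_deduped(paper_like):
    cfg, report_set, ledger = paper_like
    return cfg, pv.deduplicate(report_set), ledger


@pytest.fixture(scope="session")
def event_def(paper_like):
    cfg, _, _ = paper_like
    terms = frozenset(cfg.event_terms)
    return pv.intersect(pv.TermSet("smq", terms), pv.TermSet("soc", terms), "gi_hemorrhage")


def toy_report_set(rows, drugs=(), reactions=()):
    """Build a small ReportSet from plain tuples.

    rows: (primary_id, case_id, year, age, sex); drugs: (primary_id,
    drug_code, role, start_date); reactions: (primary_id, pt_code,
    onset_date).
    """
    rep = pd.DataFrame(
        rows, columns=["primary_id", "case_id", "report_year", "age_years", "sex"]
    )
    rep["source_tag"] = "toy"
    drug_df = pd.DataFrame(
        list(drugs), columns=["primary_id", "drug_code", "role", "start_date"]
    )
    reac_df = pd.DataFrame(list(reactions), columns=["primary_id", "pt_code", "onset_date"])
    return pv.ReportSet(rep, drug_df, reac_df)
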