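"""Report store: FAERS-style ingestion, canonical round-trip, dedup, filters."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.dates import PartialDate, parse_partial_date
from pvsignal.report_store import _version_order_key

from conftest import toy_report_set


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, iso, completeness",
    [
        ("2014-03-21", "2014-03-21", "YMD"),
        ("2014-03", "2014-03", "YM"),
        ("2014", "2014", "Y"),
        ("20140321", "2014-03-21", "YMD"),
        ("201403", "2014-03", "YM"),
        ("20140300", "2014-03", "YM"),  # unknown day encoded as 00
    ],
)
def test_partial_date_parsing(raw, iso, completeness):
    d = parse_partial_date(raw)
    assert d.isoformat() == iso
    assert d.completeness == completeness


@pytest.mark.parametrize("raw", ["", "XX", "2014-13", "99", None, "2014-02-30"])
def test_unparseable_dates_become_missing(raw):
    assert parse_partial_date(raw) is None


# ---------------------------------------------------------------------------
# FAERS-style ASCII reader
# ---------------------------------------------------------------------------

def _write_faers(tmp_path, demo, drug, reac, ther=None):
    paths = {}
    for name, header, rows in (
        ("demo", "primaryid$caseid$event_dt$age$age_cod$sex", demo),
        ("drug", "primaryid$drug_seq$drugname$role_cod", drug),
        ("reac", "primaryid$pt", reac),
        ("ther", "primaryid$dsg_drug_seq$start_dt", ther or []),
    ):
        p = tmp_path / f"{name}.txt"
        p.write_text("\n".join([header] + [("$".join(map(str, r))) for r in rows]) + "\n")
        paths[name] = p
    return paths


def test_faers_join_identity(tmp_path):
    """One report per DEMO row, child rows joined by primary id."""
    paths = _write_faers(
        tmp_path,
        demo=[(1, 10, 2014, 70, "YR", "F"), (2, 20, 2015, 55, "YR", "M"), (3, 30, 2016, 80, "YR", "F")],
        drug=[(1, 1, "Dabigatran", "PS"), (1, 2, "aspirin", "C")],
        reac=[(1, "PT1"), (2, "PT2")],
    )
    out = pv.read_faers_ascii(paths["demo"], paths["drug"], paths["reac"])
    assert len(out) == 3
    reports = {r.primary_id: r for r in out.iter_reports()}
    assert len(reports["1"].drugs) == 2
    assert reports["1"].drugs[0].drug_code == "dabigatran"  # case-folded
    assert reports["1"].drugs[0].role == "suspect_primary"
    assert len(reports["2"].drugs) == 0
    assert reports["2"].reactions[0].pt_code == "PT2"
    assert out.provenance["reports_read"] == 3


def test_faers_tolerant_age_parse(tmp_path):
    """Bad age keeps the report, sets age missing, and is counted."""
    paths = _write_faers(
        tmp_path,
        demo=[(1, 10, 2014, "XX", "YR", "F"), (2, 20, 2014, 18, "MON", "M")],
        drug=[],
        reac=[],
    )
    out = pv.read_faers_ascii(paths["demo"], paths["drug"], paths["reac"])
    assert len(out) == 2
    assert np.isnan(out.reports["age_years"].iloc[0])
    assert out.provenance["age_unparseable"] == 1
    # 18 months = 1.5 years via the unit map
    assert out.reports["age_years"].iloc[1] == pytest.approx(1.5)


def test_faers_age_unit_decades_and_plausibility(tmp_path):
    paths = _write_faers(
        tmp_path,
        demo=[(1, 10, 2014, 7, "DEC", "F"), (2, 20, 2014, 1500, "YR", "M")],
        drug=[],
        reac=[],
    )
    out = pv.read_faers_ascii(paths["demo"], paths["drug"], paths["reac"])
    assert out.reports["age_years"].iloc[0] == pytest.approx(70.0)
    assert np.isnan(out.reports["age_years"].iloc[1])  # > 120 years -> missing
    assert out.provenance["age_implausible"] == 1


def test_faers_therapy_start_dates(tmp_path):
    paths = _write_faers(
        tmp_path,
        demo=[(1, 10, 2014, 70, "YR", "F")],
        drug=[(1, 1, "drugA", "PS")],
        reac=[(1, "PT1")],
        ther=[(1, 1, "20140305"), (1, 1, "20140301")],  # earliest complete wins
    )
    out = pv.read_faers_ascii(paths["demo"], paths["drug"], paths["reac"], paths["ther"])
    assert out.drugs["start_date"].iloc[0] == "2014-03-01"


def test_faers_missing_file_and_column_are_fatal(tmp_path):
    paths = _write_faers(tmp_path, demo=[(1, 10, 2014, 70, "YR", "F")], drug=[], reac=[])
    with pytest.raises(FileNotFoundError, match="nonexistent"):
        pv.read_faers_ascii(tmp_path / "nonexistent.txt", paths["drug"], paths["reac"])
    bad = tmp_path / "bad_demo.txt"
    bad.write_text("notid$caseid\n1$10\n")
    with pytest.raises(KeyError, match="primaryid"):
        pv.read_faers_ascii(bad, paths["drug"], paths["reac"])


# ---------------------------------------------------------------------------
# canonical format round-trip
# ---------------------------------------------------------------------------

def test_canonical_round_trip(tmp_path, paper_like):
    _, report_set, _ = paper_like
    sub = report_set.subset(np.arange(len(report_set)) < 100)
    pv.write_canonical(sub, tmp_path / "c")
    back = pv.read_canonical(tmp_path / "c")
    pd.testing.assert_frame_equal(sub.reports, back.reports)
    pd.testing.assert_frame_equal(sub.drugs, back.drugs)
    pd.testing.assert_frame_equal(sub.reactions, back.reactions)


def test_canonical_empty_round_trip(tmp_path):
    empty = pv.ReportSet()
    pv.write_canonical(empty, tmp_path / "e")
    back = pv.read_canonical(tmp_path / "e")
    assert len(back) == 0


def test_canonical_preserves_date_completeness(tmp_path):
    rset = toy_report_set(
        [("1", "10", 2014, 70, "F")],
        drugs=[("1", "druga", "suspect_primary", "2014-03")],
    )
    pv.write_canonical(rset, tmp_path / "p")
    back = pv.read_canonical(tmp_path / "p")
    d = next(back.iter_reports()).drugs[0]
    assert d.start_date.completeness == "YM"


def test_canonical_schema_version_mismatch(tmp_path):
    rset = toy_report_set([("1", "10", 2014, 70, "F")])
    pv.write_canonical(rset, tmp_path / "v")
    meta = tmp_path / "v" / "metadata.json"
    meta.write_text(meta.read_text().replace('"schema_version": "1"', '"schema_version": "99"'))
    with pytest.raises(ValueError, match="99"):
        pv.read_canonical(tmp_path / "v")


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_dedup_keeps_greatest_primary_id():
    rset = toy_report_set(
        [("101", "C1", 2014, 70, "F"), ("205", "C1", 2015, 70, "F"), ("7", "C2", 2014, 50, "M")]
    )
    out = pv.deduplicate(rset)
    assert list(out.reports["primary_id"]) == ["205", "7"]
    assert out.provenance["duplicates_removed"] == 1


def test_dedup_numeric_vs_lexicographic_comparator():
    # all-numeric ids order numerically: "9" < "100"
    assert list(_version_order_key(pd.Series(["9", "100"]))) == [9, 100]
    # mixed ids fall back to lexicographic
    assert list(_version_order_key(pd.Series(["9b", "100a"]))) == ["9b", "100a"]


def test_dedup_idempotent_and_survivor_count(paper_like):
    _, report_set, ledger = paper_like
    once = pv.deduplicate(report_set)
    twice = pv.deduplicate(once)
    assert len(once) == report_set.reports["case_id"].nunique()
    assert twice.provenance["duplicates_removed"] == 0
    pd.testing.assert_frame_equal(once.reports, twice.reports)
    assert once.provenance["duplicates_removed"] == ledger.n_duplicates


def test_dedup_survivors_match_ledger_truth(paper_like):
    """The surviving version of each duplicated case is the newer near-copy."""
    _, report_set, ledger = paper_like
    out = pv.deduplicate(report_set)
    survivors = set(out.reports["primary_id"])
    assert set(ledger.per_report["final_primary_id"]) == survivors


# ---------------------------------------------------------------------------
# completeness filter
# ---------------------------------------------------------------------------

def test_filter_complete_counts():
    rows = [(str(i), f"C{i}", 2014, 50, "F" if i >= 3 else np.nan) for i in range(10)]
    rset = toy_report_set(rows)
    out = pv.filter_complete(rset, ["sex"])
    assert len(out) == 7
    assert out.provenance["incomplete_sex"] == 3


def test_filter_complete_empty_is_identity(paper_like):
    _, report_set, _ = paper_like
    out = pv.filter_complete(report_set, [])
    assert len(out) == len(report_set)


def test_filter_complete_unknown_field_fatal(paper_like):
    _, report_set, _ = paper_like
    with pytest.raises(ValueError, match="country"):
        pv.filter_complete(report_set, ["country"])


def test_filter_complete_composes_over_field_partition(paper_like):
    _, report_set, _ = paper_like
    joint = pv.filter_complete(report_set, ["report_year", "age_years", "sex"])
    seq = pv.filter_complete(
        pv.filter_complete(report_set, ["report_year"]), ["age_years", "sex"]
    )
    pd.testing.assert_frame_equal(joint.reports, seq.reports)


def test_filter_complete_matches_configured_missingness():
    """20% age missingness at n=10,000 drops about 2,000 reports."""
    cfg = pv.GeneratorConfig(
        n_reports=10_000,
        missingness=(("age_years", 0.2),),
        seed=5,
    )
    report_set, _ = pv.generate(cfg)
    out = pv.filter_complete(report_set, ["age_years"])
    # within 3 binomial standard errors of 8,000
    se = np.sqrt(10_000 * 0.2 * 0.8)
    assert abs(len(out) - 8_000) < 3 * se


def test_drug_code_normalization():
    rset = toy_report_set(
        [("1", "C1", 2014, 70, "F")],
        drugs=[("1", "  PRADAXA ", "suspect_primary", np.nan)],
    )
    out = pv.normalize_drug_codes(rset, {"pradaxa": "dabigatran"})
    assert out.drugs["drug_code"].iloc[0] == "dabigatran"
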