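"""Canonical individual-case-safety-report (ICSR) store.

A :class:`ReportSet` holds one spontaneous-report snapshot as three aligned
tables mirroring the structure regulators publish (demographics, drug
exposures, reactions), keyed by ``primary_id`` — the per-version report id —
with ``case_id`` shared across successive versions of the same case.
Readers exist for FAERS-style "$"-delimited quarterly ASCII files and for the
package's own canonical CSV schema; deduplication keeps the most recent
version of each case, and completeness filters drop reports lacking the
demographic fields a regression needs.

All field parsing is tolerant: an unparseable age or date becomes missing
and is counted in the provenance log, never aborting the row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dates import PartialDate, parse_partial_date

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Drug role vocabulary (FAERS role_cod PS/SS/C/I plus a catch-all).
ROLES = ("suspect_primary", "suspect_secondary", "concomitant", "interacting", "unknown")

DEFAULT_ROLE_MAP = {
    "PS": "suspect_primary",
    "SS": "suspect_secondary",
    "C": "concomitant",
    "I": "interacting",
}

#: Age-unit code -> multiplier to years (FAERS age_cod conventions).
DEFAULT_AGE_UNIT_MAP = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Ages above this are treated as data errors and set missing.
MAX_PLAUSIBLE_AGE = 120.0

#: source column names for each canonical field, FAERS quarterly-file naming.
DEFAULT_COLUMN_MAP = {
    "demo.primary_id": "primaryid",
    "demo.case_id": "caseid",
    "demo.report_year": "event_dt",
    "demo.age": "age",
    "demo.age_unit": "age_cod",
    "demo.sex": "sex",
    "drug.primary_id": "primaryid",
    "drug.seq": "drug_seq",
    "drug.drug": "drugname",
    "drug.role": "role_cod",
    "reac.primary_id": "primaryid",
    "reac.pt": "pt",
    "ther.primary_id": "primaryid",
    "ther.seq": "dsg_drug_seq",
    "ther.start_date": "start_dt",
}


@dataclass(frozen=True)
class DrugExposure:
    drug_code: str
    role: str = "unknown"
    start_date: Optional[PartialDate] = None


@dataclass(frozen=True)
class ReactionEvent:
    pt_code: str
    onset_date: Optional[PartialDate] = None


@dataclass(frozen=True)
class CaseReport:
    """One report version: demographics plus its drug and reaction lists."""

    primary_id: str
    case_id: str
    report_year: Optional[int] = None
    age_years: Optional[float] = None
    sex: Optional[str] = None  # "M" / "F" / None
    drugs: tuple = ()
    reactions: tuple = ()
    source_tag: str = ""


REPORT_COLUMNS = ["primary_id", "case_id", "report_year", "age_years", "sex", "source_tag"]
DRUG_COLUMNS = ["primary_id", "drug_code", "role", "start_date"]
REACTION_COLUMNS = ["primary_id", "pt_code", "onset_date"]


def _empty_frame(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


class ReportSet:
    """An ordered collection of case reports with an ingestion provenance log.

    Parameters
    ----------
    reports, drugs, reactions
        The three canonical tables.  ``reports`` must have one row per
        report version with a unique ``primary_id``; ``drugs`` and
        ``reactions`` are long-format child tables keyed by ``primary_id``.
    provenance
        Counter dict recording rows read/kept/dropped per ingestion rule.
    """

    def __init__(
        self,
        reports: Optional[pd.DataFrame] = None,
        drugs: Optional[pd.DataFrame] = None,
        reactions: Optional[pd.DataFrame] = None,
        provenance: Optional[dict] = None,
    ):
        self.reports = reports.copy() if reports is not None else _empty_frame(REPORT_COLUMNS)
        self.drugs = drugs.copy() if drugs is not None else _empty_frame(DRUG_COLUMNS)
        self.reactions = (
            reactions.copy() if reactions is not None else _empty_frame(REACTION_COLUMNS)
        )
        for frame, cols in (
            (self.reports, REPORT_COLUMNS),
            (self.drugs, DRUG_COLUMNS),
            (self.reactions, REACTION_COLUMNS),
        ):
            for c in cols:
                if c not in frame.columns:
                    frame[c] = "" if c == "source_tag" else np.nan
        self.reports = self.reports[REPORT_COLUMNS].reset_index(drop=True)
        self.drugs = self.drugs[DRUG_COLUMNS].reset_index(drop=True)
        self.reactions = self.reactions[REACTION_COLUMNS].reset_index(drop=True)
        if self.reports["primary_id"].duplicated().any():
            dup = self.reports.loc[self.reports["primary_id"].duplicated(), "primary_id"].iloc[0]
            raise ValueError(f"duplicate primary_id within ReportSet: {dup!r}")
        self.provenance = dict(provenance or {})

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.reports)

    @property
    def primary_ids(self) -> pd.Series:
        return self.reports["primary_id"]

    def iter_reports(self) -> Iterator[CaseReport]:
        """Yield reports as :class:`CaseReport` objects in stored order."""
        drugs_by_id = {k: v for k, v in self.drugs.groupby("primary_id", sort=False)}
        reacs_by_id = {k: v for k, v in self.reactions.groupby("primary_id", sort=False)}
        for row in self.reports.itertuples(index=False):
            pid = row.primary_id
            dd = drugs_by_id.get(pid)
            rr = reacs_by_id.get(pid)
            drugs = tuple(
                DrugExposure(d.drug_code, d.role, parse_partial_date(d.start_date))
                for d in (dd.itertuples(index=False) if dd is not None else ())
            )
            reacs = tuple(
                ReactionEvent(r.pt_code, parse_partial_date(r.onset_date))
                for r in (rr.itertuples(index=False) if rr is not None else ())
            )
            yield CaseReport(
                primary_id=pid,
                case_id=row.case_id,
                report_year=None if pd.isna(row.report_year) else int(row.report_year),
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                sex=None if pd.isna(row.sex) or row.sex == "" else str(row.sex),
                drugs=drugs,
                reactions=reacs,
                source_tag=row.source_tag or "",
            )

    def subset(self, keep_mask: np.ndarray, provenance: Optional[dict] = None) -> "ReportSet":
        """New ReportSet restricted to reports where ``keep_mask`` is True."""
        kept = self.reports.loc[np.asarray(keep_mask, dtype=bool)]
        ids = set(kept["primary_id"])
        return ReportSet(
            kept,
            self.drugs[self.drugs["primary_id"].isin(ids)],
            self.reactions[self.reactions["primary_id"].isin(ids)],
            provenance if provenance is not None else dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# FAERS-style ASCII reader
# ---------------------------------------------------------------------------

def _read_delimited(path, delimiter: str, encoding: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        encoding=encoding,
        encoding_errors="replace",
        engine="python",
    )
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_column(df: pd.DataFrame, column: str, table: str) -> None:
    if column not in df.columns:
        raise KeyError(f"{table} header lacks mapped column {column!r}; has {list(df.columns)}")


def _parse_age(value: str, unit: str, unit_map: Mapping[str, float], prov: dict) -> float:
    v = value.strip()
    if not v:
        return np.nan
    try:
        age = float(v)
    except ValueError:
        prov["age_unparseable"] = prov.get("age_unparseable", 0) + 1
        return np.nan
    mult = unit_map.get(unit.strip().upper(), 1.0) if unit else 1.0
    age *= mult
    if age < 0 or age > MAX_PLAUSIBLE_AGE:
        prov["age_implausible"] = prov.get("age_implausible", 0) + 1
        return np.nan
    return age


def _parse_sex(value: str) -> object:
    v = value.strip().upper()
    if v in {"M", "MALE"}:
        return "M"
    if v in {"F", "FEMALE"}:
        return "F"
    return np.nan


def read_faers_ascii(
    demo_path,
    drug_path,
    reac_path,
    ther_path=None,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    delimiter: str = "$",
    encoding: str = "utf-8",
    role_map: Optional[Mapping[str, str]] = None,
    age_unit_map: Optional[Mapping[str, float]] = None,
    source_tag: str = "faers",
) -> ReportSet:
    """Read FAERS-style quarterly ASCII tables into a :class:`ReportSet`.

    One CaseReport per demographics row, joined to drug and reaction rows by
    primary id; therapy start dates join onto drug rows by (primary id, drug
    sequence).  Unparseable field values become missing and are counted in
    the provenance log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    role_map = dict(role_map or DEFAULT_ROLE_MAP)
    unit_map = dict(age_unit_map or DEFAULT_AGE_UNIT_MAP)
    prov: dict = {"source_files": {}}

    demo = _read_delimited(demo_path, delimiter, encoding)
    drug = _read_delimited(drug_path, delimiter, encoding)
    reac = _read_delimited(reac_path, delimiter, encoding)
    prov["source_files"][str(demo_path)] = len(demo)
    prov["source_files"][str(drug_path)] = len(drug)
    prov["source_files"][str(reac_path)] = len(reac)
    for df, key, table in (
        (demo, "demo.primary_id", "DEMO"),
        (drug, "drug.primary_id", "DRUG"),
        (reac, "reac.primary_id", "REAC"),
    ):
        _require_column(df, cmap[key], table)

    # demographics
    year_col = cmap["demo.report_year"]
    years = []
    for raw in demo.get(year_col, pd.Series([""] * len(demo))):
        pdate = parse_partial_date(raw)
        if pdate is None:
            if str(raw).strip():
                prov["year_unparseable"] = prov.get("year_unparseable", 0) + 1
            years.append(np.nan)
        else:
            years.append(float(pdate.year))
    unit_col = cmap["demo.age_unit"]
    units = demo[unit_col] if unit_col in demo.columns else pd.Series([""] * len(demo))
    ages = [
        _parse_age(a, u, unit_map, prov)
        for a, u in zip(demo.get(cmap["demo.age"], pd.Series([""] * len(demo))), units)
    ]
    reports = pd.DataFrame(
        {
            "primary_id": demo[cmap["demo.primary_id"]].str.strip(),
            "case_id": demo[cmap["demo.case_id"]].str.strip(),
            "report_year": years,
            "age_years": ages,
            "sex": [_parse_sex(s) for s in demo.get(cmap["demo.sex"], pd.Series([""] * len(demo)))],
            "source_tag": source_tag,
        }
    )

    # drug exposures (+ optional therapy start dates)
    def _col(df: pd.DataFrame, name: str) -> pd.Series:
        return df[name] if name in df.columns else pd.Series([""] * len(df))

    drugs = pd.DataFrame(
        {
            "primary_id": drug[cmap["drug.primary_id"]].str.strip(),
            "drug_code": _col(drug, cmap["drug.drug"]).str.strip().str.casefold(),
            "role": [
                role_map.get(r.strip().upper(), "unknown")
                for r in _col(drug, cmap["drug.role"])
            ],
            "start_date": np.nan,
        }
    )
    if ther_path is not None:
        ther = _read_delimited(ther_path, delimiter, encoding)
        prov["source_files"][str(ther_path)] = len(ther)
        _require_column(ther, cmap["ther.primary_id"], "THER")
        seq_col_drug, seq_col_ther = cmap["drug.seq"], cmap["ther.seq"]
        if seq_col_drug in drug.columns and seq_col_ther in ther.columns:
            starts: dict = {}
            for pid, seq, raw_start in zip(
                ther[cmap["ther.primary_id"]],
                ther[seq_col_ther],
                _col(ther, cmap["ther.start_date"]),
            ):
                key = (pid.strip(), seq.strip())
                pdate = parse_partial_date(raw_start)
                if pdate is None:
                    continue
                # several therapy rows per drug: keep the earliest complete one
                prev = starts.get(key)
                if prev is None or (pdate.is_complete and (not prev.is_complete or pdate < prev)):
                    starts[key] = pdate
            keys = list(zip(drugs["primary_id"], drug[seq_col_drug].str.strip()))
            drugs["start_date"] = [
                starts[k].isoformat() if k in starts else np.nan for k in keys
            ]
        else:
            warnings.warn("THER given but drug-sequence columns missing; start dates skipped")

    reactions = pd.DataFrame(
        {
            "primary_id": reac[cmap["reac.primary_id"]].str.strip(),
            "pt_code": _col(reac, cmap["reac.pt"]).str.strip(),
            "onset_date": np.nan,
        }
    )

    # drop child rows with no parent demographics row
    known = set(reports["primary_id"])
    orphan_drugs = ~drugs["primary_id"].isin(known)
    orphan_reacs = ~reactions["primary_id"].isin(known)
    prov["orphan_drug_rows"] = int(orphan_drugs.sum())
    prov["orphan_reaction_rows"] = int(orphan_reacs.sum())
    prov["reports_read"] = len(reports)
    prov["reports_kept"] = len(reports)
    prov["reports_dropped"] = 0
    return ReportSet(reports, drugs[~orphan_drugs], reactions[~orphan_reacs], prov)


# ---------------------------------------------------------------------------
# Canonical CSV format
# ---------------------------------------------------------------------------

def write_canonical(report_set: ReportSet, path) -> None:
    """Write reports.csv / drugs.csv / reactions.csv plus sidecar metadata.

    Dates are ISO-8601 prefixes whose length encodes the completeness level;
    sex is "M" / "F" / empty.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rep = report_set.reports.copy()
    rep["report_year"] = rep["report_year"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    rep["age_years"] = rep["age_years"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    rep["sex"] = rep["sex"].fillna("")
    rep.to_csv(path / "reports.csv", index=False)
    for name, frame in (("drugs", report_set.drugs), ("reactions", report_set.reactions)):
        frame.fillna("").to_csv(path / f"{name}.csv", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_reports": len(report_set),
        "provenance": report_set.provenance,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_canonical(path) -> ReportSet:
    """Read a canonical report-set directory written by :func:`write_canonical`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"canonical metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    version = str(meta.get("schema_version"))
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"canonical schema version mismatch: file has {version!r}, "
            f"reader supports {SCHEMA_VERSION!r}"
        )
    rep = pd.read_csv(path / "reports.csv", dtype=str, keep_default_na=False)
    rep["report_year"] = pd.to_numeric(rep["report_year"].replace("", np.nan))
    rep["age_years"] = pd.to_numeric(rep["age_years"].replace("", np.nan))
    rep["sex"] = rep["sex"].replace("", np.nan)
    drugs = pd.read_csv(path / "drugs.csv", dtype=str, keep_default_na=False)
    drugs["start_date"] = drugs["start_date"].replace("", np.nan)
    reacs = pd.read_csv(path / "reactions.csv", dtype=str, keep_default_na=False)
    reacs["onset_date"] = reacs["onset_date"].replace("", np.nan)
    return ReportSet(rep, drugs, reacs, meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# Deduplication and completeness filtering
# ---------------------------------------------------------------------------

def _version_order_key(primary_ids: pd.Series):
    """Numeric order when every id is numeric, else lexicographic."""
    stripped = primary_ids.astype(str).str.strip()
    numeric = pd.to_numeric(stripped, errors="coerce")
    if not numeric.isna().any():
        return numeric
    return stripped


def deduplicate(report_set: ReportSet) -> ReportSet:
    """Keep the most recent version of each case.

    Regulators recommend retaining only the latest version of a case when
    the same patient is reported from several sources; the proxy for recency
    is the greatest ``primary_id`` per ``case_id`` (version ids increase over
    time).  Survivors preserve input order.  Idempotent.
    """
    rep = report_set.reports
    if len(rep) == 0:
        prov = dict(report_set.provenance)
        prov["duplicates_removed"] = 0
        return report_set.subset(np.zeros(0, dtype=bool), prov)
    order = _version_order_key(rep["primary_id"])
    df = pd.DataFrame({"case_id": rep["case_id"], "order": order})
    max_order = df.groupby("case_id")["order"].transform("max")
    keep = (df["order"] == max_order).to_numpy()
    # ties on identical order key: keep first encountered, warn
    tie_dup = pd.DataFrame({"case_id": rep["case_id"], "order": order}).duplicated()
    if (keep & tie_dup.to_numpy()).any():
        warnings.warn("tied primary_id versions within a case; keeping first encountered")
        keep &= ~tie_dup.to_numpy()
    prov = dict(report_set.provenance)
    prov["duplicates_removed"] = int((~keep).sum())
    return report_set.subset(keep, prov)


def filter_complete(report_set: ReportSet, required_fields: Iterable[str]) -> ReportSet:
    """Drop reports missing any of the required demographic fields.

    ``required_fields`` is a subset of {"report_year", "age_years", "sex"};
    the provenance log records the per-field and total drop counts.
    """
    allowed = {"report_year", "age_years", "sex"}
    required = list(required_fields)
    unknown = set(required) - allowed
    if unknown:
        raise ValueError(f"unknown completeness field(s): {sorted(unknown)}")
    rep = report_set.reports
    keep = np.ones(len(rep), dtype=bool)
    prov = dict(report_set.provenance)
    for f in required:
        missing = rep[f].isna().to_numpy()
        prov[f"incomplete_{f}"] = int((keep & missing).sum())
        keep &= ~missing
    prov["incomplete_removed"] = int((~keep).sum())
    return report_set.subset(keep, prov)


def normalize_drug_codes(report_set: ReportSet, synonym_map: Mapping[str, str]) -> ReportSet:
    """Map drug codes through a synonym table (exact match after case-fold/trim)."""
    table = {str(k).strip().casefold(): str(v) for k, v in synonym_map.items()}
    drugs = report_set.drugs.copy()
    folded = drugs["drug_code"].astype(str).str.strip().str.casefold()
    drugs["drug_code"] = folded.map(lambda c: table.get(c, c))
    return ReportSet(report_set.reports, drugs, report_set.reactions, dict(report_set.provenance))
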