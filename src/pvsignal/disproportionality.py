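"""Crude disproportionality analysis: the reporting odds ratio (ROR).

For one drug and one event the analyzed reports are cross-tabulated as

    ==============  =======  ==========
                     event    no event
    ==============  =======  ==========
    drug               a         b
    no drug            c         d
    ==============  =======  ==========

and the ROR is the odds ratio (a·d)/(b·c) with the Wald 95% CI
exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).  A drug–event pair is flagged
as a signal when the lower CI limit exceeds 1 and at least 2 exposed case
reports exist.  Tables with a zero cell receive the Haldane–Anscombe +0.5
correction (flagged in the result).  Analyses can be stratified by age
group; the conventional strata are 0–59 and ≥60 years.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .report_store import ReportSet

#: 95% two-sided normal quantile used throughout for Wald intervals.
Z_95 = 1.96

DEFAULT_ROLE_FILTER = frozenset({"suspect_primary", "suspect_secondary"})


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts (drug × event)."""

    a: float  # drug & event
    b: float  # drug & no event
    c: float  # no drug & event
    d: float  # no drug & no event

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RORResult:
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_cases_with_drug: int
    signal: bool
    corrected: bool
    table: Optional[ContingencyTable] = None


@dataclass(frozen=True)
class StratumSpec:
    """Ordered, disjoint half-open age intervals [lo, hi) with labels."""

    strata: Tuple[Tuple[str, float, float], ...]

    def __post_init__(self):
        labels = [s[0] for s in self.strata]
        if len(labels) != len(set(labels)):
            raise ValueError("stratum labels must be unique")
        ivs = sorted((lo, hi) for _, lo, hi in self.strata)
        for (lo1, hi1), (lo2, _) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                raise ValueError("stratum intervals must be disjoint")
        for _, lo, hi in self.strata:
            if not lo < hi:
                raise ValueError("stratum interval must satisfy lo < hi")


#: 0–59 vs ≥60 years — the conventional elderly cutoff in this analysis.
DEFAULT_AGE_STRATA = StratumSpec((("0-59", 0.0, 60.0), ("60+", 60.0, math.inf)))


def exposure_indicator(
    report_set: ReportSet,
    drug_code: str,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
) -> pd.Series:
    """Boolean per-report indicator of exposure to ``drug_code``.

    A report is exposed iff it has at least one exposure to the drug with a
    role in ``role_filter`` (default: suspect drugs only).
    """
    roles = frozenset(role_filter)
    d = report_set.drugs
    hits = d.loc[(d["drug_code"] == drug_code) & d["role"].isin(roles), "primary_id"]
    out = report_set.reports["primary_id"].isin(set(hits))
    out.name = drug_code
    return out


def build_contingency(
    report_set: ReportSet,
    drug_code: str,
    case_indicator: pd.Series,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
) -> ContingencyTable:
    """Cross-tabulate drug exposure against event case status.

    Each report contributes to exactly one cell; a+b+c+d equals the number
    of reports analyzed.
    """
    if len(case_indicator) != len(report_set):
        raise ValueError("case_indicator not aligned with report_set")
    exposed = exposure_indicator(report_set, drug_code, role_filter).to_numpy()
    if not exposed.any():
        warnings.warn(f"drug {drug_code!r}: no exposed reports in the analyzed set")
    case = np.asarray(case_indicator, dtype=bool)
    a = int((exposed & case).sum())
    b = int((exposed & ~case).sum())
    c = int((~exposed & case).sum())
    d = int((~exposed & ~case).sum())
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable, z: float = Z_95) -> RORResult:
    """Point estimate and Wald CI of the reporting odds ratio.

    Zero cells trigger the Haldane–Anscombe correction (+0.5 to every cell,
    ``corrected=True``); a table with a=0 before correction can never be a
    signal.  An all-zero table yields an undefined (None) result.
    """
    a0 = table.a
    if table.n == 0:
        return RORResult(None, None, None, 0, False, False, table)
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci_low = math.exp(math.log(ror) - z * se)
    ci_high = math.exp(math.log(ror) + z * se)
    result = RORResult(ror, ci_low, ci_high, int(a0), False, corrected, table)
    signal = apply_signal_criterion(result) and a0 > 0
    return RORResult(ror, ci_low, ci_high, int(a0), signal, corrected, table)


def apply_signal_criterion(result: RORResult) -> bool:
    """Signal rule: lower 95% CI limit > 1 and at least 2 exposed cases."""
    if result.ci_low is None:
        return False
    return result.ci_low > 1.0 and result.n_cases_with_drug >= 2


def stratified_ror(
    report_set: ReportSet,
    drug_code: str,
    case_indicator: pd.Series,
    stratum_spec: StratumSpec = DEFAULT_AGE_STRATA,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
    z: float = Z_95,
) -> List[Tuple[str, RORResult]]:
    """Crude ROR within each age stratum.

    Reports with missing age are excluded from every stratum; each stratum
    is analyzed independently.  An empty stratum yields an undefined result
    (warned).
    """
    ages = report_set.reports["age_years"].to_numpy(dtype=float)
    case = np.asarray(case_indicator, dtype=bool)
    out: List[Tuple[str, RORResult]] = []
    for label, lo, hi in stratum_spec.strata:
        in_stratum = (~np.isnan(ages)) & (ages >= lo) & (ages < hi)
        if not in_stratum.any():
            warnings.warn(f"age stratum {label!r} is empty")
            out.append((label, RORResult(None, None, None, 0, False, False, None)))
            continue
        sub = report_set.subset(in_stratum)
        sub_case = pd.Series(case[in_stratum], index=sub.reports.index)
        table = build_contingency(sub, drug_code, sub_case, role_filter)
        out.append((label, compute_ror(table, z)))
    return out


def ror_table(
    report_set: ReportSet,
    drug_codes: Sequence[str],
    case_indicator: pd.Series,
    event_name: str,
    stratum_spec: Optional[StratumSpec] = DEFAULT_AGE_STRATA,
    role_filter: Iterable[str] = DEFAULT_ROLE_FILTER,
) -> pd.DataFrame:
    """Tidy crude-ROR results: one row per (event, drug, stratum).

    The "all" stratum is the unstratified analysis; further rows follow the
    stratum spec.  Mirrors the usual disproportionality table layout.
    """
    rows = []

    def _row(drug: str, stratum: str, res: RORResult):
        t = res.table
        rows.append(
            {
                "event": event_name,
                "drug": drug,
                "stratum": stratum,
                "a": None if t is None else t.a,
                "b": None if t is None else t.b,
                "c": None if t is None else t.c,
                "d": None if t is None else t.d,
                "ror": res.ror,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "corrected": res.corrected,
                "signal": res.signal,
            }
        )

    for drug in drug_codes:
        table = build_contingency(report_set, drug, case_indicator, role_filter)
        _row(drug, "all", compute_ror(table))
        if stratum_spec is not None:
            for label, res in stratified_ror(
                report_set, drug, case_indicator, stratum_spec, role_filter
            ):
                _row(drug, label, res)
    return pd.DataFrame(rows)
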