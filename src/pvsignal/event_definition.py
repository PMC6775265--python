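"""Adverse-event case definitions from MedDRA preferred-term sets.

An event such as "gastrointestinal hemorrhage" is defined by intersecting a
standardized MedDRA query (SMQ) term list with a system-organ-class (SOC)
term list: a report is a *case* when it carries at least one reaction whose
preferred-term code is in both lists, i.e. in the intersection.  Term lists
are user-supplied CSV (the MedDRA dictionary itself is licensed and not
bundled).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Optional

import numpy as np
import pandas as pd

from .report_store import ReportSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermSet:
    """A named set of MedDRA preferred-term codes."""

    name: str
    pt_codes: FrozenSet[str]

    def __len__(self) -> int:
        return len(self.pt_codes)


@dataclass(frozen=True)
class EventDefinition:
    """An event defined as the intersection of an SMQ and an SOC term set."""

    name: str
    smq: TermSet
    soc: TermSet
    effective_terms: FrozenSet[str] = field(default=frozenset())

    def __post_init__(self):
        if not self.effective_terms:
            object.__setattr__(
                self, "effective_terms", self.smq.pt_codes & self.soc.pt_codes
            )
        assert self.effective_terms <= self.smq.pt_codes
        assert self.effective_terms <= self.soc.pt_codes


def load_term_table(path, set_name: Optional[str] = None) -> TermSet:
    """Load a term set from a CSV with columns (set_name, pt_code).

    When ``set_name`` is given, only matching rows are loaded. Duplicate
    codes are dropped (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"term table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("set_name", "pt_code"):
        if col not in df.columns:
            raise ValueError(f"term table {path} lacks required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"term table {path} is empty")
    if set_name is not None:
        df = df[df["set_name"] == set_name]
        if len(df) == 0:
            raise ValueError(f"term table {path} has no rows for set {set_name!r}")
    name = set_name if set_name is not None else df["set_name"].iloc[0]
    codes = [c.strip() for c in df["pt_code"] if c.strip()]
    n_dup = len(codes) - len(set(codes))
    if n_dup:
        logger.info("term table %s set %s: dropped %d duplicate codes", path, name, n_dup)
    return TermSet(name=name, pt_codes=frozenset(codes))


def intersect(smq: TermSet, soc: TermSet, name: str) -> EventDefinition:
    """Define an event as the exact SMQ ∩ SOC preferred-term intersection."""
    definition = EventDefinition(name=name, smq=smq, soc=soc)
    if not definition.effective_terms:
        warnings.warn(
            f"event definition {name!r}: SMQ {smq.name!r} and SOC {soc.name!r} are disjoint"
        )
    return definition


def flag_cases(report_set: ReportSet, definition: EventDefinition) -> pd.Series:
    """Per-report case indicator, aligned with ``report_set.reports``.

    True iff the report has at least one reaction whose preferred term is in
    the event's effective term set; a report with no reactions is a non-case.
    """
    terms = definition.effective_terms
    hits = report_set.reactions.loc[
        report_set.reactions["pt_code"].isin(terms), "primary_id"
    ]
    flagged = set(hits)
    out = report_set.reports["primary_id"].isin(flagged)
    out.name = definition.name
    return out
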