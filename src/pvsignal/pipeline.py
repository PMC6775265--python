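"""End-to-end orchestration: ingest → dedup → flag cases → crude/stratified
ROR → completeness filter → stepwise adjusted model → time-to-onset.

A run is described by a :class:`PipelineConfig` (loadable from YAML),
produces tidy CSVs per stage plus a JSON run manifest (config hash, seed,
per-stage row counts), and is deterministic: the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import event_definition as ed
from . import report_store as rs
from . import synthetic
from .adjusted_model import ModelSpec, adjusted_ror_table, adjusted_rors, stepwise_select
from .disproportionality import DEFAULT_AGE_STRATA, DEFAULT_ROLE_FILTER, StratumSpec, ror_table
from .time_to_onset import (
    MIN_FIT_N,
    compute_durations,
    onset_table,
    summarize_onset,
    weibull_mle,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one analysis run."""

    drugs: List[str]
    event_name: str = "event"
    # input: exactly one of (preset, input_dir)
    preset: Optional[str] = None
    n_reports: int = 50_000
    input_dir: Optional[str] = None
    # event definition: term tables, or the generator's event pool
    smq_table: Optional[str] = None
    soc_table: Optional[str] = None
    smq_name: Optional[str] = None
    soc_name: Optional[str] = None
    role_filter: Tuple[str, ...] = tuple(sorted(DEFAULT_ROLE_FILTER))
    age_strata: Tuple[Tuple[str, float, float], ...] = tuple(DEFAULT_AGE_STRATA.strata)
    window_days: int = 365
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    hierarchy: bool = True
    out_dir: str = "pvsignal_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.drugs:
            raise ValueError("config error: drug list is empty")
        if (self.preset is None) == (self.input_dir is None):
            raise ValueError("config error: give exactly one of preset / input_dir")
        if (self.smq_table is None) != (self.soc_table is None):
            raise ValueError("config error: smq_table and soc_table go together")
        if self.input_dir is not None and self.smq_table is None:
            raise ValueError("config error: file input requires SMQ/SOC term tables")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config error: unknown keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.drugs = list(cfg.drugs)
        cfg.role_filter = tuple(cfg.role_filter)
        cfg.age_strata = tuple(tuple(s) for s in cfg.age_strata)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drugs"] = list(d["drugs"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_input(config: PipelineConfig):
    """Report set plus (for preset runs) the ground-truth ledger."""
    if config.preset is not None:
        gen_cfg = synthetic.get_preset(
            config.preset, n_reports=config.n_reports, seed=config.seed
        )
        return synthetic.generate(gen_cfg)
    return rs.read_canonical(config.input_dir), None


def _event_definition(config: PipelineConfig, gen_cfg) -> ed.EventDefinition:
    if config.smq_table is not None:
        smq = ed.load_term_table(config.smq_table, config.smq_name)
        soc = ed.load_term_table(config.soc_table, config.soc_name)
        return ed.intersect(smq, soc, config.event_name)
    # synthetic fallback: the generator's event PT pool is the effective set
    terms = frozenset(gen_cfg.event_terms)
    smq = ed.TermSet("synthetic_smq", terms)
    soc = ed.TermSet("synthetic_soc", terms)
    return ed.intersect(smq, soc, config.event_name)


def run_all(config: PipelineConfig, write: bool = True) -> Dict[str, object]:
    """Execute every stage and (optionally) write the output bundle.

    Returns a dict with the stage DataFrames, the selection trace, the
    manifest, and (for generator input) the ground-truth ledger.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    counts: Dict[str, int] = {}

    report_set, ledger = _load_input(config)
    counts["ingested_reports"] = len(report_set)

    deduped = rs.deduplicate(report_set)
    counts["after_dedup"] = len(deduped)
    counts["duplicates_removed"] = deduped.provenance.get("duplicates_removed", 0)

    gen_cfg = ledger.config if ledger is not None else None
    definition = _event_definition(config, gen_cfg)
    cases = ed.flag_cases(deduped, definition)
    counts["cases"] = int(cases.sum())

    strata = StratumSpec(config.age_strata)
    crude = ror_table(
        deduped, config.drugs, cases, config.event_name, strata, config.role_filter
    )

    complete = rs.filter_complete(deduped, ["report_year", "age_years", "sex"])
    counts["complete_reports"] = len(complete)
    cases_complete = ed.flag_cases(complete, definition)
    spec = ModelSpec(
        drugs=tuple(config.drugs),
        alpha_enter=config.alpha_enter,
        alpha_remove=config.alpha_remove,
        hierarchy=config.hierarchy,
    )
    fit, trace = stepwise_select(complete, spec, cases_complete, config.role_filter)
    adjusted = adjusted_ror_table(adjusted_rors(fit), config.event_name)

    tto_results = {}
    for drug in config.drugs:
        sample = compute_durations(
            deduped,
            drug,
            cases,
            event_terms=definition.effective_terms,
            window_days=config.window_days,
            role_filter=config.role_filter,
        )
        summary = summarize_onset(sample) if sample.n else None
        fit_w = weibull_mle(sample) if sample.n >= MIN_FIT_N else None
        tto_results[drug] = (sample, summary, fit_w)
    tto = onset_table(tto_results, config.event_name)
    counts["tto_durations"] = int(tto["n"].sum())

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": counts,
        "selected_terms": [t for t in fit.terms if t != "intercept"],
        "minus2_loglik": fit.minus2_loglik,
    }
    results = {
        "report_set": deduped,
        "crude_ror": crude,
        "adjusted_ror": adjusted,
        "fit": fit,
        "trace": trace,
        "tto": tto,
        "manifest": manifest,
        "ledger": ledger,
        "event_definition": definition,
        "case_indicator": cases,
    }
    if write:
        out.mkdir(parents=True, exist_ok=True)
        crude.to_csv(out / "crude_ror.csv", index=False, float_format="%.10g")
        adjusted.to_csv(out / "adjusted_ror.csv", index=False, float_format="%.10g")
        tto_out = tto.copy()
        tto_out.to_csv(out / "time_to_onset.csv", index=False, float_format="%.10g")
        pd.DataFrame(trace).to_csv(out / "selection_trace.csv", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    return results


def run_from_manifest(manifest_path) -> Dict[str, object]:
    """Reproduce a run from its manifest alone."""
    manifest = json.loads(Path(manifest_path).read_text())
    raw = manifest["config"]
    cfg = PipelineConfig(**{k: v for k, v in raw.items()})
    cfg.drugs = list(cfg.drugs)
    cfg.role_filter = tuple(cfg.role_filter)
    cfg.age_strata = tuple(tuple(s) for s in cfg.age_strata)
    return run_all(cfg)
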