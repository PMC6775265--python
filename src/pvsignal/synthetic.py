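"""Synthetic spontaneous-report generator with a known ground truth.

Emulates the statistical structure a pharmacovigilance analysis assumes of
an SRS snapshot — per-report demographics (year, age, sex) with
missingness, several drugs per report with role codes, several reactions
per report drawn from event and decoy preferred-term pools, duplicate case
versions, event status following a logistic model in year/age/sex/drug
with interactions, and drug–event onset latencies following per-drug
Weibull distributions — while recording, per report, the pre-missingness
truth in a ledger that determines every expected analysis outcome exactly.

Structure, not realism, is the target: marginal drug/reaction frequencies
are not matched to any real database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .report_store import ReportSet

#: number of preferred terms in the synthetic event pool (sized like a
#: GI-hemorrhage SMQ∩SOC intersection) and the decoy pool.
DEFAULT_N_EVENT_TERMS = 152
DEFAULT_N_DECOY_TERMS = 500


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class DrugSpec:
    """One study drug: exposure prevalence and role assignment mix."""

    drug_code: str
    exposure_prob: float
    role_mix: Tuple[Tuple[str, float], ...] = (
        ("suspect_primary", 0.8),
        ("suspect_secondary", 0.2),
    )

    def __post_init__(self):
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise ValueError(f"exposure_prob out of [0,1] for {self.drug_code}")
        total = sum(w for _, w in self.role_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"role_mix weights must sum to 1 for {self.drug_code}")


@dataclass(frozen=True)
class EventModel:
    """Logistic model for event status: intercept plus per-term log-odds.

    ``interactions`` keys use the design-term naming of the adjusted model,
    e.g. "age60:female", "female:drug[rivaroxaban]".
    """

    intercept: float
    year_slope: float = 0.0
    age60: float = 0.0
    female: float = 0.0
    drug_effects: Tuple[Tuple[str, float], ...] = ()
    interactions: Tuple[Tuple[str, float], ...] = ()


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int
    year_range: Tuple[int, int] = (2004, 2016)
    p_female: float = 0.5
    #: (weight, mean, sd) mixture of normals truncated to [0, 100] years
    age_mixture: Tuple[Tuple[float, float, float], ...] = (
        (0.35, 45.0, 12.0),
        (0.65, 72.0, 10.0),
    )
    drugs: Tuple[DrugSpec, ...] = ()
    #: at most one study-drug exposure per report when True
    exclusive_exposure: bool = False
    event_model: EventModel = field(default_factory=lambda: EventModel(intercept=_logit(0.1)))
    #: drug_code -> (scale alpha in days, shape beta)
    onset_model: Tuple[Tuple[str, Tuple[float, float]], ...] = ()
    #: per-field missingness rates; dates are degraded to year-month
    missingness: Tuple[Tuple[str, float], ...] = (
        ("report_year", 0.02),
        ("age_years", 0.15),
        ("sex", 0.05),
        ("start_date", 0.2),
        ("onset_date", 0.2),
    )
    duplicate_rate: float = 0.0
    n_event_terms: int = DEFAULT_N_EVENT_TERMS
    n_decoy_terms: int = DEFAULT_N_DECOY_TERMS
    n_background_drugs: int = 20
    mean_background_drugs: float = 1.5
    mean_extra_reactions: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female out of [0,1]")
        if abs(sum(w for w, _, _ in self.age_mixture) - 1.0) > 1e-9:
            raise ValueError("age mixture weights must sum to 1")
        for fname, rate in self.missingness:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate out of [0,1] for {fname}")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate out of [0,1]")
        for code, (alpha, beta) in self.onset_model:
            if alpha <= 0 or beta <= 0:
                raise ValueError(f"onset model for {code}: alpha and beta must be > 0")

    @property
    def drug_codes(self) -> List[str]:
        return [d.drug_code for d in self.drugs]

    @property
    def event_terms(self) -> List[str]:
        return [f"EVT{i:04d}" for i in range(1, self.n_event_terms + 1)]

    @property
    def decoy_terms(self) -> List[str]:
        return [f"DCY{i:04d}" for i in range(1, self.n_decoy_terms + 1)]


@dataclass
class GroundTruthLedger:
    """Pre-missingness truth: one row per original report plus globals."""

    per_report: pd.DataFrame
    effects: Dict[str, float]
    onset_params: Dict[str, Tuple[float, float]]
    duplicate_map: pd.DataFrame  # case_id, original_primary_id, duplicate_primary_id
    config: GeneratorConfig

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicate_map)


def _draw_ages(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    ages = np.empty(n)
    for k, (_, mean, sd) in enumerate(mixture):
        idx = np.flatnonzero(comp == k)
        vals = rng.normal(mean, sd, size=len(idx))
        bad = (vals < 0) | (vals > 100)
        while bad.any():  # rejection sampling of the truncation
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = (vals < 0) | (vals > 100)
        ages[idx] = vals
    return ages


def _iso_dates(years: np.ndarray, day_offsets: np.ndarray) -> pd.Series:
    base = pd.to_datetime(pd.Series(years.astype(int) * 10000 + 101), format="%Y%m%d")
    return (base + pd.to_timedelta(day_offsets, unit="D")).dt.strftime("%Y-%m-%d")


def generate(config: GeneratorConfig) -> Tuple[ReportSet, GroundTruthLedger]:
    """Draw a synthetic report set and its ground-truth ledger.

    Deterministic under the config seed: the same config yields
    byte-identical canonical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    y0, y1 = config.year_range

    # --- covariates -------------------------------------------------------
    years = rng.integers(y0, y1 + 1, size=n)
    female = rng.random(n) < config.p_female
    ages = _draw_ages(rng, n, config.age_mixture)

    # --- study-drug exposures --------------------------------------------
    k = len(config.drugs)
    if config.exclusive_exposure and k:
        probs = np.array([d.exposure_prob for d in config.drugs])
        if probs.sum() > 1.0:
            raise ValueError("exclusive exposure probabilities exceed 1")
        cut = np.concatenate([[0.0], np.cumsum(probs)])
        u = rng.random(n)
        exposure = np.zeros((n, k), dtype=bool)
        for j in range(k):
            exposure[:, j] = (u >= cut[j]) & (u < cut[j + 1])
    else:
        exposure = np.zeros((n, k), dtype=bool)
        for j, d in enumerate(config.drugs):
            exposure[:, j] = rng.random(n) < d.exposure_prob

    # --- event status from the logistic model ----------------------------
    em = config.event_model
    year_c = years - (y0 + y1) / 2.0
    age60 = (ages >= 60.0).astype(float)
    fem = female.astype(float)
    lp = em.intercept + em.year_slope * year_c + em.age60 * age60 + em.female * fem
    drug_effects = dict(em.drug_effects)
    cols = {"age60": age60, "female": fem}
    for j, d in enumerate(config.drugs):
        cols[f"drug[{d.drug_code}]"] = exposure[:, j].astype(float)
        lp = lp + drug_effects.get(d.drug_code, 0.0) * exposure[:, j]
    for term, coef in em.interactions:
        p1, p2 = term.split(":")
        lp = lp + coef * cols[p1] * cols[p2]
    p_event = 1.0 / (1.0 + np.exp(-lp))
    event = rng.random(n) < p_event

    # --- ids --------------------------------------------------------------
    primary_ids = np.array([f"{100000 + i}" for i in range(n)])
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    # --- drug table (study drugs + background noise drugs) ---------------
    drug_frames = []
    onset_params = dict(config.onset_model)
    start_offsets = {}
    for j, d in enumerate(config.drugs):
        idx = np.flatnonzero(exposure[:, j])
        if len(idx) == 0:
            continue
        roles = np.array([r for r, _ in d.role_mix])
        weights = np.array([w for _, w in d.role_mix])
        role_draw = rng.choice(roles, size=len(idx), p=weights / weights.sum())
        offs = rng.integers(0, 365, size=len(idx))
        start_offsets[d.drug_code] = dict(zip(idx, offs))
        drug_frames.append(
            pd.DataFrame(
                {
                    "report_idx": idx,
                    "drug_code": d.drug_code,
                    "role": role_draw,
                    "start_date": _iso_dates(years[idx], offs).to_numpy(),
                }
            )
        )
    n_bg = rng.poisson(config.mean_background_drugs, size=n)
    bg_idx = np.repeat(np.arange(n), n_bg)
    if len(bg_idx):
        bg_codes = rng.integers(1, config.n_background_drugs + 1, size=len(bg_idx))
        bg_roles = rng.choice(
            np.array(["concomitant", "suspect_secondary", "interacting"]),
            size=len(bg_idx),
            p=[0.7, 0.2, 0.1],
        )
        drug_frames.append(
            pd.DataFrame(
                {
                    "report_idx": bg_idx,
                    "drug_code": [f"bgd{c:02d}" for c in bg_codes],
                    "role": bg_roles,
                    "start_date": np.nan,
                }
            )
        )
    drugs_df = (
        pd.concat(drug_frames, ignore_index=True)
        if drug_frames
        else pd.DataFrame(columns=["report_idx", "drug_code", "role", "start_date"])
    )
    drugs_df = drugs_df.sort_values("report_idx", kind="stable").reset_index(drop=True)

    # --- onset latencies for exposed event reports ------------------------
    # the latency is drawn from the first exposed study drug's Weibull and
    # rounded up to whole days, so the analysis convention
    # duration = onset - start + 1 recovers the drawn value exactly
    onset_drug = np.full(n, "", dtype=object)
    true_duration = np.full(n, np.nan)
    onset_date = np.full(n, np.nan, dtype=object)
    exposed_any = exposure.any(axis=1) if k else np.zeros(n, dtype=bool)
    first_drug = exposure.argmax(axis=1) if k else np.zeros(n, dtype=int)
    for j, d in enumerate(config.drugs):
        if d.drug_code not in onset_params:
            continue
        idx = np.flatnonzero(event & exposed_any & (first_drug == j) & exposure[:, j])
        if len(idx) == 0:
            continue
        alpha, beta = onset_params[d.drug_code]
        w = alpha * rng.weibull(beta, size=len(idx))
        dur = np.ceil(np.maximum(w, 1e-9)).astype(int)
        true_duration[idx] = dur
        onset_drug[idx] = d.drug_code
        offs = np.array([start_offsets[d.drug_code][i] for i in idx])
        onset_date[idx] = _iso_dates(years[idx], offs + dur - 1).to_numpy()

    # --- reaction table ----------------------------------------------------
    event_pool = np.array(config.event_terms)
    decoy_pool = np.array(config.decoy_terms)
    reac_frames = []
    ev_idx = np.flatnonzero(event)
    if len(ev_idx):
        reac_frames.append(
            pd.DataFrame(
                {
                    "report_idx": ev_idx,
                    "pt_code": rng.choice(event_pool, size=len(ev_idx)),
                    "onset_date": onset_date[ev_idx],
                }
            )
        )
    n_extra = rng.poisson(config.mean_extra_reactions, size=n)
    n_extra[~event] += 1  # every report carries at least one reaction
    dc_idx = np.repeat(np.arange(n), n_extra)
    if len(dc_idx):
        reac_frames.append(
            pd.DataFrame(
                {
                    "report_idx": dc_idx,
                    "pt_code": rng.choice(decoy_pool, size=len(dc_idx)),
                    "onset_date": np.nan,
                }
            )
        )
    reacs_df = pd.concat(reac_frames, ignore_index=True)
    reacs_df = reacs_df.sort_values("report_idx", kind="stable").reset_index(drop=True)

    # --- missingness (after the truth is recorded) ------------------------
    miss = dict(config.missingness)
    rep_year = years.astype(float)
    rep_age = ages.copy()
    rep_sex = np.where(female, "F", "M").astype(object)
    for fname, arr in (("report_year", rep_year), ("age_years", rep_age)):
        rate = miss.get(fname, 0.0)
        if rate > 0:
            arr[rng.random(n) < rate] = np.nan
    rate = miss.get("sex", 0.0)
    if rate > 0:
        rep_sex[rng.random(n) < rate] = np.nan
    for fname, frame, col in (
        ("start_date", drugs_df, "start_date"),
        ("onset_date", reacs_df, "onset_date"),
    ):
        rate = miss.get(fname, 0.0)
        if rate > 0 and len(frame):
            has_date = frame[col].notna().to_numpy()
            hit = (rng.random(len(frame)) < rate) & has_date
            # degrade complete dates to year-month precision
            frame.loc[hit, col] = frame.loc[hit, col].str.slice(0, 7)

    reports_df = pd.DataFrame(
        {
            "primary_id": primary_ids,
            "case_id": case_ids,
            "report_year": rep_year,
            "age_years": rep_age,
            "sex": rep_sex,
            "source_tag": "synthetic",
        }
    )
    drugs_df["primary_id"] = primary_ids[drugs_df["report_idx"].to_numpy(dtype=int)]
    reacs_df["primary_id"] = primary_ids[reacs_df["report_idx"].to_numpy(dtype=int)]
    drugs_out = drugs_df[["primary_id", "drug_code", "role", "start_date"]]
    reacs_out = reacs_df[["primary_id", "pt_code", "onset_date"]]

    # --- duplicate case versions ------------------------------------------
    dup_rows = []
    if config.duplicate_rate > 0:
        dup_mask = rng.random(n) < config.duplicate_rate
        dup_idx = np.flatnonzero(dup_mask)
        dup_pids = np.array([f"{100000 + n + j}" for j in range(len(dup_idx))])
        if len(dup_idx):
            extra_rep = reports_df.iloc[dup_idx].copy()
            extra_rep["primary_id"] = dup_pids
            # near-copy: one perturbed non-key field (source tag) so the
            # surviving version's analysis fields equal the ledger truth
            extra_rep["source_tag"] = "synthetic-v2"
            extra_drugs = drugs_out[drugs_out["primary_id"].isin(primary_ids[dup_idx])].copy()
            extra_reacs = reacs_out[reacs_out["primary_id"].isin(primary_ids[dup_idx])].copy()
            pid_map = dict(zip(primary_ids[dup_idx], dup_pids))
            extra_drugs["primary_id"] = extra_drugs["primary_id"].map(pid_map)
            extra_reacs["primary_id"] = extra_reacs["primary_id"].map(pid_map)
            reports_df = pd.concat([reports_df, extra_rep], ignore_index=True)
            drugs_out = pd.concat([drugs_out, extra_drugs], ignore_index=True)
            reacs_out = pd.concat([reacs_out, extra_reacs], ignore_index=True)
            dup_rows = [
                {
                    "case_id": case_ids[i],
                    "original_primary_id": primary_ids[i],
                    "duplicate_primary_id": pid,
                }
                for i, pid in zip(dup_idx, dup_pids)
            ]

    provenance = {
        "generator_seed": config.seed,
        "reports_read": len(reports_df),
        "reports_kept": len(reports_df),
        "reports_dropped": 0,
        "n_original_reports": n,
        "n_duplicate_versions": len(dup_rows),
    }
    report_set = ReportSet(reports_df, drugs_out, reacs_out, provenance)

    duplicate_map = pd.DataFrame(
        dup_rows, columns=["case_id", "original_primary_id", "duplicate_primary_id"]
    )
    final_pid = pd.Series(primary_ids, copy=True)
    if len(duplicate_map):
        repl = dict(
            zip(duplicate_map["original_primary_id"], duplicate_map["duplicate_primary_id"])
        )
        final_pid = final_pid.map(lambda p: repl.get(p, p))
    per_report = pd.DataFrame(
        {
            "primary_id": primary_ids,
            "final_primary_id": final_pid.to_numpy(),
            "case_id": case_ids,
            "report_year": years,
            "age_years": ages,
            "sex": np.where(female, "F", "M"),
            "event": event,
            "p_event": p_event,
            "onset_drug": onset_drug,
            "true_duration": true_duration,
        }
    )
    for j, d in enumerate(config.drugs):
        per_report[f"exposed[{d.drug_code}]"] = exposure[:, j]
    effects = {
        "intercept": em.intercept,
        "year": em.year_slope,
        "age60": em.age60,
        "female": em.female,
    }
    for code, eff in em.drug_effects:
        effects[f"drug[{code}]"] = eff
    for term, eff in em.interactions:
        effects[term] = eff
    ledger = GroundTruthLedger(
        per_report=per_report,
        effects=effects,
        onset_params=dict(onset_params),
        duplicate_map=duplicate_map,
        config=config,
    )
    return report_set, ledger


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

_DOACS = ("apixaban", "rivaroxaban", "edoxaban", "dabigatran")


def scenario_presets(n_reports: int = 50_000, seed: int = 0) -> Dict[str, GeneratorConfig]:
    """Named generator configurations used across tests and examples.

    - "null": four study drugs, every effect log-odds zero (baseline event
      prevalence 10%); crude RORs are 1 in truth.
    - "paper_like": four anticoagulants with strong main-effect odds ratios
      (≈10–12), female×drug ratio-of-OR 1.5, age≥60 OR 2, female OR 1.2,
      age×sex OR 1.15, a mild secular trend, and per-drug Weibull onset
      profiles.  Anticoagulant exposures are mutually exclusive (these
      drugs are not co-prescribed).
    - "tto_profiles": drugs whose onset shapes span decreasing (β=0.7),
      constant (β=1) and increasing (β=1.5) hazards, with light date
      missingness so most latencies are usable.
    """
    drugs4 = tuple(DrugSpec(c, 0.05) for c in _DOACS)
    presets = {
        "null": GeneratorConfig(
            n_reports=n_reports,
            drugs=drugs4,
            event_model=EventModel(intercept=_logit(0.10)),
            duplicate_rate=0.0,
            seed=seed,
        ),
        "paper_like": GeneratorConfig(
            n_reports=n_reports,
            drugs=drugs4,
            exclusive_exposure=True,
            event_model=EventModel(
                intercept=_logit(0.03),
                year_slope=0.02,
                age60=math.log(2.0),
                female=math.log(1.2),
                drug_effects=(
                    ("apixaban", math.log(11.8)),
                    ("rivaroxaban", math.log(11.0)),
                    ("edoxaban", math.log(10.2)),
                    ("dabigatran", math.log(9.9)),
                ),
                interactions=(
                    ("age60:female", math.log(1.15)),
                    ("female:drug[apixaban]", math.log(1.5)),
                    ("female:drug[rivaroxaban]", math.log(1.5)),
                    ("female:drug[edoxaban]", math.log(1.5)),
                    ("female:drug[dabigatran]", math.log(1.5)),
                ),
            ),
            onset_model=(
                ("apixaban", (60.0, 0.9)),
                ("rivaroxaban", (90.0, 1.0)),
                ("edoxaban", (40.0, 0.8)),
                ("dabigatran", (70.0, 1.1)),
            ),
            duplicate_rate=0.05,
            seed=seed,
        ),
        "tto_profiles": GeneratorConfig(
            n_reports=n_reports,
            drugs=tuple(DrugSpec(c, 0.08) for c in ("wdec", "wconst", "winc")),
            exclusive_exposure=True,
            event_model=EventModel(
                intercept=_logit(0.05),
                drug_effects=(("wdec", math.log(8.0)), ("wconst", math.log(8.0)), ("winc", math.log(8.0))),
            ),
            onset_model=(
                ("wdec", (50.0, 0.7)),
                ("wconst", (50.0, 1.0)),
                ("winc", (50.0, 1.5)),
            ),
            missingness=(
                ("report_year", 0.02),
                ("age_years", 0.1),
                ("sex", 0.05),
                ("start_date", 0.05),
                ("onset_date", 0.05),
            ),
            seed=seed,
        ),
    }
    return presets


def get_preset(name: str, n_reports: int = 50_000, seed: int = 0) -> GeneratorConfig:
    presets = scenario_presets(n_reports=n_reports, seed=seed)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
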