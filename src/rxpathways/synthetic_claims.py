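"""Synthetic longitudinal claims with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for an elderly Parkinson's-disease claims cohort:

* an age-stratified population (30–100 y) with per-age-group comorbidity
  prevalences in a pre-index lookback window;
* a monthly Markov model over treatment patterns — an initial pattern
  (the levodopa-monotherapy-vs-other choice follows a logistic model in
  age, sex, and neuropsychiatric comorbidities, mirroring the factor
  analysis the pipeline performs) and a row-stochastic monthly transition
  matrix with geometric pattern durations;
* deterministic levodopa dose escalation toward an add-on threshold
  (default 300 mg/day): while the dose is below the threshold, add-on
  transitions out of a levodopa-containing pattern are damped by a
  configurable factor, so the modal dose at switching is the threshold by
  construction;
* enrollment censoring with a constant monthly hazard.

Every random draw comes from a named, per-patient substream of one seed
(`[seed, stream, patient_index]`), so enlarging the population never
reshuffles earlier patients' histories.

Default parameter values are illustrative, loosely calibrated to the
demographics of published Japanese PD claims cohorts; they are study
conditions for testing the pipeline, not estimates of any real
population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .claims_model import (
    ClaimsBundle,
    CodeLists,
    DiagnosisClaim,
    DrugClass,
    Patient,
    PrescriptionClaim,
    StudyConfig,
    default_codelists,
    parse_pattern_name,
    write_claims_tables,
)
from .util import add_months

_STREAM_POPULATION = 0
_STREAM_COMORBIDITY = 1
_STREAM_PATHWAY = 2
_STREAM_CENSOR = 3

# non-anti-PD codes used for concomitant-medication claims
_CONCOMITANT_CODES = ["A02BC01", "A06AB02", "B01AC06", "C07AB02", "M01AE01", "N05BA01"]

_AGE_GROUP_RANGES = {"<65": (30, 64), "65-74": (65, 74), "75-84": (75, 84), ">=85": (85, 99)}

_LOGIT_COVARIATES = ["age", "sex_male", "cognitive_disorder", "hallucination", "depression_anxiety"]


class SimParams(BaseModel):
    """All knobs of the generator; defaults are the standard study conditions."""

    n_patients: int = Field(ge=1)
    seed: int = Field(ge=0)
    study_start: date = date(2016, 6, 1)
    age_distribution: dict[str, float] = Field(
        default_factory=lambda: {"<65": 0.25, "65-74": 0.24, "75-84": 0.38, ">=85": 0.13}
    )
    sex_ratio_male: float = 0.476
    comorbidity_prevalence: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "constipation": {"<65": 0.20, "65-74": 0.28, "75-84": 0.52, ">=85": 0.56},
            "insomnia": {"<65": 0.16, "65-74": 0.19, "75-84": 0.30, ">=85": 0.31},
            "pain": {"<65": 0.14, "65-74": 0.18, "75-84": 0.35, ">=85": 0.36},
            "cognitive_disorder": {"<65": 0.02, "65-74": 0.05, "75-84": 0.14, ">=85": 0.17},
            "depression_anxiety": {"<65": 0.16, "65-74": 0.17, "75-84": 0.18, ">=85": 0.19},
            "hallucination": {"<65": 0.006, "65-74": 0.006, "75-84": 0.008, ">=85": 0.009},
        }
    )
    cci_condition_prevalence: dict[str, float] = Field(
        default_factory=lambda: {"diabetes": 0.20, "copd": 0.10, "congestive_heart_failure": 0.08}
    )
    concomitant_mean: float = 2.0  # Poisson mean of distinct non-anti-PD drugs
    initial_pattern_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "NE-DA": 0.45,
            "MAOBI": 0.20,
            "Anticholinergic": 0.10,
            "L-dopa+NE-DA": 0.15,
            "L-dopa+MAOBI": 0.10,
        }
    )
    monotherapy_logit: dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": -2.6,
            "age": 0.05,
            "sex_male": -0.16,
            "cognitive_disorder": 0.74,
            "hallucination": -0.87,
            "depression_anxiety": 0.03,
        }
    )
    monthly_transition_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "L-dopa": {
                "L-dopa": 0.93,
                "L-dopa+MAOBI": 0.030,
                "L-dopa+NE-DA": 0.025,
                "L-dopa+Zonisamide": 0.015,
            },
            "NE-DA": {"NE-DA": 0.94, "L-dopa+NE-DA": 0.04, "L-dopa": 0.02},
            "MAOBI": {"MAOBI": 0.95, "L-dopa+MAOBI": 0.05},
            "Anticholinergic": {"Anticholinergic": 0.97, "L-dopa": 0.03},
            "L-dopa+NE-DA": {"L-dopa+NE-DA": 0.97, "L-dopa+NE-DA+MAOBI": 0.03},
            "L-dopa+MAOBI": {"L-dopa+MAOBI": 0.97, "L-dopa+NE-DA+MAOBI": 0.03},
            "L-dopa+Zonisamide": {"L-dopa+Zonisamide": 1.0},
            "L-dopa+NE-DA+MAOBI": {"L-dopa+NE-DA+MAOBI": 1.0},
        }
    )
    dose_start_mg: float = 100.0
    dose_step_mg: float = 50.0
    dose_escalation_cycles: int = Field(default=1, ge=1)  # cycles per escalation step
    dose_add_on_mg: float = 300.0  # escalation ceiling and add-on trigger
    pre_threshold_addon_factor: float = 0.1  # damping of add-on transitions below the trigger
    rx_cycle_days: int = Field(default=30, ge=1)
    n_cycles: int = Field(default=36, ge=1)
    lookback_months: int = 6
    washout_slack_months: int = 6  # extra pre-index enrollment beyond the washout
    enroll_censor_rate: float = 0.01  # monthly probability of leaving the database

    @field_validator("sex_ratio_male", "enroll_censor_rate", "pre_threshold_addon_factor")
    @classmethod
    def _proportion(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _stochastic_rows(self) -> "SimParams":
        for name, dist in [("age_distribution", self.age_distribution),
                           ("initial_pattern_probs", self.initial_pattern_probs)]:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has a negative probability")
        for row_name, row in self.monthly_transition_probs.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row {row_name!r} must sum to 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"transition row {row_name!r} has a negative probability")
        for group in self.age_distribution:
            if group not in _AGE_GROUP_RANGES:
                raise ValueError(f"unknown age group label {group!r}")
        for prevs in self.comorbidity_prevalence.values():
            for p in prevs.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("prevalences must lie in [0, 1]")
        return self


@dataclass
class PatientLatent:
    """Per-patient latent state produced by the population stage."""

    patient: Patient
    index_date: date
    age: int
    age_group: str
    comorbidity_flags: dict[str, bool]
    covariates: dict[str, float]


@dataclass
class GroundTruth:
    """Latent record of the simulation, in the schema of the inference outputs."""

    pattern_sequences: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    initial_choice: dict[str, str] = field(default_factory=dict)
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    true_logit: dict[str, float] = field(default_factory=dict)
    true_transition: dict[str, dict[str, float]] = field(default_factory=dict)


def _rng(params: SimParams, stream: int, i: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream, i])


def _choice(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _first_code(codes: set[str]) -> str:
    return sorted(codes)[0]


def generate_population(
    params: SimParams,
    config: Optional[StudyConfig] = None,
    codelists: Optional[CodeLists] = None,
) -> tuple[list[PatientLatent], list[DiagnosisClaim]]:
    """Draw patients, enrollment intervals, and all diagnosis claims.

    Every patient gets a first G20-family claim inside enrollment (whose
    month floor is the intended index date), confirming PD claims every
    three months while enrolled, comorbidity claims placed uniformly in
    the lookback window at the configured per-age-group prevalence, and a
    censoring-determined enrollment end.
    """
    config = config or StudyConfig()
    codelists = codelists or default_codelists()
    pd_code = _first_code(codelists.pd_codes)

    latents: list[PatientLatent] = []
    dx_claims: list[DiagnosisClaim] = []
    horizon_days = params.n_cycles * params.rx_cycle_days

    for i in range(params.n_patients):
        rng_pop = _rng(params, _STREAM_POPULATION, i)
        rng_com = _rng(params, _STREAM_COMORBIDITY, i)
        rng_cen = _rng(params, _STREAM_CENSOR, i)
        pid = f"S{i:06d}"

        group = _choice(rng_pop, params.age_distribution)
        lo, hi = _AGE_GROUP_RANGES[group]
        age = int(rng_pop.integers(lo, hi + 1))
        sex = "male" if rng_pop.random() < params.sex_ratio_male else "female"
        source = "ELDERLY" if age >= 75 else ("JMDC" if rng_pop.random() < 0.7 else "NHI")

        index = add_months(params.study_start, int(rng_pop.integers(7, 19)))
        birth_ym = add_months(index, -(age * 12 + int(rng_pop.integers(0, 12))))
        washout = StudyConfig().washout_months if config is None else config.washout_months
        enroll_start = add_months(
            index, -(washout + 1 + int(rng_pop.integers(0, params.washout_slack_months)))
        )

        if params.enroll_censor_rate > 0:
            censor_months = int(rng_cen.geometric(params.enroll_censor_rate))
            enroll_end = min(index + timedelta(days=horizon_days), add_months(index, censor_months))
        else:
            enroll_end = index + timedelta(days=horizon_days)

        patient = Patient(
            patient_id=pid,
            sex=sex,
            birth_ym=birth_ym,
            source=source,
            enroll_start=enroll_start,
            enroll_end=enroll_end,
        )

        # first PD claim inside the index month, then confirmations quarterly
        first_pd = index + timedelta(days=int(rng_pop.integers(0, 28)))
        if first_pd > enroll_end:
            first_pd = index
        dx_claims.append(DiagnosisClaim(pid, pd_code, first_pd))
        confirm = first_pd + timedelta(days=90)
        while confirm <= enroll_end:
            dx_claims.append(DiagnosisClaim(pid, pd_code, confirm))
            confirm += timedelta(days=90)

        window_start = add_months(index, -params.lookback_months)
        span = (index - window_start).days
        flags: dict[str, bool] = {}
        for name in sorted(params.comorbidity_prevalence):
            prev = params.comorbidity_prevalence[name].get(group, 0.0)
            present = bool(rng_com.random() < prev)
            flags[name] = present
            if present and span > 0:
                day = window_start + timedelta(days=int(rng_com.integers(0, span)))
                dx_claims.append(
                    DiagnosisClaim(pid, _first_code(codelists.comorbidity_map[name]), day)
                )
        for name in sorted(params.cci_condition_prevalence):
            if rng_com.random() < params.cci_condition_prevalence[name] and span > 0:
                day = window_start + timedelta(days=int(rng_com.integers(0, span)))
                dx_claims.append(DiagnosisClaim(pid, _first_code(codelists.cci_map[name].codes), day))

        covariates = {
            "age": float(age),
            "sex_male": 1.0 if sex == "male" else 0.0,
            "cognitive_disorder": float(flags.get("cognitive_disorder", False)),
            "hallucination": float(flags.get("hallucination", False)),
            "depression_anxiety": float(flags.get("depression_anxiety", False)),
        }
        latents.append(PatientLatent(patient, index, age, group, flags, covariates))

    return latents, dx_claims


def _class_code_map(codelists: CodeLists) -> dict[DrugClass, str]:
    out: dict[DrugClass, str] = {}
    for code, cls in sorted(codelists.drug_class_map.items()):
        out.setdefault(cls, code)
    return out


def _adjusted_row(
    row: dict[str, float],
    current: str,
    dose_gate_open: bool,
    factor: float,
) -> dict[str, float]:
    """Damp add-on transitions while the levodopa dose is below the trigger.

    An add-on transition is one whose target class set strictly contains
    the current (levodopa-containing) set; the removed probability mass
    stays on the current pattern.
    """
    current_classes = parse_pattern_name(current)
    if dose_gate_open or DrugClass.LEVODOPA not in current_classes:
        return row
    adjusted: dict[str, float] = {}
    freed = 0.0
    for target, p in row.items():
        target_classes = parse_pattern_name(target)
        if target != current and target_classes > current_classes:
            adjusted[target] = p * factor
            freed += p * (1 - factor)
        else:
            adjusted[target] = p
    adjusted[current] = adjusted.get(current, 0.0) + freed
    return adjusted


def generate_prescriptions(
    latents: list[PatientLatent],
    params: SimParams,
    codelists: Optional[CodeLists] = None,
) -> tuple[list[PrescriptionClaim], GroundTruth]:
    """Emit prescription claims from the latent Markov pathway of each patient.

    Each active drug class yields one claim per cycle with
    ``days_supplied = rx_cycle_days``; levodopa claims carry the current
    escalating daily dose. The latent pattern sequence, the true logistic
    coefficients, and the true transition matrix are recorded as ground
    truth.
    """
    codelists = codelists or default_codelists()
    class_codes = _class_code_map(codelists)
    truth = GroundTruth(
        true_logit=dict(params.monotherapy_logit),
        true_transition={k: dict(v) for k, v in params.monthly_transition_probs.items()},
    )
    claims: list[PrescriptionClaim] = []

    for i, latent in enumerate(latents):
        rng = _rng(params, _STREAM_PATHWAY, i)
        pid = latent.patient.patient_id
        index = latent.index_date
        enroll_end = latent.patient.enroll_end

        logit = params.monotherapy_logit["intercept"] + sum(
            params.monotherapy_logit.get(k, 0.0) * latent.covariates[k] for k in _LOGIT_COVARIATES
        )
        p_mono = 1.0 / (1.0 + np.exp(-logit))
        if rng.random() < p_mono:
            pattern = "L-dopa"
            truth.initial_choice[pid] = "levodopa monotherapy"
        else:
            pattern = _choice(rng, params.initial_pattern_probs)
            truth.initial_choice[pid] = "other"
        truth.covariates[pid] = dict(latent.covariates)
        sequence: list[tuple[str, str]] = [(pattern, index.isoformat())]

        # concomitant (non-anti-PD) medication claims in the lookback window
        n_con = int(rng.poisson(params.concomitant_mean))
        window_start = add_months(index, -params.lookback_months)
        span = (index - window_start).days
        for code in rng.permutation(_CONCOMITANT_CODES)[: min(n_con, len(_CONCOMITANT_CODES))]:
            day = window_start + timedelta(days=int(rng.integers(0, max(span, 1))))
            if latent.patient.enroll_start <= day <= enroll_end:
                claims.append(PrescriptionClaim(pid, str(code), DrugClass.OTHER, day, 30))

        for t in range(params.n_cycles):
            dispense = index + timedelta(days=t * params.rx_cycle_days)
            if dispense > enroll_end:
                break
            dose = min(
                params.dose_start_mg + params.dose_step_mg * (t // params.dose_escalation_cycles),
                params.dose_add_on_mg,
            )
            for cls in sorted(parse_pattern_name(pattern), key=lambda c: c.name):
                claims.append(
                    PrescriptionClaim(
                        patient_id=pid,
                        drug_code=class_codes.get(cls, "UNMAPPED"),
                        drug_class=cls,
                        dispense_date=dispense,
                        days_supplied=params.rx_cycle_days,
                        daily_dose_mg=dose if cls is DrugClass.LEVODOPA else None,
                    )
                )
            next_date = index + timedelta(days=(t + 1) * params.rx_cycle_days)
            if t + 1 >= params.n_cycles or next_date > enroll_end:
                break  # no further observed cycle: the latent state stays as emitted
            row = params.monthly_transition_probs.get(pattern, {pattern: 1.0})
            row = _adjusted_row(
                row, pattern, dose >= params.dose_add_on_mg, params.pre_threshold_addon_factor
            )
            nxt = _choice(rng, row)
            if nxt != pattern:
                sequence.append((nxt, next_date.isoformat()))
            pattern = nxt
        truth.pattern_sequences[pid] = sequence

    claims.sort(key=lambda c: (c.patient_id, c.dispense_date, c.drug_class.name))
    return claims, truth


def ground_truth_summary(truth: GroundTruth) -> dict:
    """True quantities in the schema of the inference outputs.

    Coefficients are exponentiated to odds ratios so they compare
    field-by-field with the logistic-stage output; transition rows are
    row-stochastic by construction.
    """
    return {
        "odds_ratios": {
            k: float(np.exp(v)) for k, v in truth.true_logit.items() if k != "intercept"
        },
        "transition_matrix": {k: dict(v) for k, v in truth.true_transition.items()},
        "n_patients": len(truth.pattern_sequences),
        "initial_levodopa_monotherapy_fraction": (
            sum(1 for v in truth.initial_choice.values() if v == "levodopa monotherapy")
            / len(truth.initial_choice)
            if truth.initial_choice
            else None
        ),
    }


def simulate(
    params: SimParams,
    config: Optional[StudyConfig] = None,
    codelists: Optional[CodeLists] = None,
) -> tuple[ClaimsBundle, GroundTruth]:
    """Run both stages and assemble a ready-to-analyse claims bundle."""
    config = config or StudyConfig()
    codelists = codelists or default_codelists()
    latents, dx_claims = generate_population(params, config, codelists)
    rx_claims, truth = generate_prescriptions(latents, params, codelists)
    bundle = ClaimsBundle(
        patients=[l.patient for l in latents],
        diagnoses=sorted(dx_claims, key=lambda c: (c.patient_id, c.claim_date, c.icd10_code)),
        prescriptions=rx_claims,
    )
    return bundle, truth


def write_simulation(params: SimParams, out_dir: str | Path,
                     config: Optional[StudyConfig] = None,
                     codelists: Optional[CodeLists] = None) -> dict[str, Path]:
    """Write the three claims tables plus ``ground_truth.json``."""
    bundle, truth = simulate(params, config, codelists)
    paths = write_claims_tables(bundle, out_dir)
    gt_path = Path(out_dir) / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                "summary": ground_truth_summary(truth),
                "pattern_sequences": truth.pattern_sequences,
                "initial_choice": truth.initial_choice,
            },
            indent=2,
        )
    )
    paths["ground_truth"] = gt_path
    return paths
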