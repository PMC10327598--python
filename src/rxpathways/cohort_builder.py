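"""Cohort construction: index dates, eligibility, new-initiator flags, age groups.

The index date is the first day of the month of a patient's first
qualifying diagnosis claim; it anchors every window in the study. A
patient enters the analysis cohort when, at index, they are old enough,
have a later confirming diagnosis claim (>= 6 months after index), have
at least one anti-PD prescription within the first 6 months of follow-up,
and at least two anti-PD prescriptions during the whole observation
period. Patients who additionally show a clean 6-month pre-index washout
(no anti-PD prescription, no drug-induced/vascular parkinsonism code)
are flagged as new initiators of treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

import pandas as pd

from .claims_model import (
    ClaimsBundle,
    CodeLists,
    DiagnosisClaim,
    Patient,
    PrescriptionClaim,
    StudyConfig,
    code_matches,
    is_anti_pd,
)
from .util import add_months, month_floor


@dataclass
class CohortRecord:
    patient_id: str
    index_date: Optional[date]
    age_at_index: Optional[int]
    age_group: Optional[str]
    age_group_coarse: Optional[str]
    new_initiator: bool
    observation_end: Optional[date]
    eligible: bool
    exclusion_reasons: list[str] = field(default_factory=list)


def compute_index_date(
    dx_claims: Iterable[DiagnosisClaim], codelists: CodeLists
) -> Optional[date]:
    """Month-floor of the earliest qualifying diagnosis claim; None if absent.

    Order-independent: the claims may arrive in any order.
    """
    pd_dates = [c.claim_date for c in dx_claims if code_matches(c.icd10_code, codelists.pd_codes)]
    if not pd_dates:
        return None
    return month_floor(min(pd_dates))


def age_at_index(birth_ym: date, index_date: date) -> int:
    """Completed years of age at the index month (month precision, floored)."""
    months = (index_date.year - birth_ym.year) * 12 + (index_date.month - birth_ym.month)
    return months // 12


def assign_age_group(age: int, config: StudyConfig) -> tuple[str, str]:
    """Half-open binning on the configured bounds plus the coarse elderly split."""
    if age < 0:
        raise ValueError("age must be non-negative")
    bounds = config.age_group_bounds
    if age < bounds[0]:
        fine = f"<{bounds[0]}"
    elif age >= bounds[-1]:
        fine = f">={bounds[-1]}"
    else:
        for lo, hi in zip(bounds, bounds[1:]):
            if lo <= age < hi:
                fine = f"{lo}-{hi - 1}"
                break
    coarse = (
        f">={config.elderly_cutoff_years}"
        if age >= config.elderly_cutoff_years
        else f"<{config.elderly_cutoff_years}"
    )
    return fine, coarse


def apply_inclusion_criteria(
    patient: Patient,
    dx_claims: Sequence[DiagnosisClaim],
    rx_claims: Sequence[PrescriptionClaim],
    config: StudyConfig,
    codelists: CodeLists,
    data_cutoff: Optional[date] = None,
) -> CohortRecord:
    """Evaluate every inclusion criterion and record each failure reason.

    Reason codes: ``no_pd_claim``, ``age``, ``pd_followup`` (no confirming
    diagnosis claim >= ``min_followup_months`` after index), ``rx_within_followup``
    (no anti-PD prescription inside the first follow-up window), ``rx_count``
    (< 2 anti-PD prescriptions in the observation period).
    """
    index = compute_index_date(dx_claims, codelists)
    observation_end = patient.enroll_end if data_cutoff is None else min(patient.enroll_end, data_cutoff)
    if index is None:
        return CohortRecord(
            patient_id=patient.patient_id,
            index_date=None,
            age_at_index=None,
            age_group=None,
            age_group_coarse=None,
            new_initiator=False,
            observation_end=observation_end,
            eligible=False,
            exclusion_reasons=["no_pd_claim"],
        )

    age = age_at_index(patient.birth_ym, index)
    fine, coarse = assign_age_group(age, config)
    reasons: list[str] = []

    if age < config.min_age_years:
        reasons.append("age")

    followup_cut = add_months(index, config.min_followup_months)
    has_late_pd = any(
        code_matches(c.icd10_code, codelists.pd_codes) and c.claim_date >= followup_cut
        for c in dx_claims
    )
    if not has_late_pd:
        reasons.append("pd_followup")

    anti_pd_rx = [c for c in rx_claims if is_anti_pd(c.drug_class)]
    if not any(index <= c.dispense_date < followup_cut for c in anti_pd_rx):
        reasons.append("rx_within_followup")

    n_rx_obs = sum(1 for c in anti_pd_rx if index <= c.dispense_date <= observation_end)
    if n_rx_obs < 2:
        reasons.append("rx_count")

    record = CohortRecord(
        patient_id=patient.patient_id,
        index_date=index,
        age_at_index=age,
        age_group=fine,
        age_group_coarse=coarse,
        new_initiator=False,
        observation_end=observation_end,
        eligible=not reasons,
        exclusion_reasons=reasons,
    )
    if record.eligible:
        record.new_initiator = flag_new_initiator(
            patient, rx_claims, dx_claims, index, config, codelists
        )
    return record


def flag_new_initiator(
    patient: Patient,
    rx_claims: Iterable[PrescriptionClaim],
    dx_claims: Iterable[DiagnosisClaim],
    index_date: date,
    config: StudyConfig,
    codelists: CodeLists,
) -> bool:
    """True when the patient demonstrably starts anti-PD treatment at index.

    Requires enough pre-index enrollment to observe the washout, no
    anti-PD prescription before index, and no exclusionary parkinsonism
    diagnosis in the washout window.
    """
    if add_months(patient.enroll_start, config.washout_months) > index_date:
        return False
    if any(
        is_anti_pd(c.drug_class) and patient.enroll_start <= c.dispense_date < index_date
        for c in rx_claims
    ):
        return False
    window_start = add_months(index_date, -config.washout_months)
    if any(
        code_matches(c.icd10_code, codelists.exclusion_codes)
        and window_start <= c.claim_date < index_date
        for c in dx_claims
    ):
        return False
    return True


def compute_prevalence(n_eligible_in_group: int, n_insured_in_group: int) -> float:
    """Period prevalence per 100 insured people."""
    if n_insured_in_group <= 0:
        raise ValueError("denominator must be positive")
    if n_eligible_in_group > n_insured_in_group:
        raise ValueError("eligible count exceeds insured population")
    return 100.0 * n_eligible_in_group / n_insured_in_group


def build_cohort(
    bundle: ClaimsBundle,
    config: StudyConfig,
    codelists: CodeLists,
    data_cutoff: Optional[date] = None,
) -> list[CohortRecord]:
    """Apply the inclusion criteria to every patient in the bundle."""
    dx_by_pid: dict[str, list[DiagnosisClaim]] = {}
    for c in bundle.diagnoses:
        dx_by_pid.setdefault(c.patient_id, []).append(c)
    rx_by_pid: dict[str, list[PrescriptionClaim]] = {}
    for c in bundle.prescriptions:
        rx_by_pid.setdefault(c.patient_id, []).append(c)
    return [
        apply_inclusion_criteria(
            p, dx_by_pid.get(p.patient_id, []), rx_by_pid.get(p.patient_id, []),
            config, codelists, data_cutoff,
        )
        for p in bundle.patients
    ]


def cohort_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tabulate cohort records for ``cohort.csv``."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "index_date": r.index_date.isoformat() if r.index_date else "",
                "age_at_index": "" if r.age_at_index is None else r.age_at_index,
                "age_group": r.age_group or "",
                "age_group_coarse": r.age_group_coarse or "",
                "new_initiator": r.new_initiator,
                "observation_end": r.observation_end.isoformat() if r.observation_end else "",
                "eligible": r.eligible,
                "exclusion_reasons": ";".join(r.exclusion_reasons),
            }
            for r in records
        ],
        columns=[
            "patient_id",
            "index_date",
            "age_at_index",
            "age_group",
            "age_group_coarse",
            "new_initiator",
            "observation_end",
            "eligible",
            "exclusion_reasons",
        ],
    )
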