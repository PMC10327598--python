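"""Comorbidity screening, Charlson Comorbidity Index, concomitant-drug counts.

Comorbidities are screened as simple code-list membership among diagnosis
claims in a lookback window strictly before the index date. The CCI is
the weighted sum of flagged Charlson conditions, with hierarchy rules
applied first (a severe form supersedes its mild form so the pair never
double-counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping

import pandas as pd

from .claims_model import (
    CodeLists,
    DiagnosisClaim,
    DrugClass,
    PrescriptionClaim,
    StudyConfig,
    code_matches,
)
from .util import add_months


@dataclass
class ComorbidityProfile:
    patient_id: str
    flags: dict[str, bool]
    cci_flags: dict[str, bool]
    cci: int
    n_concomitant_categories: int


def screen_code_map(
    dx_claims: Iterable[DiagnosisClaim],
    code_map: Mapping[str, set[str]],
    index_date: date,
    lookback_months: int,
) -> dict[str, bool]:
    """Flag each named condition with >=1 claim in ``[index - lookback, index)``."""
    window_start = add_months(index_date, -lookback_months)
    in_window = [c for c in dx_claims if window_start <= c.claim_date < index_date]
    return {
        name: any(code_matches(c.icd10_code, codes) for c in in_window)
        for name, codes in code_map.items()
    }


def screen_comorbidities(
    dx_claims: Iterable[DiagnosisClaim],
    index_date: date,
    config: StudyConfig,
    codelists: CodeLists,
) -> dict[str, bool]:
    """Presence/absence of each configured comorbidity in the lookback window."""
    return screen_code_map(
        dx_claims, codelists.comorbidity_map, index_date, config.comorbidity_lookback_months
    )


def compute_cci(flags: Mapping[str, bool], codelists: CodeLists) -> int:
    """Weighted sum of present Charlson conditions after hierarchy resolution.

    Raises a configuration error when a flagged condition has no weight.
    """
    effective = dict(flags)
    for mild, severe in codelists.cci_hierarchy.items():
        if effective.get(mild) and effective.get(severe):
            effective[mild] = False
    total = 0
    for name, present in effective.items():
        if not present:
            continue
        if name not in codelists.cci_map:
            raise KeyError(f"no CCI weight configured for flagged condition {name!r}")
        total += codelists.cci_map[name].weight
    return total


def count_concomitant_drugs(
    rx_claims: Iterable[PrescriptionClaim],
    index_date: date,
    config: StudyConfig,
) -> int:
    """Distinct ATC top-level categories among non-anti-PD prescriptions.

    Counted in the comorbidity lookback window; the top-level category is
    the first (anatomical main group) letter of the drug code.
    """
    window_start = add_months(index_date, -config.comorbidity_lookback_months)
    cats = {
        c.drug_code[:1].upper()
        for c in rx_claims
        if c.drug_class is DrugClass.OTHER
        and c.drug_code
        and window_start <= c.dispense_date < index_date
    }
    return len(cats)


def profile_patient(
    patient_id: str,
    dx_claims: Iterable[DiagnosisClaim],
    rx_claims: Iterable[PrescriptionClaim],
    index_date: date,
    config: StudyConfig,
    codelists: CodeLists,
) -> ComorbidityProfile:
    dx_claims = list(dx_claims)
    flags = screen_comorbidities(dx_claims, index_date, config, codelists)
    cci_flags = screen_code_map(
        dx_claims,
        {name: entry.codes for name, entry in codelists.cci_map.items()},
        index_date,
        config.comorbidity_lookback_months,
    )
    return ComorbidityProfile(
        patient_id=patient_id,
        flags=flags,
        cci_flags=cci_flags,
        cci=compute_cci(cci_flags, codelists),
        n_concomitant_categories=count_concomitant_drugs(rx_claims, index_date, config),
    )


def profiles_frame(profiles: Iterable[ComorbidityProfile]) -> pd.DataFrame:
    """Tabulate profiles for ``comorbidity.csv`` (one flag column per comorbidity)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"patient_id": p.patient_id}
        row.update({name: flag for name, flag in sorted(p.flags.items())})
        row["cci"] = p.cci
        row["n_concomitant_categories"] = p.n_concomitant_categories
        rows.append(row)
    return pd.DataFrame(rows)
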