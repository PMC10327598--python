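"""Domain types, study configuration, code lists, and claims-table I/O.

The analysis operates on three longitudinal claims tables (patients,
diagnosis claims, prescription claims) plus a configuration object that
holds every numeric rule of the study design and the code lists used to
classify diagnoses and drugs.

Conventions used throughout the package
---------------------------------------
* Dates are day-resolution :class:`datetime.date`; month-level quantities
  (birth month, index date) are represented as the first day of the month.
* All intervals are half-open ``[start, end)``.
* ICD-10 membership is prefix-based: a claim code matches a configured
  code if it equals it or extends it (``G20.1`` matches ``G20``).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .util import parse_iso_date


class ClaimsFormatError(ValueError):
    """A claims table is structurally invalid (e.g. a required column is missing)."""


# ---------------------------------------------------------------------------
# Drug classes
# ---------------------------------------------------------------------------


class DrugClass(enum.Enum):
    """Anti-parkinsonian drug classes, in canonical display order.

    The enum order is the canonical sort order used when rendering a
    combination pattern name, so node identities in transition networks
    are stable.
    """

    LEVODOPA = "L-dopa"
    NON_ERGOT_DA = "NE-DA"
    ERGOT_DA = "E-DA"
    MAOB_INHIBITOR = "MAOBI"
    COMT_INHIBITOR = "COMTI"
    ZONISAMIDE = "Zonisamide"
    AMANTADINE = "Amantadine"
    DROXIDOPA = "Droxidopa"
    ANTICHOLINERGIC = "Anticholinergic"
    ISTRADEFYLLINE = "Istradefylline"
    OTHER = "Other"


_CLASS_ORDER = {c: i for i, c in enumerate(DrugClass)}
_LABEL_TO_CLASS = {c.value: c for c in DrugClass}


def is_anti_pd(drug_class: DrugClass) -> bool:
    """True for every anti-PD class, i.e. everything except ``OTHER``."""
    return drug_class is not DrugClass.OTHER


def pattern_name(classes: Iterable[DrugClass]) -> str:
    """Render a set of classes as a stable ``+``-joined pattern label."""
    ordered = sorted(set(classes), key=_CLASS_ORDER.__getitem__)
    return "+".join(c.value for c in ordered) if ordered else "(none)"


def parse_pattern_name(name: str) -> frozenset[DrugClass]:
    """Inverse of :func:`pattern_name` (``"(none)"`` maps to the empty set)."""
    if name == "(none)":
        return frozenset()
    try:
        return frozenset(_LABEL_TO_CLASS[part] for part in name.split("+"))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown drug-class label in pattern {name!r}") from exc


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


class StudyConfig(BaseModel):
    """Every numeric rule of the study design in one validated object.

    Defaults encode the new-user claims design this package implements:
    adults (>=30 y) indexed at the month of their first qualifying
    diagnosis claim, a 6-month washout for the new-initiator flag, a
    6-month comorbidity lookback, 90-day grace gaps when building drug
    exposure episodes, >=7-day regimen patterns, transition-network edges
    kept at >=2% of the group, and a 300 mg/day levodopa dose of interest
    for the dose-at-switch analysis.
    """

    min_age_years: int = 30
    washout_months: int = 6
    min_followup_months: int = 6
    comorbidity_lookback_months: int = 6
    grace_days: int = 90
    min_pattern_days: int = 7
    edge_fraction_threshold: float = 0.02
    dose_focus_mg: float = 300.0
    age_group_bounds: list[int] = Field(default_factory=lambda: [65, 75, 85])
    elderly_cutoff_years: int = 75
    # behaviour switches (each documents the alternative reading of a rule)
    grace_inclusive: bool = True  # gap == grace_days merges when True
    short_run_as_gap: bool = False  # sub-threshold runs split instead of merge
    edge_count_events: bool = False  # count transition events, not patients

    @field_validator(
        "min_age_years",
        "washout_months",
        "min_followup_months",
        "comorbidity_lookback_months",
        "grace_days",
        "min_pattern_days",
        "elderly_cutoff_years",
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("count parameters must be > 0")
        return v

    @field_validator("edge_fraction_threshold")
    @classmethod
    def _proportion(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("edge_fraction_threshold must be in (0, 1)")
        return v

    @field_validator("age_group_bounds")
    @classmethod
    def _increasing(cls, v: list[int]) -> list[int]:
        if any(b >= a for b, a in zip(v, v[1:])):
            raise ValueError("age_group_bounds must be strictly increasing")
        return v


class CciEntry(BaseModel):
    codes: set[str]
    weight: int = Field(ge=1)


class CodeLists(BaseModel):
    """Configurable ICD-10 / drug-code lists driving every classification step.

    ``cci_hierarchy`` maps a mild condition to its severe form; when both
    are flagged only the severe form contributes to the Charlson score.
    """

    pd_codes: set[str]
    exclusion_codes: set[str]
    comorbidity_map: dict[str, set[str]]
    cci_map: dict[str, CciEntry]
    cci_hierarchy: dict[str, str] = Field(default_factory=dict)
    drug_class_map: dict[str, DrugClass]

    @model_validator(mode="after")
    def _check(self) -> "CodeLists":
        for mild, severe in self.cci_hierarchy.items():
            if mild not in self.cci_map or severe not in self.cci_map:
                raise ValueError(f"hierarchy pair ({mild}, {severe}) not in cci_map")
        return self


def code_matches(code: str, codeset: Iterable[str]) -> bool:
    """Prefix membership test for ICD-10-style codes."""
    return any(code.startswith(c) for c in codeset)


def map_drug_class(drug_code: str, codelists: CodeLists) -> DrugClass:
    """Classify a drug code; total function, unmapped codes are ``OTHER``.

    Exact matches win; otherwise the longest configured code that is a
    prefix of ``drug_code`` decides (ATC codes are hierarchical).
    """
    m = codelists.drug_class_map
    if drug_code in m:
        return m[drug_code]
    best: Optional[str] = None
    for key in m:
        if drug_code.startswith(key) and (best is None or len(key) > len(best)):
            best = key
    return m[best] if best is not None else DrugClass.OTHER


def default_codelists() -> CodeLists:
    """A plausible default code map for demonstration and simulation.

    The drug-class map uses ATC-style codes for the drugs approved for
    Parkinson's disease in Japan; it is an illustrative stand-in, NOT a
    validated national receipt-code dictionary, and should be replaced
    with a site-specific list for any real analysis. The Charlson weights
    follow the updated ICD-10 claims weighting (Quan et al.).
    """
    return CodeLists(
        pd_codes={"G20"},
        exclusion_codes={"G21.0", "G21.1", "G21.4"},  # drug-induced / vascular parkinsonism
        comorbidity_map={
            "constipation": {"K59.0"},
            "insomnia": {"G47.0", "F51.0"},
            "pain": {"R52", "M79.6"},
            "cognitive_disorder": {"F00", "F01", "F02", "F03", "G30"},
            "depression_anxiety": {"F32", "F33", "F41"},
            "hallucination": {"R44.0", "R44.1", "F06.0"},
        },
        cci_map={
            "myocardial_infarction": CciEntry(codes={"I21", "I22", "I25.2"}, weight=1),
            "congestive_heart_failure": CciEntry(codes={"I50"}, weight=2),
            "peripheral_vascular_disease": CciEntry(codes={"I70", "I71"}, weight=1),
            "cerebrovascular_disease": CciEntry(codes={"I60", "I61", "I63", "G45"}, weight=1),
            "dementia": CciEntry(codes={"F00", "F01", "F02", "F03", "G30"}, weight=2),
            "copd": CciEntry(codes={"J43", "J44"}, weight=1),
            "rheumatic_disease": CciEntry(codes={"M05", "M06"}, weight=1),
            "mild_liver_disease": CciEntry(codes={"K70.0", "K73", "K74"}, weight=2),
            "severe_liver_disease": CciEntry(codes={"K72.1", "K72.9", "K76.6"}, weight=4),
            "diabetes": CciEntry(codes={"E10.9", "E11.9"}, weight=1),
            "diabetes_with_complication": CciEntry(codes={"E10.2", "E11.2", "E10.3", "E11.3"}, weight=1),
            "renal_disease": CciEntry(codes={"N18", "N19"}, weight=1),
            "any_malignancy": CciEntry(codes={"C18", "C34", "C50", "C61"}, weight=2),
            "metastatic_tumor": CciEntry(codes={"C77", "C78", "C79", "C80"}, weight=6),
            "aids": CciEntry(codes={"B20", "B21", "B22", "B24"}, weight=4),
        },
        cci_hierarchy={
            "mild_liver_disease": "severe_liver_disease",
            "diabetes": "diabetes_with_complication",
            "any_malignancy": "metastatic_tumor",
        },
        drug_class_map={
            # levodopa / levodopa-decarboxylase-inhibitor combinations
            "N04BA01": DrugClass.LEVODOPA,
            "N04BA02": DrugClass.LEVODOPA,
            "N04BA03": DrugClass.LEVODOPA,
            # non-ergot dopamine agonists
            "N04BC04": DrugClass.NON_ERGOT_DA,  # ropinirole
            "N04BC05": DrugClass.NON_ERGOT_DA,  # pramipexole
            "N04BC07": DrugClass.NON_ERGOT_DA,  # apomorphine
            "N04BC09": DrugClass.NON_ERGOT_DA,  # rotigotine
            # ergot dopamine agonists
            "N04BC01": DrugClass.ERGOT_DA,  # bromocriptine
            "N04BC02": DrugClass.ERGOT_DA,  # pergolide
            "N04BC06": DrugClass.ERGOT_DA,  # cabergoline
            # MAO-B inhibitors
            "N04BD01": DrugClass.MAOB_INHIBITOR,  # selegiline
            "N04BD02": DrugClass.MAOB_INHIBITOR,  # rasagiline
            "N04BD03": DrugClass.MAOB_INHIBITOR,  # safinamide
            # COMT inhibitors
            "N04BX02": DrugClass.COMT_INHIBITOR,  # entacapone
            "N04BX04": DrugClass.COMT_INHIBITOR,  # opicapone
            "N03AX15": DrugClass.ZONISAMIDE,
            "N04BB01": DrugClass.AMANTADINE,
            "C01CA21": DrugClass.DROXIDOPA,
            "N04AA01": DrugClass.ANTICHOLINERGIC,  # trihexyphenidyl
            "N04AA02": DrugClass.ANTICHOLINERGIC,  # biperiden
            "N04CX01": DrugClass.ISTRADEFYLLINE,
        },
    )


def load_config(path: str | Path) -> tuple[StudyConfig, CodeLists]:
    """Read one JSON config file with ``study`` and ``codelists`` sections.

    Either section may be omitted, in which case the defaults are used.
    """
    raw = json.loads(Path(path).read_text())
    config = StudyConfig(**raw.get("study", {}))
    if "codelists" in raw:
        codelists = CodeLists(**raw["codelists"])
    else:
        codelists = default_codelists()
    return config, codelists


def dump_default_config(path: str | Path) -> None:
    """Write the default configuration (editable schema example) to ``path``."""
    payload = {
        "study": StudyConfig().model_dump(),
        "codelists": json.loads(default_codelists().model_dump_json()),
    }

    def _setify(obj):  # sets serialise as lists; keep deterministic order
        if isinstance(obj, dict):
            return {k: _setify(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return sorted(obj) if all(isinstance(x, str) for x in obj) else obj
        return obj

    Path(path).write_text(json.dumps(_setify(payload), indent=2, default=sorted))


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass
class Patient:
    patient_id: str
    sex: str  # "male" | "female"
    birth_ym: date  # first day of birth month
    source: str  # "ELDERLY" | "JMDC" | "NHI"
    enroll_start: date
    enroll_end: date
    has_dbs_or_lcig: bool = False

    def __post_init__(self) -> None:
        if self.enroll_start > self.enroll_end:
            raise ValueError(f"{self.patient_id}: enroll_start after enroll_end")


@dataclass
class DiagnosisClaim:
    patient_id: str
    icd10_code: str
    claim_date: date


@dataclass
class PrescriptionClaim:
    patient_id: str
    drug_code: str
    drug_class: DrugClass
    dispense_date: date
    days_supplied: int
    daily_dose_mg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.days_supplied < 1:
            raise ValueError("days_supplied must be >= 1")
        if self.daily_dose_mg is not None and self.drug_class is not DrugClass.LEVODOPA:
            raise ValueError("daily_dose_mg is only meaningful for levodopa claims")


@dataclass
class LoadReport:
    """Bookkeeping for one bundle load; accepted + rejected = input rows per table."""

    n_input: dict[str, int] = field(default_factory=dict)
    n_accepted: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    n_unmapped_codes: int = 0
    n_dose_cleared: int = 0

    def n_rejected(self, table: str) -> int:
        return len(self.rejected.get(table, []))


@dataclass
class ClaimsBundle:
    patients: list[Patient]
    diagnoses: list[DiagnosisClaim]
    prescriptions: list[PrescriptionClaim]
    load_report: LoadReport = field(default_factory=LoadReport)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["patient_id", "sex", "birth_ym", "source", "enroll_start", "enroll_end"]
DX_COLUMNS = ["patient_id", "icd10_code", "claim_date"]
RX_COLUMNS = ["patient_id", "drug_code", "dispense_date", "days_supplied"]


def _read_table(path: str | Path, required: Sequence[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ClaimsFormatError(f"{name} table {path}: missing required column {col!r}")
    return df


def read_claims_tables(
    patient_path: str | Path,
    dx_path: str | Path,
    rx_path: str | Path,
    codelists: CodeLists,
) -> ClaimsBundle:
    """Load and validate the three claims tables into a :class:`ClaimsBundle`.

    Delimiter is sniffed (comma or tab). Rows violating an invariant
    (unparseable date, ``days_supplied`` < 1, inverted enrollment) are
    rejected and listed with their line number in the load report; drug
    codes missing from the class map are retained with class ``OTHER``
    and counted.
    """
    report = LoadReport()

    patients: list[Patient] = []
    pdf = _read_table(patient_path, PATIENT_COLUMNS, "patients")
    report.n_input["patients"] = len(pdf)
    report.rejected["patients"] = []
    for i, row in enumerate(pdf.itertuples(index=False), start=2):  # header is line 1
        try:
            patients.append(
                Patient(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    birth_ym=parse_iso_date(row.birth_ym).replace(day=1),
                    source=row.source,
                    enroll_start=parse_iso_date(row.enroll_start),
                    enroll_end=parse_iso_date(row.enroll_end),
                    has_dbs_or_lcig=str(getattr(row, "has_dbs_or_lcig", "false")).lower()
                    in {"1", "true", "yes"},
                )
            )
        except (ValueError, TypeError) as exc:
            report.rejected["patients"].append((i, str(exc)))
    report.n_accepted["patients"] = len(patients)

    diagnoses: list[DiagnosisClaim] = []
    ddf = _read_table(dx_path, DX_COLUMNS, "diagnoses")
    report.n_input["diagnoses"] = len(ddf)
    report.rejected["diagnoses"] = []
    for i, row in enumerate(ddf.itertuples(index=False), start=2):
        try:
            diagnoses.append(
                DiagnosisClaim(row.patient_id, row.icd10_code, parse_iso_date(row.claim_date))
            )
        except (ValueError, TypeError) as exc:
            report.rejected["diagnoses"].append((i, str(exc)))
    report.n_accepted["diagnoses"] = len(diagnoses)

    prescriptions: list[PrescriptionClaim] = []
    rdf = _read_table(rx_path, RX_COLUMNS, "prescriptions")
    report.n_input["prescriptions"] = len(rdf)
    report.rejected["prescriptions"] = []
    for i, row in enumerate(rdf.itertuples(index=False), start=2):
        try:
            drug_class = map_drug_class(row.drug_code, codelists)
            if drug_class is DrugClass.OTHER:
                report.n_unmapped_codes += 1
            dose_raw = getattr(row, "daily_dose_mg", "")
            dose = float(dose_raw) if dose_raw not in ("", None) else None
            if dose is not None and drug_class is not DrugClass.LEVODOPA:
                dose = None
                report.n_dose_cleared += 1
            prescriptions.append(
                PrescriptionClaim(
                    patient_id=row.patient_id,
                    drug_code=row.drug_code,
                    drug_class=drug_class,
                    dispense_date=parse_iso_date(row.dispense_date),
                    days_supplied=int(row.days_supplied),
                    daily_dose_mg=dose,
                )
            )
        except (ValueError, TypeError) as exc:
            report.rejected["prescriptions"].append((i, str(exc)))
    report.n_accepted["prescriptions"] = len(prescriptions)

    return ClaimsBundle(patients, diagnoses, prescriptions, report)


def write_claims_tables(bundle: ClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle back to ``patients.csv`` / ``diagnoses.csv`` / ``prescriptions.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "diagnoses": out / "diagnoses.csv",
        "prescriptions": out / "prescriptions.csv",
    }
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_ym": p.birth_ym.isoformat(),
                "source": p.source,
                "enroll_start": p.enroll_start.isoformat(),
                "enroll_end": p.enroll_end.isoformat(),
                "has_dbs_or_lcig": str(p.has_dbs_or_lcig).lower(),
            }
            for p in bundle.patients
        ],
        columns=PATIENT_COLUMNS + ["has_dbs_or_lcig"],
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [
            {"patient_id": d.patient_id, "icd10_code": d.icd10_code, "claim_date": d.claim_date.isoformat()}
            for d in bundle.diagnoses
        ],
        columns=DX_COLUMNS,
    ).to_csv(paths["diagnoses"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "drug_code": r.drug_code,
                "dispense_date": r.dispense_date.isoformat(),
                "days_supplied": r.days_supplied,
                "daily_dose_mg": "" if r.daily_dose_mg is None else r.daily_dose_mg,
            }
            for r in bundle.prescriptions
        ],
        columns=RX_COLUMNS + ["daily_dose_mg"],
    ).to_csv(paths["prescriptions"], index=False)
    return paths
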