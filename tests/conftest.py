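from __future__ import annotations

from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pytest

from rxpathways import (
    DrugClass,
    PrescriptionClaim,
    StudyConfig,
    default_codelists,
)

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"
GOLDEN_DIR = Path(__file__).parent / "data" / "fixture_golden"

EPOCH = date(2018, 1, 1)


def day(n: int) -> date:
    """Fixture shorthand: day n of an arbitrary calendar."""
    return EPOCH + timedelta(days=n)


def rx(
    offset: int,
    days_supplied: int,
    drug_class: DrugClass = DrugClass.LEVODOPA,
    pid: str = "P",
    dose: float | None = None,
    code: str = "X",
) -> PrescriptionClaim:
    return PrescriptionClaim(
        patient_id=pid,
        drug_code=code,
        drug_class=drug_class,
        dispense_date=day(offset),
        days_supplied=days_supplied,
        daily_dose_mg=dose if drug_class is DrugClass.LEVODOPA else None,
    )


def random_claims(rng: np.random.Generator, drug_class=DrugClass.LEVODOPA, max_claims: int = 8):
    """A random single-patient, single-class claim set for oracle checks."""
    n = int(rng.integers(1, max_claims + 1))
    claims = []
    for _ in range(n):
        start = int(rng.integers(0, 400))
        supply = int(rng.integers(1, 61))
        claims.append(rx(start, supply, drug_class))
    return claims


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def codelists():
    return default_codelists()


@pytest.fixture(scope="session")
def fixture_paths() -> dict[str, Path]:
    return {
        "patients": FIXTURE_DIR / "patients.csv",
        "diagnoses": FIXTURE_DIR / "diagnoses.csv",
        "prescriptions": FIXTURE_DIR / "prescriptions.csv",
    }


@pytest.fixture(scope="session")
def fixture_bundle(fixture_paths, codelists):
    from rxpathways import read_claims_tables

    return read_claims_tables(
        fixture_paths["patients"],
        fixture_paths["diagnoses"],
        fixture_paths["prescriptions"],
        codelists,
    )
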