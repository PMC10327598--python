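"""Drug-exposure episode construction from prescription claims.

Each prescription covers ``[dispense_date, dispense_date + days_supplied)``.
Overlapping coverage within a patient-class is unioned (supply does not
stack). Consecutive coverage blocks whose gap does not exceed the grace
period are merged into one continuous episode that includes the blank
period; a larger gap ends the episode on the last covered day.

The gap is measured from the half-open end of the current coverage to the
next dispense date, so coverage ``[0, 30)`` followed by a dispense on day
120 has a gap of 90 days. With the default inclusive reading ("within 90
days") that boundary merges; day 121 splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import pandas as pd

from .claims_model import DrugClass, PrescriptionClaim

Interval = tuple[date, date]


@dataclass
class DrugEpisode:
    patient_id: str
    drug_class: DrugClass
    start: date
    end: date  # half-open
    n_claims: int
    total_supplied_days: int

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days


def prescription_coverage(claims: Sequence[PrescriptionClaim]) -> list[Interval]:
    """Union the per-claim coverage intervals of one patient-class.

    Returns sorted, disjoint, half-open intervals. Idempotent: duplicate
    claims contribute nothing extra.
    """
    if not claims:
        return []
    raw = sorted(
        (c.dispense_date, c.dispense_date + timedelta(days=c.days_supplied)) for c in claims
    )
    merged: list[Interval] = [raw[0]]
    for start, end in raw[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end:  # touching intervals union seamlessly
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def build_episodes(
    intervals: Sequence[Interval],
    grace_days: int,
    *,
    grace_inclusive: bool = True,
) -> list[Interval]:
    """Merge sorted disjoint coverage intervals across grace-sized gaps.

    The returned episode intervals span the merged blank periods. With
    ``grace_days = 0`` the input is returned unchanged (limit case).
    """
    if any(a[1] > b[0] for a, b in zip(intervals, intervals[1:])):
        raise ValueError("intervals must be sorted and disjoint")
    if not intervals:
        return []
    episodes: list[Interval] = [intervals[0]]
    for start, end in intervals[1:]:
        gap = (start - episodes[-1][1]).days
        merge = gap <= grace_days if grace_inclusive else gap < grace_days
        if merge:
            episodes[-1] = (episodes[-1][0], end)
        else:
            episodes.append((start, end))
    return episodes


def build_drug_episodes(
    claims: Iterable[PrescriptionClaim],
    grace_days: int,
    *,
    grace_inclusive: bool = True,
    observation_end: Optional[date] = None,
) -> list[DrugEpisode]:
    """Construct all :class:`DrugEpisode` records for one patient.

    Claims are grouped by drug class; processing order does not matter.
    Episodes are truncated at ``observation_end`` (episodes starting on or
    after it are dropped).
    """
    by_class: dict[DrugClass, list[PrescriptionClaim]] = {}
    patient_ids = set()
    for c in claims:
        by_class.setdefault(c.drug_class, []).append(c)
        patient_ids.add(c.patient_id)
    if len(patient_ids) > 1:
        raise ValueError("claims must belong to a single patient")
    patient_id = patient_ids.pop() if patient_ids else ""

    episodes: list[DrugEpisode] = []
    for drug_class, cls_claims in by_class.items():
        coverage = prescription_coverage(cls_claims)
        for start, end in build_episodes(coverage, grace_days, grace_inclusive=grace_inclusive):
            if observation_end is not None:
                if start >= observation_end:
                    continue
                end = min(end, observation_end)
            in_ep = [c for c in cls_claims if start <= c.dispense_date < end]
            episodes.append(
                DrugEpisode(
                    patient_id=patient_id,
                    drug_class=drug_class,
                    start=start,
                    end=end,
                    n_claims=len(in_ep),
                    total_supplied_days=sum(c.days_supplied for c in in_ep),
                )
            )
    episodes.sort(key=lambda e: (e.start, e.end, e.drug_class.name))
    return episodes


def episodes_frame(episodes: Iterable[DrugEpisode]) -> pd.DataFrame:
    """Tabulate episodes for ``episodes.csv``."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "drug_class": e.drug_class.value,
                "start": e.start.isoformat(),
                "end": e.end.isoformat(),
                "duration_days": e.duration_days,
                "n_claims": e.n_claims,
                "total_supplied_days": e.total_supplied_days,
            }
            for e in episodes
        ],
        columns=[
            "patient_id",
            "drug_class",
            "start",
            "end",
            "duration_days",
            "n_claims",
            "total_supplied_days",
        ],
    )
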