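"""Treatment-pattern (regimen) extraction from drug-exposure episodes.

A treatment pattern is a maximal run of days on which the set of active
anti-PD drug classes is constant, kept only when it lasts at least
``min_pattern_days`` (7 by default). Sub-threshold runs — transient
overlaps at a switch — are dropped, and if the flanking surviving runs
have identical class sets they are merged into one pattern spanning the
transient. Unexposed gaps (no active episode of any class) always end the
current pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional, Sequence

import pandas as pd

from .claims_model import DrugClass, Patient, PrescriptionClaim, pattern_name
from .exposure_episodes import DrugEpisode


@dataclass
class ClassRun:
    """A maximal run of days with a constant (non-empty) active class set."""

    start: date
    end: date  # half-open
    classes: frozenset[DrugClass]

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days


@dataclass
class RegimenPattern:
    patient_id: str
    classes: frozenset[DrugClass]
    start: date
    end: date  # half-open
    ordinal: int  # 1 = first pattern

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days

    @property
    def name(self) -> str:
        return pattern_name(self.classes)


@dataclass
class PatternTransition:
    patient_id: str
    from_classes: frozenset[DrugClass]
    to_classes: frozenset[DrugClass]
    transition_date: date
    from_ordinal: int


@dataclass
class FirstPatternSummary:
    """Time from the first pattern to the second, for the duration analyses."""

    patient_id: str
    first_classes: frozenset[DrugClass]
    stayed_on_first: bool
    time_to_second_days: int  # censored at observation end when stayed_on_first
    event: bool  # True when a second pattern started


def daily_class_sets(episodes: Sequence[DrugEpisode]) -> list[ClassRun]:
    """Partition a patient's exposed calendar into constant-class-set runs.

    Episodes must be per-class disjoint (as produced by episode building).
    Days covered by no episode are unexposed and are simply absent from
    the returned runs.
    """
    if not episodes:
        return []
    cuts = sorted({e.start for e in episodes} | {e.end for e in episodes})
    runs: list[ClassRun] = []
    for lo, hi in zip(cuts, cuts[1:]):
        active = frozenset(e.drug_class for e in episodes if e.start <= lo and hi <= e.end)
        if not active:
            continue
        if runs and runs[-1].end == lo and runs[-1].classes == active:
            runs[-1] = ClassRun(runs[-1].start, hi, active)
        else:
            runs.append(ClassRun(lo, hi, active))
    return runs


def _segment_blocks(runs: Sequence[ClassRun]) -> list[list[ClassRun]]:
    """Split runs at unexposed gaps: contiguous runs form one block."""
    blocks: list[list[ClassRun]] = []
    for run in runs:
        if blocks and blocks[-1][-1].end == run.start:
            blocks[-1].append(run)
        else:
            blocks.append([run])
    return blocks


def extract_patterns(
    runs: Sequence[ClassRun],
    min_pattern_days: int,
    patient_id: str = "",
    *,
    short_run_as_gap: bool = False,
) -> list[RegimenPattern]:
    """Turn class-set runs into ordered, validated regimen patterns.

    Within each contiguous exposure block, runs shorter than
    ``min_pattern_days`` are dropped; adjacent surviving runs with equal
    class sets are then merged, absorbing the transient days, so a <7-day
    overlap at a switch never splits or creates a pattern. When the
    flanking patterns differ the dropped run leaves them consecutive with
    their own extents. ``short_run_as_gap=True`` selects the alternative
    reading where a sub-threshold run splits the block like an unexposed
    gap (identical flanking patterns are then NOT merged).
    """
    patterns: list[RegimenPattern] = []
    for block in _segment_blocks(runs):
        surviving = [r for r in block if r.duration_days >= min_pattern_days]
        if short_run_as_gap:
            merged = surviving
        else:
            merged: list[ClassRun] = []
            for run in surviving:
                if merged and merged[-1].classes == run.classes:
                    # span the dropped transient between them
                    merged[-1] = ClassRun(merged[-1].start, run.end, run.classes)
                else:
                    merged.append(run)
        for run in merged:
            patterns.append(
                RegimenPattern(
                    patient_id=patient_id,
                    classes=run.classes,
                    start=run.start,
                    end=run.end,
                    ordinal=len(patterns) + 1,
                )
            )
    return patterns


def detect_transitions(
    patterns: Sequence[RegimenPattern],
    observation_end: Optional[date] = None,
) -> tuple[list[PatternTransition], Optional[FirstPatternSummary]]:
    """Emit one transition per adjacent pattern pair with differing classes.

    Also summarises the first pattern: whether the patient stayed on it,
    and the time from first-pattern start to second-pattern start (or to
    ``observation_end`` when censored).
    """
    transitions = [
        PatternTransition(
            patient_id=b.patient_id,
            from_classes=a.classes,
            to_classes=b.classes,
            transition_date=b.start,
            from_ordinal=a.ordinal,
        )
        for a, b in zip(patterns, patterns[1:])
        if a.classes != b.classes
    ]
    if not patterns:
        return transitions, None
    first = patterns[0]
    if len(patterns) > 1:
        summary = FirstPatternSummary(
            patient_id=first.patient_id,
            first_classes=first.classes,
            stayed_on_first=False,
            time_to_second_days=(patterns[1].start - first.start).days,
            event=True,
        )
    else:
        end = observation_end if observation_end is not None else first.end
        summary = FirstPatternSummary(
            patient_id=first.patient_id,
            first_classes=first.classes,
            stayed_on_first=True,
            time_to_second_days=max((end - first.start).days, 0),
            event=False,
        )
    return transitions, summary


def classify_first_pattern(patterns: Sequence[RegimenPattern]) -> str:
    """Label the initial regimen: levodopa monotherapy, another single-class
    monotherapy (named), or a combination."""
    if not patterns:
        raise ValueError("patient has no regimen patterns")
    classes = patterns[0].classes
    if len(classes) == 1:
        (only,) = classes
        if only is DrugClass.LEVODOPA:
            return "levodopa monotherapy"
        return f"{only.value} monotherapy"
    return "combination"


def levodopa_dose_at_transition(
    rx_claims: Iterable[PrescriptionClaim],
    transition: PatternTransition,
    patient: Optional[Patient] = None,
) -> Optional[float]:
    """Daily levodopa dose in force on the transition date.

    The dose comes from the levodopa claim whose coverage contains the
    transition date, taking the most recent dispense when several cover
    it. Returns ``None`` (undefined) for patients with deep-brain
    stimulation / intestinal-gel therapy — their doses are not comparable
    — or when no claim covers the date.
    """
    if patient is not None and patient.has_dbs_or_lcig:
        return None
    covering = [
        c
        for c in rx_claims
        if c.drug_class is DrugClass.LEVODOPA
        and c.patient_id == transition.patient_id
        and c.dispense_date <= transition.transition_date
        and (transition.transition_date - c.dispense_date).days < c.days_supplied
    ]
    if not covering:
        return None
    latest = max(covering, key=lambda c: c.dispense_date)
    return latest.daily_dose_mg


def patterns_frame(patterns: Iterable[RegimenPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "pattern": p.name,
                "start": p.start.isoformat(),
                "end": p.end.isoformat(),
                "duration_days": p.duration_days,
                "ordinal": p.ordinal,
            }
            for p in patterns
        ],
        columns=["patient_id", "pattern", "start", "end", "duration_days", "ordinal"],
    )


def transitions_frame(transitions: Iterable[PatternTransition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "from_pattern": pattern_name(t.from_classes),
                "to_pattern": pattern_name(t.to_classes),
                "transition_date": t.transition_date.isoformat(),
                "from_ordinal": t.from_ordinal,
            }
            for t in transitions
        ],
        columns=["patient_id", "from_pattern", "to_pattern", "transition_date", "from_ordinal"],
    )
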