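"""Pattern extraction: constant-class runs, the >=7-day rule, transitions,
first-pattern classification, and dose at add-on."""

from __future__ import annotations

import numpy as np
import pytest

from rxpathways import (
    DrugClass,
    Patient,
    build_drug_episodes,
    classify_first_pattern,
    daily_class_sets,
    detect_transitions,
    extract_patterns,
    levodopa_dose_at_transition,
)
from rxpathways.exposure_episodes import DrugEpisode
from rxpathways.regimen_patterns import PatternTransition

from conftest import day, random_claims, rx
from oracles import oracle_patterns

L = DrugClass.LEVODOPA
DA = DrugClass.NON_ERGOT_DA
M = DrugClass.MAOB_INHIBITOR


def ep(cls, start, end):
    return DrugEpisode("P", cls, day(start), day(end), 1, end - start)


class TestDailyClassSets:
    def test_single_class_single_run(self):
        runs = daily_class_sets([ep(L, 0, 100)])
        assert [(r.classes, r.start, r.end) for r in runs] == [
            (frozenset({L}), day(0), day(100))
        ]

    def test_overlap_splits_runs(self):
        runs = daily_class_sets([ep(L, 0, 100), ep(DA, 50, 100)])
        assert [(set(r.classes), r.duration_days) for r in runs] == [
            ({L}, 50),
            ({L, DA}, 50),
        ]

    def test_empty(self):
        assert daily_class_sets([]) == []

    def test_unexposed_days_are_absent(self):
        runs = daily_class_sets([ep(L, 0, 10), ep(L, 50, 60)])
        assert [(r.start, r.end) for r in runs] == [(day(0), day(10)), (day(50), day(60))]


class TestExtractPatterns:
    def test_two_long_runs_become_two_patterns(self):
        runs = daily_class_sets([ep(L, 0, 100), ep(DA, 50, 100)])
        patterns = extract_patterns(runs, 7, "P")
        assert [(set(p.classes), p.ordinal) for p in patterns] == [({L}, 1), ({L, DA}, 2)]

    def test_short_terminal_run_dropped(self):
        runs = daily_class_sets([ep(L, 0, 100), ep(DA, 95, 100)])
        patterns = extract_patterns(runs, 7, "P")
        assert [set(p.classes) for p in patterns] == [{L}]

    def test_short_transient_absorbed_into_merged_pattern(self):
        # {L}: 30 d, {L,DA}: 5 d, {L}: 30 d -> one 65-day {L} pattern
        episodes = [ep(L, 0, 65), ep(DA, 30, 35)]
        patterns = extract_patterns(daily_class_sets(episodes), 7, "P")
        assert len(patterns) == 1
        assert set(patterns[0].classes) == {L}
        assert patterns[0].duration_days == 65

    def test_short_run_between_different_patterns_leaves_both(self):
        # {L} 30 d, {L,DA} 5 d, {DA} 30 d -> [{L}, {DA}] consecutive
        episodes = [ep(L, 0, 35), ep(DA, 30, 65)]
        patterns = extract_patterns(daily_class_sets(episodes), 7, "P")
        assert [set(p.classes) for p in patterns] == [{L}, {DA}]

    def test_short_run_as_gap_mode_keeps_flanks_split(self):
        episodes = [ep(L, 0, 65), ep(DA, 30, 35)]
        patterns = extract_patterns(
            daily_class_sets(episodes), 7, "P", short_run_as_gap=True
        )
        assert [(set(p.classes), p.duration_days) for p in patterns] == [({L}, 30), ({L}, 30)]

    def test_every_pattern_meets_minimum_duration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            claims = random_claims(rng) + random_claims(rng, DA) + random_claims(rng, M)
            episodes = build_drug_episodes(claims, 90)
            for p in extract_patterns(daily_class_sets(episodes), 7, "P"):
                assert p.duration_days >= 7

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_day_by_day_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            claims = random_claims(rng) + random_claims(rng, DA)
            episodes = build_drug_episodes(claims, int(rng.integers(0, 100)))
            got = [
                (p.classes, p.start, p.end)
                for p in extract_patterns(daily_class_sets(episodes), 7, "P")
            ]
            assert got == oracle_patterns(episodes, 7)


class TestTransitions:
    def test_single_pattern_is_censored(self):
        patterns = extract_patterns(daily_class_sets([ep(L, 0, 100)]), 7, "P")
        transitions, summary = detect_transitions(patterns, observation_end=day(200))
        assert transitions == []
        assert summary.stayed_on_first and not summary.event
        assert summary.time_to_second_days == 200

    def test_transition_date_and_duration(self):
        episodes = [ep(L, 0, 300), ep(M, 200, 300)]
        patterns = extract_patterns(daily_class_sets(episodes), 7, "P")
        transitions, summary = detect_transitions(patterns)
        assert len(transitions) == 1
        assert transitions[0].transition_date == day(200)
        assert summary.event and summary.time_to_second_days == 200

    def test_three_patterns_two_transitions(self):
        episodes = [ep(L, 0, 30), ep(DA, 30, 60), ep(L, 60, 90)]
        patterns = extract_patterns(daily_class_sets(episodes), 7, "P")
        transitions, _ = detect_transitions(patterns)
        assert len(transitions) == len(patterns) - 1 == 2

    def test_no_patterns(self):
        transitions, summary = detect_transitions([])
        assert transitions == [] and summary is None


class TestClassifyFirstPattern:
    @pytest.mark.parametrize(
        "classes,label",
        [
            ({L}, "levodopa monotherapy"),
            ({DA}, "NE-DA monotherapy"),
            ({L, M}, "combination"),
        ],
    )
    def test_labels(self, classes, label):
        patterns = extract_patterns(
            daily_class_sets([ep(c, 0, 50) for c in classes]), 7, "P"
        )
        assert classify_first_pattern(patterns) == label

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            classify_first_pattern([])


class TestDoseAtTransition:
    transition = PatternTransition("P", frozenset({L}), frozenset({L, M}), day(60), 1)

    def test_covering_claim_dose_returned(self):
        claims = [rx(0, 30, dose=200), rx(30, 60, dose=300)]
        assert levodopa_dose_at_transition(claims, self.transition) == 300

    def test_most_recent_dispense_wins(self):
        claims = [rx(10, 90, dose=200), rx(55, 30, dose=300)]
        assert levodopa_dose_at_transition(claims, self.transition) == 300

    def test_no_covering_claim_is_undefined(self):
        assert levodopa_dose_at_transition([rx(0, 30, dose=200)], self.transition) is None

    def test_device_therapy_patient_excluded(self):
        patient = Patient("P", "male", day(0).replace(year=1950), "JMDC", day(0), day(400),
                          has_dbs_or_lcig=True)
        claims = [rx(30, 60, dose=300)]
        assert levodopa_dose_at_transition(claims, self.transition, patient) is None
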