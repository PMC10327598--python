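"""The synthetic claims generator: determinism, degenerate limits, and
agreement of empirical frequencies with the configured probabilities."""

from __future__ import annotations

import numpy as np
import pytest

from rxpathways import (
    SimParams,
    StudyConfig,
    default_codelists,
    generate_population,
    generate_prescriptions,
    ground_truth_summary,
    simulate,
    write_claims_tables,
)


def params(**overrides) -> SimParams:
    base = dict(n_patients=50, seed=123)
    base.update(overrides)
    return SimParams(**base)


def flat_prevalence(p: float) -> dict:
    groups = {"<65": p, "65-74": p, "75-84": p, ">=85": p}
    return {
        name: dict(groups)
        for name in (
            "constipation",
            "insomnia",
            "pain",
            "cognitive_disorder",
            "depression_anxiety",
            "hallucination",
        )
    }


class TestValidation:
    def test_nonstochastic_transition_row_rejected(self):
        with pytest.raises(ValueError, match="transition row"):
            params(monthly_transition_probs={"L-dopa": {"L-dopa": 0.5}})

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            params(n_patients=0)

    def test_age_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            params(age_distribution={"<65": 0.5, "65-74": 0.2})


class TestPopulation:
    def test_degenerate_prevalence_one_flags_everyone(self, codelists):
        p = params(comorbidity_prevalence=flat_prevalence(1.0))
        latents, dx = generate_population(p)
        constipation_code = sorted(codelists.comorbidity_map["constipation"])[0]
        with_claim = {c.patient_id for c in dx if c.icd10_code == constipation_code}
        assert with_claim == {l.patient.patient_id for l in latents}

    def test_degenerate_prevalence_zero_no_comorbidity_claims(self, codelists):
        p = params(comorbidity_prevalence=flat_prevalence(0.0), cci_condition_prevalence={})
        _, dx = generate_population(p)
        pd_codes = codelists.pd_codes
        assert all(any(c.icd10_code.startswith(g) for g in pd_codes) for c in dx)

    def test_prevalence_recovered_within_binomial_error(self):
        p = params(n_patients=2000, comorbidity_prevalence=flat_prevalence(0.5))
        latents, _ = generate_population(p)
        frac = np.mean([l.comorbidity_flags["pain"] for l in latents])
        assert abs(frac - 0.5) < 0.03

    def test_every_patient_has_index_pd_claim_inside_enrollment(self):
        latents, dx = generate_population(params())
        by_pid = {}
        for c in dx:
            by_pid.setdefault(c.patient_id, []).append(c)
        for l in latents:
            claims = by_pid[l.patient.patient_id]
            assert all(l.patient.enroll_start <= c.claim_date <= l.patient.enroll_end for c in claims)
            g20 = [c for c in claims if c.icd10_code == "G20"]
            assert min(c.claim_date for c in g20).replace(day=1) == l.index_date

    def test_adding_patients_preserves_earlier_histories(self):
        small, _ = generate_population(params(n_patients=20))
        large, _ = generate_population(params(n_patients=40))
        for a, b in zip(small, large[:20]):
            assert a.patient == b.patient and a.index_date == b.index_date


class TestPrescriptions:
    def test_determinism_byte_identical(self, tmp_path):
        p = params()
        bundle1, _ = simulate(p)
        bundle2, _ = simulate(p)
        write_claims_tables(bundle1, tmp_path / "a")
        write_claims_tables(bundle2, tmp_path / "b")
        for name in ("patients.csv", "diagnoses.csv", "prescriptions.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_absorbing_chain_keeps_one_pattern(self):
        p = params(
            monthly_transition_probs={"L-dopa": {"L-dopa": 1.0}},
            initial_pattern_probs={"NE-DA": 1.0},
            enroll_censor_rate=0.0,
        )
        latents, _ = generate_population(p)
        _, truth = generate_prescriptions(latents, p)
        assert all(len(seq) == 1 for seq in truth.pattern_sequences.values())

    def test_one_month_transition_frequency(self):
        p = params(
            n_patients=5000,
            n_cycles=2,
            enroll_censor_rate=0.0,
            dose_start_mg=300.0,  # add-on gate open from the start
            monotherapy_logit={"intercept": 20.0},  # everyone starts on levodopa
            monthly_transition_probs={
                "L-dopa": {"L-dopa": 0.7, "L-dopa+MAOBI": 0.3},
                "L-dopa+MAOBI": {"L-dopa+MAOBI": 1.0},
            },
        )
        latents, _ = generate_population(p)
        _, truth = generate_prescriptions(latents, p)
        switched = sum(len(seq) > 1 for seq in truth.pattern_sequences.values())
        assert abs(switched / p.n_patients - 0.3) < 0.03

    def test_claims_stay_inside_enrollment(self):
        p = params(enroll_censor_rate=0.1)  # aggressive censoring
        bundle, _ = simulate(p)
        enroll = {x.patient_id: (x.enroll_start, x.enroll_end) for x in bundle.patients}
        for c in bundle.prescriptions:
            start, end = enroll[c.patient_id]
            assert start <= c.dispense_date <= end

    def test_levodopa_dose_escalates_to_ceiling(self):
        p = params(enroll_censor_rate=0.0, initial_pattern_probs={"L-dopa+NE-DA": 1.0},
                   monotherapy_logit={"intercept": 20.0},
                   monthly_transition_probs={"L-dopa": {"L-dopa": 1.0}})
        bundle, _ = simulate(p)
        doses = [c.daily_dose_mg for c in bundle.prescriptions if c.daily_dose_mg is not None]
        assert min(doses) == p.dose_start_mg
        assert max(doses) == p.dose_add_on_mg


class TestGroundTruthSummary:
    def test_known_odds_ratio_appears(self):
        p = params(monotherapy_logit={"intercept": -1.0, "cognitive_disorder": np.log(2.0)})
        _, truth = simulate(p)
        summary = ground_truth_summary(truth)
        assert summary["odds_ratios"]["cognitive_disorder"] == pytest.approx(2.0)

    def test_transition_rows_sum_to_one(self):
        _, truth = simulate(params())
        summary = ground_truth_summary(truth)
        for row in summary["transition_matrix"].values():
            assert sum(row.values()) == pytest.approx(1.0)

    def test_empty_cohort_keeps_schema(self):
        from rxpathways.synthetic_claims import GroundTruth

        summary = ground_truth_summary(GroundTruth())
        assert set(summary) == {
            "odds_ratios",
            "transition_matrix",
            "n_patients",
            "initial_levodopa_monotherapy_fraction",
        }
        assert summary["n_patients"] == 0
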