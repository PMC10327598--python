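"""End-to-end orchestration: claims bundle -> cohort -> episodes -> patterns
-> networks -> statistics, with plain-file stage outputs and a run manifest.

Every stage writes a delimited text file so intermediate results can be
inspected or replaced; the manifest records digests, row counts, the
seed, and timestamps so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .claims_model import (
    ClaimsBundle,
    CodeLists,
    DrugClass,
    StudyConfig,
    default_codelists,
)
from .cohort_builder import CohortRecord, build_cohort, cohort_frame
from .comorbidity_profiler import ComorbidityProfile, profile_patient, profiles_frame
from .exposure_episodes import DrugEpisode, build_drug_episodes, episodes_frame
from .outcome_stats import (
    compare_groups,
    factors_frame,
    fit_duration_factors,
    fit_monotherapy_factors,
    km_estimate,
    km_frame,
)
from .regimen_patterns import (
    FirstPatternSummary,
    PatternTransition,
    RegimenPattern,
    classify_first_pattern,
    daily_class_sets,
    detect_transitions,
    extract_patterns,
    levodopa_dose_at_transition,
    patterns_frame,
    transitions_frame,
)
from .transition_network import aggregate_network, export_network, filter_edges

log = logging.getLogger("rxpathways")

LOGISTIC_COVARIATES = [
    "age",
    "sex_male",
    "depression_anxiety",
    "hallucination",
    "cognitive_disorder",
    "n_concomitant",
    "cci",
    "source_elderly",
    "source_nhi",
]


@dataclass
class AnalysisResult:
    """In-memory results of the full pipeline for one claims bundle."""

    cohort: list[CohortRecord]
    profiles: dict[str, ComorbidityProfile]
    episodes: dict[str, list[DrugEpisode]]
    patterns: dict[str, list[RegimenPattern]]
    transitions: list[PatternTransition]
    summaries: dict[str, FirstPatternSummary]
    first_pattern_label: dict[str, str]
    addon_doses: dict[str, float] = field(default_factory=dict)

    def eligible_ids(self) -> list[str]:
        return [r.patient_id for r in self.cohort if r.eligible]

    def new_initiator_ids(self) -> list[str]:
        return [r.patient_id for r in self.cohort if r.eligible and r.new_initiator]


def analyze_bundle(
    bundle: ClaimsBundle,
    config: Optional[StudyConfig] = None,
    codelists: Optional[CodeLists] = None,
    data_cutoff: Optional[date] = None,
) -> AnalysisResult:
    """Run cohort construction through pattern/transition extraction."""
    config = config or StudyConfig()
    codelists = codelists or default_codelists()

    cohort = build_cohort(bundle, config, codelists, data_cutoff)
    by_record = {r.patient_id: r for r in cohort}
    patients = {p.patient_id: p for p in bundle.patients}
    dx_by_pid: dict[str, list] = {}
    for c in bundle.diagnoses:
        dx_by_pid.setdefault(c.patient_id, []).append(c)
    rx_by_pid: dict[str, list] = {}
    for c in bundle.prescriptions:
        rx_by_pid.setdefault(c.patient_id, []).append(c)

    profiles: dict[str, ComorbidityProfile] = {}
    episodes: dict[str, list[DrugEpisode]] = {}
    patterns: dict[str, list[RegimenPattern]] = {}
    transitions: list[PatternTransition] = []
    summaries: dict[str, FirstPatternSummary] = {}
    first_pattern_label: dict[str, str] = {}
    addon_doses: dict[str, float] = {}

    for record in cohort:
        if not record.eligible:
            log.warning("patient %s excluded: %s", record.patient_id, ";".join(record.exclusion_reasons))
            continue
        pid = record.patient_id
        profiles[pid] = profile_patient(
            pid, dx_by_pid.get(pid, []), rx_by_pid.get(pid, []), record.index_date, config, codelists
        )
        anti_pd = [
            c
            for c in rx_by_pid.get(pid, [])
            if c.drug_class is not DrugClass.OTHER and c.dispense_date >= record.index_date
        ]
        eps = build_drug_episodes(
            anti_pd,
            config.grace_days,
            grace_inclusive=config.grace_inclusive,
            observation_end=record.observation_end,
        )
        episodes[pid] = eps
        runs = daily_class_sets(eps)
        pats = extract_patterns(
            runs, config.min_pattern_days, pid, short_run_as_gap=config.short_run_as_gap
        )
        patterns[pid] = pats
        trans, summary = detect_transitions(pats, record.observation_end)
        transitions.extend(trans)
        if summary is not None:
            summaries[pid] = summary
        if pats:
            first_pattern_label[pid] = classify_first_pattern(pats)
        for t in trans:
            if DrugClass.LEVODOPA in t.from_classes and t.to_classes > t.from_classes:
                dose = levodopa_dose_at_transition(rx_by_pid.get(pid, []), t, patients.get(pid))
                if dose is not None:
                    addon_doses.setdefault(pid, dose)  # dose at first add-on
                break

    return AnalysisResult(
        cohort=cohort,
        profiles=profiles,
        episodes=episodes,
        patterns=patterns,
        transitions=transitions,
        summaries=summaries,
        first_pattern_label=first_pattern_label,
        addon_doses=addon_doses,
    )


def build_analysis_table(result: AnalysisResult, bundle: ClaimsBundle) -> pd.DataFrame:
    """Per-patient covariate/outcome table for the factor and duration models.

    Restricted to eligible new initiators with at least one treatment
    pattern; complete-case by construction. The binary outcome is a
    levodopa-monotherapy first pattern; duration is time from first to
    second pattern with censoring at observation end.
    """
    patients = {p.patient_id: p for p in bundle.patients}
    rows = []
    for record in result.cohort:
        pid = record.patient_id
        if not (record.eligible and record.new_initiator):
            continue
        if pid not in result.first_pattern_label or pid not in result.summaries:
            continue
        profile = result.profiles[pid]
        patient = patients[pid]
        summary = result.summaries[pid]
        rows.append(
            {
                "patient_id": pid,
                "levodopa_monotherapy": int(result.first_pattern_label[pid] == "levodopa monotherapy"),
                "age": record.age_at_index,
                "sex_male": int(patient.sex == "male"),
                "depression_anxiety": int(profile.flags.get("depression_anxiety", False)),
                "hallucination": int(profile.flags.get("hallucination", False)),
                "cognitive_disorder": int(profile.flags.get("cognitive_disorder", False)),
                "constipation": int(profile.flags.get("constipation", False)),
                "insomnia": int(profile.flags.get("insomnia", False)),
                "pain": int(profile.flags.get("pain", False)),
                "n_concomitant": profile.n_concomitant_categories,
                "cci": profile.cci,
                "source_elderly": int(patient.source == "ELDERLY"),
                "source_nhi": int(patient.source == "NHI"),
                "age_group": record.age_group,
                "age_group_coarse": record.age_group_coarse,
                "duration_days": summary.time_to_second_days,
                "event": int(summary.event),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-based stages and the run manifest
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    version: str
    started: str
    finished: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def run_pipeline(
    bundle: ClaimsBundle,
    out_dir: str | Path,
    config: Optional[StudyConfig] = None,
    codelists: Optional[CodeLists] = None,
    data_cutoff: Optional[date] = None,
    seed: Optional[int] = None,
    input_paths: Optional[dict[str, Path]] = None,
) -> RunManifest:
    """Analyse a bundle and write every stage output plus ``manifest.json``."""
    config = config or StudyConfig()
    codelists = codelists or default_codelists()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    result = analyze_bundle(bundle, config, codelists, data_cutoff)
    outputs: dict[str, Path] = {}

    cohort_df = cohort_frame(result.cohort)
    cohort_df.to_csv(out / "cohort.csv", index=False)
    outputs["cohort"] = out / "cohort.csv"

    prof_df = profiles_frame(result.profiles.values())
    prof_df.to_csv(out / "comorbidity.csv", index=False)
    outputs["comorbidity"] = out / "comorbidity.csv"

    ep_df = episodes_frame(e for eps in result.episodes.values() for e in eps)
    ep_df.to_csv(out / "episodes.csv", index=False)
    outputs["episodes"] = out / "episodes.csv"

    pat_df = patterns_frame(p for pats in result.patterns.values() for p in pats)
    pat_df.to_csv(out / "patterns.csv", index=False)
    outputs["patterns"] = out / "patterns.csv"

    tr_df = transitions_frame(result.transitions)
    tr_df.to_csv(out / "transitions.csv", index=False)
    outputs["transitions"] = out / "transitions.csv"

    # networks per coarse age group plus overall
    groups: dict[str, list[str]] = {"all": [r.patient_id for r in result.cohort if r.eligible]}
    for record in result.cohort:
        if record.eligible and record.age_group_coarse:
            groups.setdefault(record.age_group_coarse, []).append(record.patient_id)
    for label, pids in groups.items():
        sequences = {pid: result.patterns.get(pid, []) for pid in pids}
        net = aggregate_network(sequences, group=label, count_events=config.edge_count_events)
        net = filter_edges(net, config.edge_fraction_threshold) if net.n_group else net
        safe = label.replace("<", "lt").replace(">=", "ge")
        for fmt in ("json", "graphml", "dot"):
            p = export_network(net, out / f"network_{safe}.{fmt}", fmt)
            outputs[f"network_{safe}_{fmt}"] = p

    # statistics on the new-initiator analysis table
    table = build_analysis_table(result, bundle)
    table.to_csv(out / "analysis_table.csv", index=False)
    outputs["analysis_table"] = out / "analysis_table.csv"
    stats_meta: dict[str, object] = {
        "significance_level": 0.05,
        "two_sided": True,
        "multiplicity_adjustment": "none",
    }
    if len(table) >= 30 and table["levodopa_monotherapy"].nunique() == 2:
        covs = [c for c in LOGISTIC_COVARIATES if table[c].nunique() > 1]
        logit_df = factors_frame(
            fit_monotherapy_factors(table, "levodopa_monotherapy", covs), "odds_ratio"
        )
        logit_df.to_csv(out / "factors_logistic.csv", index=False)
        outputs["factors_logistic"] = out / "factors_logistic.csv"
        mono = table[table["levodopa_monotherapy"] == 1]
        if len(mono) >= 30 and mono["event"].sum() >= 5:
            cox_covs = [c for c in covs if mono[c].nunique() > 1]
            cox_df = factors_frame(
                fit_duration_factors(mono, "duration_days", "event", cox_covs), "hazard_ratio"
            )
            cox_df.to_csv(out / "factors_cox.csv", index=False)
            outputs["factors_cox"] = out / "factors_cox.csv"
            curve = km_estimate(mono["duration_days"], mono["event"].astype(bool))
            km_frame(curve).to_csv(out / "km_curve.csv", index=False)
            outputs["km_curve"] = out / "km_curve.csv"
            stats_meta["km_median_days"] = curve.median
        if table["age_group_coarse"].nunique() == 2:
            tests = []
            for var, kind in [
                ("age", "continuous"),
                ("cci", "continuous"),
                ("n_concomitant", "continuous"),
                ("duration_days", "continuous"),
                ("sex_male", "categorical"),
                ("cognitive_disorder", "categorical"),
                ("constipation", "categorical"),
                ("hallucination", "categorical"),
            ]:
                r = compare_groups(table, var, "age_group_coarse", kind)
                tests.append(
                    {
                        "variable": r.variable,
                        "test": r.test_name,
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "note": r.note,
                    }
                )
            pd.DataFrame(tests).to_csv(out / "group_tests.csv", index=False)
            outputs["group_tests"] = out / "group_tests.csv"

    dose_df = pd.DataFrame(
        sorted(result.addon_doses.items()), columns=["patient_id", "levodopa_dose_at_addon_mg"]
    )
    dose_df.to_csv(out / "dose_at_addon.csv", index=False)
    outputs["dose_at_addon"] = out / "dose_at_addon.csv"

    config_payload = json.dumps(
        {"study": config.model_dump(), "codelists": json.loads(codelists.model_dump_json())},
        sort_keys=True,
        default=sorted,
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_payload.encode()).hexdigest(),
        seed=seed,
        version=__version__,
        started=started,
        inputs={k: _digest(Path(v)) for k, v in (input_paths or {}).items()},
        outputs={k: _digest(v) for k, v in outputs.items()},
        row_counts={
            "patients": len(bundle.patients),
            "eligible": sum(r.eligible for r in result.cohort),
            "new_initiators": sum(r.eligible and r.new_initiator for r in result.cohort),
            "episodes": len(ep_df),
            "patterns": len(pat_df),
            "transitions": len(tr_df),
            "analysis_table": len(table),
        },
        metadata=stats_meta,
    )
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
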