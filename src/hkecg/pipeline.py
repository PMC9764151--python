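"""End-to-end orchestration: cohort -> beats -> generic model ->
personalization -> aggregated metrics.

These helpers tie the stage modules together for the CLI, the tests and the
reproduction script; they add no modelling of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .generic_training import TrainConfig, split_dataset, train_generic
from .personalize import (PersonalizationPlan, PersonalRecord, RoundMetrics,
                          run_rounds)
from .preprocess import (Beat, FilterSpec, Label, LabeledRecord, QCConfig,
                         preprocess_record)
from .resnet1d import Checkpoint, NetworkSpec
from .synthetic_cohort import CohortConfig, EcgRecord, generate_cohort


@dataclass
class PreprocessedCohort:
    records: list[LabeledRecord] = field(default_factory=list)
    beats_by_record: dict[str, list[Beat]] = field(default_factory=dict)
    qc_failures: dict[str, str] = field(default_factory=dict)

    def beats_for(self, records: list[LabeledRecord]) -> list[Beat]:
        return [b for r in records for b in self.beats_by_record.get(r.record_id, [])]

    def personal_records(self, subject_id: str) -> list[PersonalRecord]:
        return [PersonalRecord(record=r, beats=self.beats_by_record[r.record_id])
                for r in self.records
                if r.subject_id == subject_id
                and r.record_id in self.beats_by_record
                and r.label in (Label.HYPER, Label.NORMO)]


def preprocess_cohort(records: list[EcgRecord],
                      filter_spec: FilterSpec | None = None,
                      qc: QCConfig | None = None,
                      run_qc: bool = True) -> PreprocessedCohort:
    """Filter, QC, detect and segment every record; drop the excluded
    potassium band and QC failures from the beat inventory."""
    out = PreprocessedCohort()
    for rec in records:
        labeled, beats, qc_result = preprocess_record(rec, filter_spec, qc,
                                                      run_qc=run_qc)
        out.records.append(labeled)
        if qc_result is not None and not qc_result.passed:
            out.qc_failures[rec.record_id] = qc_result.reason or "failed"
            continue
        if labeled.label is Label.EXCLUDED:
            continue
        out.beats_by_record[rec.record_id] = beats
    return out


def flatten_cohort(cohort) -> list[EcgRecord]:
    return [rec for _, records in cohort for rec in records]


def train_generic_on_cohort(pre: PreprocessedCohort, spec: NetworkSpec,
                            config: TrainConfig) -> tuple[Checkpoint, dict]:
    """Subject-level split + generic training; returns the pretrained
    checkpoint and a summary of the split and validation performance."""
    usable = [r for r in pre.records
              if r.label in (Label.HYPER, Label.NORMO)
              and r.record_id in pre.beats_by_record]
    train, val, test = split_dataset(usable, config.split_ratio, config.seed)
    checkpoint, history = train_generic(pre.beats_for(train),
                                        pre.beats_for(val), spec, config)
    summary = {
        "n_train_records": len(train), "n_val_records": len(val),
        "n_test_records": len(test),
        "best_epoch": checkpoint.meta["epoch"],
        "best_val_loss": checkpoint.meta["val_loss"],
        "best_val_accuracy": checkpoint.meta["val_accuracy"],
        "history": history,
        "test_records": test,
    }
    return checkpoint, summary


def personalize_cohort(pre: PreprocessedCohort, subject_ids: list[str],
                       pretrained: Checkpoint, plan_template: PersonalizationPlan
                       ) -> tuple[list[RoundMetrics], dict[str, Checkpoint]]:
    """Run the round schedule for each subject with per-subject sub-seeds."""
    all_metrics: list[RoundMetrics] = []
    finals: dict[str, Checkpoint] = {}
    for i, subject_id in enumerate(sorted(subject_ids)):
        records = pre.personal_records(subject_id)
        if not records:
            raise InvalidArgumentError(f"no usable records for {subject_id}")
        sub_seed = int(np.random.SeedSequence(
            plan_template.seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        plan = PersonalizationPlan(
            subject_id=subject_id,
            holdout_fraction=plan_template.holdout_fraction,
            epochs_per_round=plan_template.epochs_per_round,
            max_rounds=plan_template.max_rounds,
            frozen_stages=plan_template.frozen_stages,
            learning_rate=plan_template.learning_rate,
            batch_size=plan_template.batch_size,
            score_mode=plan_template.score_mode,
            seed=sub_seed)
        metrics, final = run_rounds(records, pretrained, plan)
        all_metrics.extend(metrics)
        finals[subject_id] = final
    return all_metrics, finals


def metrics_to_frame(metrics: list[RoundMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": m.subject_id, "round": m.round_index,
        "accuracy": m.accuracy, "auc": m.auc,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
    } for m in metrics]).sort_values(["subject_id", "round"]).reset_index(drop=True)


def generate_and_preprocess(config: CohortConfig, run_qc: bool = True
                            ) -> tuple[list, PreprocessedCohort]:
    cohort = generate_cohort(config)
    return cohort, preprocess_cohort(flatten_cohort(cohort), run_qc=run_qc)


@dataclass
class TransferExperimentResult:
    pretrained: Checkpoint
    generic_summary: dict
    round_metrics: list[RoundMetrics]
    subjects: list[str]

    def round_table(self) -> pd.DataFrame:
        return metrics_to_frame(self.round_metrics)

    def mean_metric_by_round(self, metric: str) -> pd.Series:
        df = self.round_table()
        return df.groupby("round")[metric].mean()


def run_transfer_experiment(generic_config: CohortConfig,
                            personal_config: CohortConfig,
                            spec: NetworkSpec, train_config: TrainConfig,
                            plan: PersonalizationPlan,
                            run_qc: bool = False) -> TransferExperimentResult:
    """The study's two-phase workflow on synthetic data, end to end.

    A generic population (many subjects, few records each) pretrains the
    population model; a disjoint personal cohort (subjects with >= 8 records
    per class) then goes through the round-based personalization schedule.
    """
    from .personalize import eligible_subjects

    _, generic_pre = generate_and_preprocess(generic_config, run_qc=run_qc)
    pretrained, summary = train_generic_on_cohort(generic_pre, spec, train_config)
    _, personal_pre = generate_and_preprocess(personal_config, run_qc=run_qc)
    usable = [r for r in personal_pre.records
              if r.record_id in personal_pre.beats_by_record]
    subjects = eligible_subjects(usable)
    if not subjects:
        raise InvalidArgumentError("personal cohort has no eligible subjects")
    metrics, _ = personalize_cohort(personal_pre, subjects, pretrained, plan)
    return TransferExperimentResult(pretrained=pretrained,
                                    generic_summary=summary,
                                    round_metrics=metrics, subjects=subjects)
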