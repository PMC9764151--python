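"""Round-based patient-adaptive transfer learning.

Starting from the pretrained population checkpoint, each eligible subject
(at least 8 records of each class) gets: a per-class 25% record-level
holdout; a freshly re-initialized classification head; the stem plus the
first three residual stages frozen; and up to five rounds, each consuming
one so-far-unused hyperkalemic and one normokalemic record, fine-tuning the
trainable tail for 5 epochs, then evaluating record-level majority-vote
metrics on the fixed holdout.  Round 0 is the pretrained model itself.

The fine-tuning rate defaults to 1e-3 (Adam's default): only the last stage
and a randomly re-initialized two-class head are trained, for a few dozen
optimizer steps per round, which the population-scale rate of 5e-5 cannot
move off their initialization.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, cross_entropy
from .errors import InvalidArgumentError
from .evaluate import RecordPrediction, auc, confusion_metrics
from .generic_training import beats_to_arrays, predict_classes
from .preprocess import Beat, Label, LabeledRecord
from .resnet1d import Checkpoint, ResNet1D, checkpoint_from_model

ELIGIBILITY_MIN_RECORDS = 8  # per class


@dataclass(frozen=True)
class PersonalizationPlan:
    subject_id: str
    holdout_fraction: float = 0.25
    epochs_per_round: int = 5
    max_rounds: int = 5
    frozen_stages: int = 3  # stem + stages 1..3 frozen, stage 4 + head trained
    learning_rate: float = 1e-3
    batch_size: int = 64
    score_mode: str = "mean_probability"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise InvalidArgumentError("holdout fraction must be in (0, 1)")
        if self.max_rounds < 1 or self.epochs_per_round < 1:
            raise InvalidArgumentError("rounds and epochs must be >= 1")


@dataclass
class RoundMetrics:
    subject_id: str
    round_index: int  # 0 = pretrained baseline
    accuracy: float | None
    auc: float | None
    sensitivity: float | None
    specificity: float | None
    n_holdout: int = 0
    records_seen: int = 0  # training records consumed so far (2 per round)


@dataclass
class PersonalRecord:
    """A labelled record together with its segmented beats."""

    record: LabeledRecord
    beats: list[Beat]


def eligible_subjects(records: list[LabeledRecord]) -> list[str]:
    """Subjects with at least 8 hyperkalemic and 8 normokalemic records;
    everyone else stays in the generic-training population."""
    counts: dict[str, dict[Label, int]] = defaultdict(lambda: defaultdict(int))
    for r in records:
        counts[r.subject_id][r.label] += 1
    return sorted(s for s, c in counts.items()
                  if c[Label.HYPER] >= ELIGIBILITY_MIN_RECORDS
                  and c[Label.NORMO] >= ELIGIBILITY_MIN_RECORDS)


def prepare_personal_model(pretrained: Checkpoint, plan: PersonalizationPlan
                           ) -> tuple[ResNet1D, dict[str, bool]]:
    """Load the pretrained weights, re-initialize the classification head
    from the plan's seed, and freeze the stem + leading stages."""
    if plan.frozen_stages >= len(pretrained.spec.stage_blocks):
        raise InvalidArgumentError("frozen prefix must leave a trainable stage")
    model = pretrained.build_model()
    model.load_state_dict(pretrained.weights)
    rng = np.random.default_rng(plan.seed)
    model.fc.w.value = rng.normal(
        0.0, math.sqrt(2.0 / model.fc.din),
        size=model.fc.w.value.shape).astype(model.fc.w.value.dtype)
    model.fc.b.value = np.zeros_like(model.fc.b.value)
    model.set_frozen_stages(plan.frozen_stages)
    mask = {name: p.frozen for name, p in model.named_parameters().items()}
    return model, mask


def split_holdout(records: list[PersonalRecord], plan: PersonalizationPlan
                  ) -> tuple[list[PersonalRecord], list[PersonalRecord]]:
    """Per-class record-level holdout, ceil(fraction * n) per class, seeded."""
    rng = np.random.default_rng(plan.seed)
    holdout, train = [], []
    for label in (Label.NORMO, Label.HYPER):
        group = [r for r in records if r.record.label == label]
        if not group:
            raise InvalidArgumentError(f"no {label.value} records for holdout")
        n_hold = math.ceil(plan.holdout_fraction * len(group))
        idx = rng.permutation(len(group))
        holdout.extend(group[i] for i in sorted(idx[:n_hold]))
        train.extend(group[i] for i in sorted(idx[n_hold:]))
    return train, holdout


def _evaluate_holdout(model: ResNet1D, holdout: list[PersonalRecord],
                      plan: PersonalizationPlan, subject_id: str,
                      round_index: int, records_seen: int) -> RoundMetrics:
    preds, truths, scores = [], [], []
    for pr in holdout:
        x, _ = beats_to_arrays(pr.beats)
        classes, probs = predict_classes(model, x)
        rp = RecordPrediction(pr.record.record_id, classes, probs,
                              score_mode=plan.score_mode)
        preds.append(rp.record_class)
        scores.append(rp.score)
        truths.append(pr.record.label)
    cm = confusion_metrics(preds, truths)
    try:
        auc_value = auc(scores, truths)
    except InvalidArgumentError:
        auc_value = None
    return RoundMetrics(subject_id=subject_id, round_index=round_index,
                        accuracy=cm["accuracy"], auc=auc_value,
                        sensitivity=cm["sensitivity"],
                        specificity=cm["specificity"],
                        n_holdout=len(holdout), records_seen=records_seen)


def _finetune(model: ResNet1D, beats: list[Beat], plan: PersonalizationPlan,
              optimizer: Adam, rng: np.random.Generator) -> None:
    x, y = beats_to_arrays(beats)
    for _ in range(plan.epochs_per_round):
        order = rng.permutation(len(x))
        for i in range(0, len(order), plan.batch_size):
            idx = order[i: i + plan.batch_size]
            optimizer.zero_grad()
            logits = model.forward(x[idx], train=True)
            _, dlogits = cross_entropy(logits, y[idx])
            model.backward(dlogits)
            optimizer.step()


def run_rounds(records: list[PersonalRecord], pretrained: Checkpoint,
               plan: PersonalizationPlan
               ) -> tuple[list[RoundMetrics], Checkpoint]:
    """Execute the personalization schedule for one subject.

    Round 0 evaluates the pretrained checkpoint (original head) on the
    holdout.  Each later round consumes one unused record per class (all of
    their beats), fine-tunes the unfrozen tail for ``epochs_per_round``
    epochs, and re-evaluates the same holdout.  Stops at ``max_rounds`` or
    when either class runs out of training records.  Frozen weights are
    bitwise unchanged across all rounds.
    """
    records = [r for r in records if r.record.label in (Label.HYPER, Label.NORMO)]
    train, holdout = split_holdout(records, plan)
    if not holdout:
        raise InvalidArgumentError("empty holdout")

    baseline = pretrained.build_model()
    metrics = [_evaluate_holdout(baseline, holdout, plan, plan.subject_id,
                                 round_index=0, records_seen=0)]

    model, _ = prepare_personal_model(pretrained, plan)
    optimizer = Adam(model.named_parameters(), lr=plan.learning_rate)
    rng = np.random.default_rng(plan.seed)
    pools = {label: [r for r in train if r.record.label == label]
             for label in (Label.HYPER, Label.NORMO)}
    for label in pools:  # seeded round order, without replacement
        pools[label] = [pools[label][i]
                        for i in rng.permutation(len(pools[label]))]
    n_rounds = min(plan.max_rounds,
                   len(pools[Label.HYPER]), len(pools[Label.NORMO]))
    for r in range(n_rounds):
        pair = [pools[Label.HYPER][r], pools[Label.NORMO][r]]
        beats = [b for pr in pair for b in pr.beats]
        _finetune(model, beats, plan, optimizer, rng)
        metrics.append(_evaluate_holdout(model, holdout, plan, plan.subject_id,
                                         round_index=r + 1,
                                         records_seen=2 * (r + 1)))
    final = checkpoint_from_model(
        model, meta={"subject_id": plan.subject_id, "seed": plan.seed,
                     "rounds": n_rounds, "epoch": pretrained.meta.get("epoch"),
                     "val_loss": pretrained.meta.get("val_loss")})
    return metrics, final
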