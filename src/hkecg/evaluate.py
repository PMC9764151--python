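"""Record-level prediction by majority voting and the statistical toolkit:
confusion metrics, rank-based AUC, Mann-Whitney U (exact for small samples),
and per-round aggregation of personalization metrics.

Hyperkalemia is the positive class throughout.  A record's class is the
majority of its beat-level predictions (exact ties resolve to hyperkalemia,
a sensitivity-favouring rule); its continuous score is the mean per-beat
hyperkalemia probability (a vote-fraction alternative is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InvalidArgumentError
from .preprocess import Label

EXACT_ENUMERATION_MAX_N = 12


@dataclass
class RecordPrediction:
    record_id: str
    beat_classes: np.ndarray  # 0 = normo, 1 = hyper
    beat_hyper_probs: np.ndarray
    score_mode: str = "mean_probability"  # or "vote_fraction"
    record_class: Label = field(init=False)
    score: float = field(init=False)

    def __post_init__(self) -> None:
        self.beat_classes = np.asarray(self.beat_classes, dtype=int)
        self.beat_hyper_probs = np.asarray(self.beat_hyper_probs, dtype=float)
        self.record_class = majority_vote(self.beat_classes)
        if self.score_mode == "mean_probability":
            self.score = float(np.mean(self.beat_hyper_probs))
        elif self.score_mode == "vote_fraction":
            self.score = float(np.mean(self.beat_classes == 1))
        else:
            raise InvalidArgumentError(f"unknown score mode {self.score_mode!r}")


def majority_vote(beat_classes) -> Label:
    """Record class = more frequent beat class; an exact tie is called
    hyperkalemia."""
    votes = np.asarray([1 if c in (1, Label.HYPER) else 0 for c in beat_classes])
    if votes.size == 0:
        raise InvalidArgumentError("cannot vote on an empty beat list")
    n_hyper = int(votes.sum())
    return Label.HYPER if n_hyper >= votes.size - n_hyper else Label.NORMO


def confusion_metrics(predictions, truths) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity with hyperkalemia positive.
    Ratios with an empty denominator are reported as None, not zero."""
    predictions, truths = list(predictions), list(truths)
    if len(predictions) != len(truths):
        raise InvalidArgumentError("predictions and truths differ in length")
    if any(t not in (Label.HYPER, Label.NORMO) for t in truths):
        raise InvalidArgumentError("truths must be hyper or normo")
    tp = sum(p == Label.HYPER and t == Label.HYPER
             for p, t in zip(predictions, truths))
    tn = sum(p == Label.NORMO and t == Label.NORMO
             for p, t in zip(predictions, truths))
    n_pos = sum(t == Label.HYPER for t in truths)
    n_neg = len(truths) - n_pos
    return {
        "accuracy": (tp + tn) / len(truths) if truths else None,
        "sensitivity": tp / n_pos if n_pos else None,
        "specificity": tn / n_neg if n_neg else None,
    }


def auc(scores, truths) -> float:
    """AUC via the rank (Mann-Whitney) formulation, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    truths = list(truths)
    pos = scores[[t == Label.HYPER for t in truths]]
    neg = scores[[t == Label.NORMO for t in truths]]
    if pos.size == 0 or neg.size == 0:
        raise InvalidArgumentError("AUC needs both classes in the truths")
    ranks = sstats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sstats.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def mann_whitney_u(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumerating all group assignments when the pooled sample has
    at most 12 observations (ties handled by mid-ranks); otherwise the
    normal approximation with tie correction and continuity correction.
    The two-sided p is symmetric in the group order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_ENUMERATION_MAX_N:
        pooled = np.concatenate([a, b])
        dev = abs(u_obs - mu)
        hits = total = 0
        for pick in combinations(range(n1 + n2), n1):
            u = _u_statistic(pooled[list(pick)],
                             np.delete(pooled, list(pick)))
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sstats.norm.sf(max(z, 0.0))
    return MannWhitneyResult(u_obs, min(1.0, p), "normal")


METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity")


def aggregate_rounds(metrics: list) -> pd.DataFrame:
    """Across-subject mean (SD) of each metric per personalization round,
    with a rank-test p-value against the round-0 (pretrained) baseline.

    ``metrics`` is a flat list of RoundMetrics-like objects with attributes
    subject_id, round_index and the four metric names.
    """
    rows = [{"subject_id": m.subject_id, "round": m.round_index,
             **{k: getattr(m, k) for k in METRIC_NAMES}} for m in metrics]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if 0 not in set(df["round"]):
        raise InvalidArgumentError("round 0 (pretrained baseline) is required")
    out = []
    baseline = df[df["round"] == 0]
    for rnd, group in df.groupby("round"):
        row: dict[str, float | None] = {"round": int(rnd),
                                        "n_subjects": len(group)}
        for k in METRIC_NAMES:
            vals = group[k].dropna().to_numpy()
            row[f"{k}_mean"] = float(np.mean(vals)) if vals.size else None
            row[f"{k}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else None
            if rnd == 0 or vals.size == 0:
                row[f"{k}_p_vs_round0"] = None
            else:
                base = baseline[k].dropna().to_numpy()
                row[f"{k}_p_vs_round0"] = (
                    mann_whitney_u(vals, base).p_value if base.size else None)
        out.append(row)
    return pd.DataFrame(out).sort_values("round").reset_index(drop=True)
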