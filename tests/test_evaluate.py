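"""Majority voting, confusion metrics, rank-based AUC and the Mann-Whitney
U test, each checked against an independent brute-force oracle."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from hkecg.errors import InvalidArgumentError
from hkecg.evaluate import (RecordPrediction, aggregate_rounds, auc,
                            confusion_metrics, majority_vote, mann_whitney_u)
from hkecg.personalize import RoundMetrics
from hkecg.preprocess import Label


class TestMajorityVote:
    @pytest.mark.parametrize("votes,expected", [
        ([1] * 12, Label.HYPER),
        ([1] * 7 + [0] * 5, Label.HYPER),
        ([1] * 6 + [0] * 6, Label.HYPER),  # exact tie resolves to hyper
        ([1] * 5 + [0] * 7, Label.NORMO),
    ])
    def test_count_comparison(self, votes, expected):
        assert majority_vote(votes) is expected

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            majority_vote([])

    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_direct_counting(self, votes):
        n1 = sum(votes)
        n0 = len(votes) - n1
        expected = Label.HYPER if n1 >= n0 else Label.NORMO
        assert majority_vote(votes) is expected


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        truths = [Label.HYPER, Label.NORMO] * 3
        m = confusion_metrics(truths, truths)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_hand_counted_table(self):
        H, N = Label.HYPER, Label.NORMO
        m = confusion_metrics(predictions=[H, H, H, N, N, H],
                              truths=[H, H, H, H, N, N])
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.5)
        assert m["accuracy"] == pytest.approx(2 / 3)

    def test_degenerate_denominator_reported_missing(self):
        truths = [Label.NORMO, Label.NORMO]
        m = confusion_metrics([Label.NORMO, Label.HYPER], truths)
        assert m["sensitivity"] is None
        assert m["specificity"] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            confusion_metrics([Label.HYPER], [Label.HYPER, Label.NORMO])


def _brute_force_auc(scores, truths):
    pos = [s for s, t in zip(scores, truths) if t is Label.HYPER]
    neg = [s for s, t in zip(scores, truths) if t is Label.NORMO]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        truths = [Label.HYPER] * 3 + [Label.NORMO] * 3
        assert auc([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], truths) == 1.0

    def test_all_ties_give_half(self):
        truths = [Label.HYPER, Label.NORMO, Label.HYPER, Label.NORMO]
        assert auc([0.5] * 4, truths) == 0.5

    def test_worked_example_vs_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.3, 0.7]
        truths = [Label.HYPER, Label.HYPER, Label.NORMO, Label.NORMO,
                  Label.HYPER]
        assert auc(scores, truths) == pytest.approx(
            _brute_force_auc(scores, truths))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            auc([0.1, 0.2], [Label.HYPER, Label.HYPER])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=2, max_size=10),
           st.data())
    @settings(max_examples=150, derandomize=True)
    def test_rank_formulation_matches_brute_force(self, scores, data):
        n = len(scores)
        n_pos = data.draw(st.integers(min_value=1, max_value=n - 1))
        truths = [Label.HYPER] * n_pos + [Label.NORMO] * (n - n_pos)
        ours = auc(scores, truths)
        assert ours == pytest.approx(_brute_force_auc(scores, truths))
        binary = [1 if t is Label.HYPER else 0 for t in truths]
        assert ours == pytest.approx(roc_auc_score(binary, scores))

    def test_record_prediction_scores(self):
        rp = RecordPrediction("r", beat_classes=[1, 1, 0],
                              beat_hyper_probs=[0.9, 0.8, 0.1])
        assert rp.record_class is Label.HYPER
        assert rp.score == pytest.approx(0.6)
        rp2 = RecordPrediction("r", beat_classes=[1, 1, 0],
                               beat_hyper_probs=[0.9, 0.8, 0.1],
                               score_mode="vote_fraction")
        assert rp2.score == pytest.approx(2 / 3)


class TestMannWhitney:
    def test_identical_singletons(self):
        result = mann_whitney_u([1.0], [1.0])
        assert result.u == 0.5
        assert result.p_value == 1.0

    def test_fully_separated_triples(self):
        result = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.u == 0.0
        assert result.p_value == pytest.approx(0.1)  # 2 of 20 arrangements
        assert result.method == "exact"

    def test_two_sided_p_symmetric_in_group_order(self):
        a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        assert mann_whitney_u(a, b).p_value == \
            pytest.approx(mann_whitney_u(b, a).p_value)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            ours = mann_whitney_u(a, b)
            ref = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact")
            assert ours.u == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_enumeration_all_sizes_to_six(self):
        """Full-enumeration oracle (direct pair counting) agrees with the
        implementation for every group size combination up to 6 + 6."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                pooled = np.round(rng.normal(size=n1 + n2), 1)  # some ties
                a, b = pooled[:n1], pooled[n1:]
                ours = mann_whitney_u(a, b)
                u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
                assert ours.u == pytest.approx(u_obs)
                mu = n1 * n2 / 2
                hits = total = 0
                for pick in combinations(range(n1 + n2), n1):
                    ga = pooled[list(pick)]
                    gb = np.delete(pooled, list(pick))
                    u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
                    total += 1
                    if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                        hits += 1
                assert ours.p_value == pytest.approx(hits / total)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = rng.normal(loc=0.8, size=25)
        ours = mann_whitney_u(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided")
        assert ours.method == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney_u([], [1.0])


class TestAggregateRounds:
    def _metrics(self, values_by_round):
        out = []
        for rnd, accs in values_by_round.items():
            for i, acc in enumerate(accs):
                out.append(RoundMetrics(subject_id=f"S{i}", round_index=rnd,
                                        accuracy=acc, auc=acc,
                                        sensitivity=acc, specificity=acc))
        return out

    def test_single_subject_sd_missing(self):
        df = aggregate_rounds(self._metrics({0: [0.5]}))
        assert df.loc[0, "accuracy_sd"] is None

    def test_mean_arithmetic(self):
        df = aggregate_rounds(self._metrics({0: [0.5, 0.7]}))
        assert df.loc[0, "accuracy_mean"] == pytest.approx(0.6)

    def test_round_comparison_p_values_present(self):
        df = aggregate_rounds(self._metrics({0: [0.4, 0.5, 0.6],
                                             1: [0.9, 0.8, 0.95]}))
        import pandas as pd

        row1 = df[df["round"] == 1].iloc[0]
        assert 0.0 < row1["accuracy_p_vs_round0"] <= 1.0
        assert pd.isna(df[df["round"] == 0].iloc[0]["accuracy_p_vs_round0"])

    def test_missing_baseline_rejected(self):
        with pytest.raises(InvalidArgumentError):
            aggregate_rounds(self._metrics({1: [0.9]}))
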