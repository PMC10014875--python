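"""Rater-agreement metrics, error-run analysis, time-saved model."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats
from sklearn.metrics import precision_recall_fscore_support

from explore.errors import ConsistencyError, UndefinedCorrelationError
from explore.evaluation import (
    ConfusionMatrix, MisclassRun, confusion_counts, misclass_runs,
    run_length_accuracy_correlation, runs_by_pair, spearman, time_saved,
    weighted_prf,
)
from explore.labeling import LabelTrack
from explore.stopwatch import PredictionTrack


def _tracks(true, pred, fps=25.0):
    true = np.asarray(true)
    pred = np.asarray(pred)
    K = int(max(true.max(), pred.max())) + 1
    return (LabelTrack("v", true),
            PredictionTrack.from_hard("v", pred, K, fps))


def _oracle_prf(counts):
    """Independent closed-form support-weighted P/R/F1 in exact rationals."""
    counts = np.asarray(counts)
    K = counts.shape[0]
    support = counts.sum(axis=1)
    total = support.sum()
    f1 = r = p = Fraction(0)
    for k in range(K):
        if support[k] == 0:
            continue
        tp = Fraction(int(counts[k, k]))
        predicted = Fraction(int(counts[:, k].sum()))
        prec = tp / predicted if predicted else Fraction(0)
        rec = tp / Fraction(int(support[k]))
        fk = 2 * prec * rec / (prec + rec) if prec + rec else Fraction(0)
        w = Fraction(int(support[k]), int(total))
        f1 += w * fk
        r += w * rec
        p += w * prec
    return float(f1), float(r), float(p)


class TestConfusionCounts:
    def test_hand_tally_on_toy_tracks(self):
        cm = confusion_counts(*_tracks([0, 0, 1, 1, 2, 2, 1, 0, 2, 1],
                                       [0, 1, 1, 1, 2, 0, 2, 0, 2, 1]))
        expected = np.array([[2, 1, 0], [0, 3, 1], [1, 0, 2]])
        np.testing.assert_array_equal(cm.counts, expected)
        assert cm.total == 10

    def test_perfect_prediction_is_diagonal(self, rng):
        c = rng.integers(0, 3, 50)
        cm = confusion_counts(*_tracks(c, c))
        assert cm.off_diagonal_total == 0

    def test_length_mismatch_rejected(self):
        t, p = _tracks([0, 1], [0, 1])
        with pytest.raises(ConsistencyError):
            confusion_counts(LabelTrack("v", np.array([0])), p)


class TestWeightedPRF:
    def test_perfect_prediction_scores_one(self):
        f1, rec, prec = weighted_prf(ConfusionMatrix(np.diag([5, 3, 2])))
        assert f1 == rec == prec == 1.0

    def test_two_class_example_matches_hand_computation(self):
        cm = np.array([[8, 2], [1, 9]])
        got = weighted_prf(ConfusionMatrix(cm))
        np.testing.assert_allclose(got, _oracle_prf(cm), atol=1e-12)
        # spot value: recall = (8/10*10 + 9/10*10)/20
        assert got[1] == pytest.approx(0.85)

    def test_never_predicted_class_contributes_zero_precision(self):
        cm = np.array([[5, 0], [3, 0]])  # class 1 never predicted
        got = weighted_prf(ConfusionMatrix(cm))
        np.testing.assert_allclose(got, _oracle_prf(cm), atol=1e-12)

    def test_exhaustive_2x2_against_oracle(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            cm = np.array([[a, b], [c, d]])
            np.testing.assert_allclose(
                weighted_prf(ConfusionMatrix(cm)), _oracle_prf(cm), atol=1e-12
            )

    def test_exhaustive_small_3x3_against_oracle(self):
        for entries in itertools.product(range(3), repeat=9):
            if sum(entries) == 0:
                continue
            cm = np.asarray(entries).reshape(3, 3)
            np.testing.assert_allclose(
                weighted_prf(ConfusionMatrix(cm)), _oracle_prf(cm), atol=1e-12
            )

    def test_against_sklearn_on_random_matrices(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 6, size=(3, 3))
            if cm.sum(axis=1).min() == 0:  # sklearn weighted needs full support
                continue
            y_true = np.repeat(np.arange(3), cm.sum(axis=1))
            y_pred = np.concatenate(
                [np.repeat(np.arange(3), cm[k]) for k in range(3)]
            )
            skl = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=0
            )
            f1, rec, prec = weighted_prf(ConfusionMatrix(cm))
            assert prec == pytest.approx(skl[0], abs=1e-12)
            assert rec == pytest.approx(skl[1], abs=1e-12)
            assert f1 == pytest.approx(skl[2], abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConsistencyError):
            weighted_prf(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


class TestSpearman:
    def test_proportional_lists_correlate_perfectly(self):
        assert spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]) == pytest.approx(1.0)
        # the two lists have the same ranks but very different totals
        assert sum([1, 2, 3, 4, 5]) == 15 and sum([10, 20, 30, 40, 50]) == 150

    def test_reversal_is_minus_one(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == -1.0

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 30).astype(float)
            y = rng.integers(0, 5, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = scipy_stats.rankdata(x)  # average ranks
            ry = scipy_stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_segment_score_correlation_pooled_and_per_object(self):
        from explore.evaluation import segment_score_correlation

        a = [{1: 10, 2: 1}, {1: 20, 2: 5}, {1: 30, 2: 7}]
        b = [{1: 12, 2: 2}, {1: 22, 2: 6}, {1: 28, 2: 8}]
        pooled = segment_score_correlation(a, b, object_classes=[1, 2])
        assert pooled == pytest.approx(1.0)  # same ordering of all scores
        per_object = segment_score_correlation(a, b, [1, 2], pooled=False)
        assert per_object[1] == pytest.approx(1.0)
        assert per_object[2] == pytest.approx(1.0)

    @given(data=st.lists(
        st.tuples(st.integers(0, 100), st.integers(0, 100)),
        min_size=4, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_invariance_under_monotone_transform(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        base = spearman(x, y)
        assert spearman(np.exp(x / 25.0), y) == pytest.approx(base, abs=1e-9)
        assert spearman(x, 3 * y + 7) == pytest.approx(base, abs=1e-9)


def _brute_force_runs(true, pred):
    runs = []
    current = None
    for i, (t, p) in enumerate(zip(true, pred)):
        if t != p:
            if current and current[2] == t and current[3] == p and \
                    current[0] + current[1] == i:
                current = (current[0], current[1] + 1, t, p)
                runs[-1] = current
            else:
                current = (i, 1, t, p)
                runs.append(current)
        else:
            current = None
    return runs


class TestMisclassRuns:
    def test_identical_tracks_no_runs(self, rng):
        c = rng.integers(0, 3, 100)
        assert misclass_runs(*_tracks(c, c)) == []

    def test_planted_bursts_match_brute_force(self):
        true = np.zeros(20, dtype=int)
        pred = np.zeros(20, dtype=int)
        pred[3:6] = 1   # one 3-frame burst
        pred[10:15] = 2  # one 5-frame burst
        runs = misclass_runs(*_tracks(true, pred))
        assert [(r.start_frame, r.length, r.true_class, r.predicted_class)
                for r in runs] == [(3, 3, 0, 1), (10, 5, 0, 2)]

    def test_pair_change_mid_error_splits_run(self):
        true = np.array([1, 1, 1, 1])
        pred = np.array([2, 2, 0, 0])
        runs = misclass_runs(*_tracks(true, pred))
        assert [(r.length, r.pair) for r in runs] == [(2, (1, 2)), (2, (1, 0))]

    def test_three_class_problem_has_six_possible_pairs(self):
        # construct a track exhibiting every misinterpretation once
        true, pred = [], []
        for t, p in itertools.permutations(range(3), 2):
            true += [t, t]  # separator correct frame avoids merging
            pred += [p, t]
        runs = misclass_runs(*_tracks(true, pred))
        assert len(runs) == 6
        assert sorted(runs_by_pair(runs)) == sorted(
            itertools.permutations(range(3), 2)
        )

    def test_thousand_random_tracks_match_brute_force(self, rng):
        """Run extraction equals an independent frame-by-frame scan, and
        run lengths sum to the off-diagonal confusion count."""
        for _ in range(1000):
            n = int(rng.integers(1, 120))
            true = rng.integers(0, 3, n)
            pred = np.where(rng.random(n) < 0.3, rng.integers(0, 3, n), true)
            lt, pt = _tracks(true, pred)
            runs = misclass_runs(lt, pt)
            expected = _brute_force_runs(true, pred)
            assert [(r.start_frame, r.length, r.true_class, r.predicted_class)
                    for r in runs] == expected
            cm = confusion_counts(lt, pt)
            assert sum(r.length for r in runs) == cm.off_diagonal_total


class TestRunLengthAccuracyCorrelation:
    def _make_runs(self, lengths_per_video, pair=(0, 1)):
        return [
            [MisclassRun(f"v{v}", 0, length, *pair) for length in lengths]
            for v, lengths in enumerate(lengths_per_video)
        ]

    def test_constant_accuracy_gives_all_nan(self):
        runs = self._make_runs([[5], [5, 5], [5, 5, 5], [5]])
        table = run_length_accuracy_correlation(np.full(4, 0.9), runs, max_length=6)
        assert table["r"].isna().all()

    def test_planted_length_drives_accuracy_down(self):
        # more 8-frame runs <-> lower accuracy, strictly
        accuracies = np.array([0.95, 0.9, 0.8, 0.7])
        runs = self._make_runs([[8], [8, 8], [8] * 3, [8] * 4])
        table = run_length_accuracy_correlation(accuracies, runs, max_length=10)
        cell = table[(table["true"] == 0) & (table["predicted"] == 1)
                     & (table["length"] == 8)]["r"].iloc[0]
        assert cell == pytest.approx(-1.0)
        # lengths with no runs anywhere are undefined
        empty = table[(table["true"] == 0) & (table["predicted"] == 1)
                      & (table["length"] == 3)]["r"].iloc[0]
        assert np.isnan(empty)
        # the median curve over the single pair mirrors it
        med = table[(table["true"] == -1) & (table["length"] == 8)]["r"].iloc[0]
        assert med == pytest.approx(-1.0)

    def test_at_least_counting_mode(self):
        accuracies = np.array([0.9, 0.8, 0.7])
        runs = self._make_runs([[4], [6, 6], [9, 9, 9]])
        table = run_length_accuracy_correlation(
            accuracies, runs, max_length=5, at_least=True
        )
        cell = table[(table["true"] == 0) & (table["length"] == 0)]["r"].iloc[0]
        assert cell == pytest.approx(-1.0)  # total runs grow as accuracy falls

    def test_fewer_than_three_videos_rejected(self):
        with pytest.raises(ConsistencyError):
            run_length_accuracy_correlation(np.array([1.0, 0.9]),
                                            self._make_runs([[1], [2]]))


class TestTimeSaved:
    def test_reference_example_25_minutes_and_92_percent(self):
        """20 six-minute videos at 15 min scoring each; 15,000 labeled
        frames at 25 fps are 10 min of footage -> 25 min total effort,
        saving ~92% over scoring everything by hand."""
        est = time_saved(n=20, video_min=6.0, scoring_min_per_video=15.0,
                         labeled_frames=15_000, fps=25.0)
        assert est.labeled_footage_min == pytest.approx(10.0)
        assert est.explore_total_min == pytest.approx(25.0)
        assert round(est.percent_saved) == 92

    def test_labeling_everything_saves_nothing(self):
        est = time_saved(n=4, video_min=6.0, scoring_min_per_video=15.0,
                         labeled_frames=4 * 6 * 60 * 25, fps=25.0)
        assert est.percent_saved == pytest.approx(0.0)

    def test_labeling_more_than_footage_rejected(self):
        with pytest.raises(ConsistencyError):
            time_saved(n=1, video_min=1.0, scoring_min_per_video=5.0,
                       labeled_frames=100_000, fps=25.0)
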