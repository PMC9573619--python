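import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsbreath import (ABLATION_SUBSETS, ablation_summary, feature_ablation,
                        train_eval_rf, weighted_accuracy, weighted_f1)


def gaussian_fm(n_per_class=40, sep=3.0, seed=0, n_participants=8):
    """Synthetic window-feature matrix with three Gaussian classes."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"baseline": (4.0, 0.4, 0.0),
               "loaded": (4.0 + sep, 0.4 + 0.2 * sep, 0.5 * sep),
               "rapid": (4.0 - 0.3 * sep, 0.4 + 0.1 * sep, 0.3 * sep)}
    for label, (iv, dp, amp) in centers.items():
        for i in range(n_per_class):
            rows.append({
                "participant": f"P{i % n_participants:02d}",
                "condition": label, "window_index": i,
                "interval_mean_s": rng.normal(iv, 1.0),
                "depth_mean": rng.normal(dp, 0.15),
                "o2hb_amplitude": rng.normal(amp, 0.5),
                "label": label})
    return pd.DataFrame(rows)


class TestMetrics:
    def test_perfect_and_fully_wrong(self):
        y = np.array(["a", "b", "c"] * 5)
        assert weighted_accuracy(y, y) == 1.0
        assert weighted_f1(y, y) == 1.0
        wrong = np.roll(y, 1)  # every prediction off-diagonal
        assert weighted_accuracy(y, wrong) == 0.0

    def test_longhand_per_class_oracle(self):
        # 10 of each class; 10/8/5 correct, errors spread over other classes
        y_true = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        y_pred = (["a"] * 10 + ["b"] * 8 + ["a", "c"]
                  + ["c"] * 5 + ["a"] * 3 + ["b"] * 2)
        # longhand: recall_a=1.0, recall_b=0.8, recall_c=0.5, equal support
        assert weighted_accuracy(y_true, y_pred) == pytest.approx(
            (1.0 + 0.8 + 0.5) / 3)
        # longhand F1: precision_a=10/14, b=8/10, c=5/6
        f1 = []
        for r, p in ((1.0, 10 / 14), (0.8, 8 / 10), (0.5, 5 / 6)):
            f1.append(2 * p * r / (p + r))
        assert weighted_f1(y_true, y_pred) == pytest.approx(np.mean(f1))

    def test_shape_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_accuracy([1, 2], [1])
        with pytest.raises(ValueError, match="empty"):
            weighted_f1([], [])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=1, max_size=60))
    def test_weighted_recall_equals_fraction_correct(self, pairs):
        yt = np.array([a for a, _ in pairs])
        yp = np.array([b for _, b in pairs])
        assert weighted_accuracy(yt, yp) == pytest.approx(np.mean(yt == yp))


class TestTrainEval:
    def test_separable_classes_high_accuracy(self):
        rep = train_eval_rf(gaussian_fm(sep=6.0), repeats=10, seed=0)
        assert rep.weighted_accuracy > 0.95
        assert len(rep.per_repeat_accuracy) == 10

    def test_permuted_labels_at_chance(self):
        fm = gaussian_fm(sep=6.0, seed=1)
        rng = np.random.default_rng(3)
        fm["label"] = rng.permutation(fm["label"].to_numpy())
        rep = train_eval_rf(fm, repeats=20, seed=0)
        assert abs(rep.weighted_accuracy - 1 / 3) < 0.1

    def test_deterministic_given_seed(self):
        fm = gaussian_fm()
        a = train_eval_rf(fm, repeats=5, seed=42)
        b = train_eval_rf(fm, repeats=5, seed=42)
        assert a.per_repeat_accuracy == b.per_repeat_accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_row_sums_equal_test_counts_times_repeats(self):
        fm = gaussian_fm(n_per_class=40)
        repeats = 6
        rep = train_eval_rf(fm, repeats=repeats, seed=0)
        # stratified 80:20 of 40 rows/class -> 8 test rows per class
        assert rep.confusion.sum(axis=1).tolist() == [8 * repeats] * 3

    def test_group_split_keeps_participants_apart(self):
        # grouped splitting must not drop accuracy to chance on separable data
        fm = gaussian_fm(sep=6.0, n_participants=10)
        rep = train_eval_rf(fm, repeats=5, seed=0, group_by_participant=True)
        assert rep.weighted_accuracy > 0.9

    def test_input_validation(self):
        fm = gaussian_fm()
        with pytest.raises(ValueError, match="empty feature subset"):
            train_eval_rf(fm, features=())
        with pytest.raises(ValueError, match="unknown features"):
            train_eval_rf(fm, features=("bogus",))
        single = fm[fm["label"] == "baseline"]
        with pytest.raises(ValueError, match="2 classes"):
            train_eval_rf(single)


class TestAblation:
    def test_four_rows_in_fixed_order(self):
        reports = feature_ablation(gaussian_fm(), repeats=3, n_trees=20)
        assert [r.feature_subset for r in reports] == list(ABLATION_SUBSETS)
        table = ablation_summary(reports)
        assert list(table.columns) == ["features", "weighted_accuracy",
                                       "f1_score"]

    def test_interval_carries_signal_when_others_are_noise(self):
        fm = gaussian_fm(sep=6.0, seed=2)
        rng = np.random.default_rng(9)
        fm["depth_mean"] = rng.normal(size=len(fm))
        fm["o2hb_amplitude"] = rng.normal(size=len(fm))
        reports = {r.feature_subset: r
                   for r in feature_ablation(fm, repeats=5, seed=0)}
        with_interval = reports[("depth", "interval")].weighted_accuracy
        without = reports[("depth", "o2hb_amplitude")].weighted_accuracy
        assert with_interval > without + 0.2

    def test_reproducible_with_seed(self):
        fm = gaussian_fm()
        a = feature_ablation(fm, seed=7, repeats=3, n_trees=20)
        b = feature_ablation(fm, seed=7, repeats=3, n_trees=20)
        assert [r.weighted_accuracy for r in a] == \
            [r.weighted_accuracy for r in b]
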