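"""Framework splits, confusion matrices, and the per-activity metric."""

import numpy as np
import pandas as pd
import pytest

from eegcascade.evaluation import (
    EvaluationReport,
    average_confusion,
    best_worst_subjects,
    confusion_matrix,
    macro_activity_accuracy,
    split_framework1,
    split_framework2,
    split_framework3,
)
from eegcascade.io_recordings import CLASS_NAMES


def _balanced_table(n_per_class, subject="S00", recording="R0", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, name in enumerate(CLASS_NAMES):
        for wi in range(n_per_class):
            rows.append({
                "FP1_m2": rng.normal(), "label": name,
                "region": name.split("-")[2], "side": name.split("-")[1],
                "mode": name.split("-")[0],
                "subject_id": subject, "recording_id": recording,
                "task_index": ci, "window_index": wi,
            })
    return pd.DataFrame(rows)


class TestFramework1:
    def test_800_rows_split_480_160_160(self):
        plan = split_framework1(_balanced_table(100), seed=0)
        assert (len(plan.train_idx), len(plan.val_idx), len(plan.test_idx)) \
            == (480, 160, 160)

    def test_per_class_counts_within_one_of_exact_fractions(self):
        plan = split_framework1(_balanced_table(19), seed=1)
        for part, frac in [(plan.train, 0.6), (plan.val, 0.2), (plan.test, 0.2)]:
            counts = part["label"].value_counts()
            assert set(counts.index) == set(CLASS_NAMES)
            assert all(abs(c - 19 * frac) <= 1 for c in counts)

    def test_same_seed_reproduces_assignment(self):
        t = _balanced_table(25)
        p1, p2 = split_framework1(t, seed=7), split_framework1(t, seed=7)
        np.testing.assert_array_equal(p1.train_idx, p2.train_idx)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)

    def test_subsets_disjoint_and_exhaustive(self):
        plan = split_framework1(_balanced_table(10), seed=3)
        allidx = np.concatenate([plan.train_idx, plan.val_idx, plan.test_idx])
        assert len(np.unique(allidx)) == len(allidx) == 80

    def test_class_with_too_few_rows_rejected(self):
        t = _balanced_table(3)
        t = t.drop(t[t["label"] == CLASS_NAMES[0]].index[1:])
        with pytest.raises(ValueError, match="rows"):
            split_framework1(t, seed=0)

    def test_multiple_recordings_rejected(self):
        t = pd.concat([_balanced_table(5, recording="R0"),
                       _balanced_table(5, recording="R1")], ignore_index=True)
        with pytest.raises(ValueError, match="single"):
            split_framework1(t, seed=0)


class TestFramework2:
    def test_equal_recordings_give_40_10_50(self):
        r1 = _balanced_table(100, recording="R0")
        r2 = _balanced_table(100, recording="R1", seed=1)
        plan = split_framework2(r1, r2, seed=0)
        assert (len(plan.train_idx), len(plan.val_idx), len(plan.test_idx)) \
            == (640, 160, 800)
        assert plan.fractions == pytest.approx((0.4, 0.1, 0.5))

    def test_second_recording_never_in_train_or_val(self):
        r1 = _balanced_table(10, recording="R0")
        r2 = _balanced_table(10, recording="R1", seed=1)
        plan = split_framework2(r1, r2, seed=0)
        for part in (plan.train, plan.val):
            assert (part["recording_id"] == "R0").all()
        assert (plan.test["recording_id"] == "R1").all()

    def test_different_subjects_rejected(self):
        r1 = _balanced_table(5, subject="S00")
        r2 = _balanced_table(5, subject="S01", recording="R1")
        with pytest.raises(ValueError, match="one subject"):
            split_framework2(r1, r2, seed=0)

    def test_same_recording_id_rejected(self):
        r1 = _balanced_table(5)
        r2 = _balanced_table(5, seed=1)
        with pytest.raises(ValueError, match="distinct"):
            split_framework2(r1, r2, seed=0)


class TestFramework3:
    @pytest.fixture
    def nine_subjects(self):
        return {
            f"S{i:02d}": [_balanced_table(50, subject=f"S{i:02d}",
                                          recording="R0", seed=i),
                          _balanced_table(50, subject=f"S{i:02d}",
                                          recording="R1", seed=100 + i)]
            for i in range(9)
        }

    def test_seven_remaining_subjects_supply_5600_test_rows(self, nine_subjects):
        plan = split_framework3(nine_subjects, "S00", "S08", seed=0)
        assert len(plan.test_idx) == 5600
        assert plan.test["subject_id"].nunique() == 7

    def test_overall_fractions_near_18_4_78(self, nine_subjects):
        plan = split_framework3(nine_subjects, "S00", "S08", seed=0)
        assert plan.fractions[0] == pytest.approx(0.18, abs=0.01)
        assert plan.fractions[1] == pytest.approx(0.04, abs=0.01)
        assert plan.fractions[2] == pytest.approx(0.78, abs=0.01)

    def test_train_and_test_subjects_disjoint(self, nine_subjects):
        plan = split_framework3(nine_subjects, "S03", "S05", seed=0)
        train_subjects = set(plan.train["subject_id"]) | set(plan.val["subject_id"])
        assert train_subjects == {"S03", "S05"}
        assert not (train_subjects & set(plan.test["subject_id"]))

    def test_identical_best_and_worst_rejected(self, nine_subjects):
        with pytest.raises(ValueError, match="differ"):
            split_framework3(nine_subjects, "S00", "S00", seed=0)

    def test_unknown_subject_rejected(self, nine_subjects):
        with pytest.raises(ValueError, match="unknown"):
            split_framework3(nine_subjects, "S00", "S99", seed=0)


class TestConfusionAndMetric:
    def test_perfect_predictions_give_diagonal(self):
        y = np.repeat(CLASS_NAMES, 3)
        m = confusion_matrix(y, y)
        assert np.all(m == np.diag([3] * 8))

    def test_row_sums_equal_class_counts(self, rng):
        y = rng.choice(CLASS_NAMES, size=200)
        p = rng.choice(CLASS_NAMES, size=200)
        m = confusion_matrix(y, p)
        for i, cls in enumerate(CLASS_NAMES):
            assert m[i].sum() == (y == cls).sum()
        assert m.sum() == 200

    def test_constant_predictions_fill_one_column(self):
        y = np.repeat(CLASS_NAMES, 2)
        p = np.full(len(y), CLASS_NAMES[3])
        m = confusion_matrix(y, p)
        assert (m[:, 3] == 2).all() and m.sum() == m[:, 3].sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix(["real-left-hand"], ["no-such-class"])

    def test_diagonal_matrix_scores_1(self):
        assert macro_activity_accuracy(np.diag([5] * 8)) == 1.0

    def test_uniform_matrix_scores_one_eighth(self):
        assert macro_activity_accuracy(np.full((8, 8), 4)) == pytest.approx(0.125)

    def test_two_class_toy_example(self):
        assert macro_activity_accuracy(np.array([[9, 1], [2, 8]])) \
            == pytest.approx(0.85)

    def test_empty_class_rejected(self):
        m = np.diag([1] * 8)
        m[2, 2] = 0
        with pytest.raises(ValueError, match="no test rows"):
            macro_activity_accuracy(m)

    def test_metric_invariant_under_class_permutation(self, rng):
        m = rng.integers(1, 20, size=(8, 8))
        perm = rng.permutation(8)
        assert macro_activity_accuracy(m[np.ix_(perm, perm)]) \
            == pytest.approx(macro_activity_accuracy(m))


class TestAverageConfusion:
    def test_identical_matrices_average_to_normalised_form(self):
        m = np.array([[8, 2], [1, 9]], dtype=float)
        avg = average_confusion([m, m, m])
        np.testing.assert_allclose(avg, m / m.sum(axis=1, keepdims=True))

    def test_rows_sum_to_one(self, rng):
        mats = [rng.integers(1, 30, size=(8, 8)) for _ in range(4)]
        avg = average_confusion(mats)
        np.testing.assert_allclose(avg.sum(axis=1), 1.0, atol=1e-9)

    def test_two_permutation_matrices(self):
        m1 = np.eye(2) * 4
        m2 = np.array([[0.0, 2.0], [2.0, 0.0]])
        avg = average_confusion([m1, m2])
        np.testing.assert_allclose(avg, [[0.5, 0.5], [0.5, 0.5]])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            average_confusion([np.array([[1.0, 0.0], [0.0, 0.0]])])


class TestBestWorst:
    def _report(self, acc):
        conf = np.diag([int(round(acc * 100))] * 8)
        off = 100 - int(round(acc * 100))
        conf[:, 0] += off  # push the remainder into one column
        return EvaluationReport(framework=1, confusion=conf,
                                subject_ids=["x"], recording_ids=["R0"],
                                seed=0)

    def test_argmax_argmin(self):
        reports = {"s1": self._report(0.9), "s2": self._report(0.7),
                   "s3": self._report(0.8)}
        assert best_worst_subjects(reports) == ("s1", "s2")

    def test_tie_breaks_by_subject_id_order(self):
        reports = {"s2": self._report(0.9), "s1": self._report(0.9),
                   "s3": self._report(0.5)}
        best, worst = best_worst_subjects(reports)
        assert best == "s1"

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            best_worst_subjects({"s1": self._report(0.9)})


def test_report_serialization_round_trip(tmp_path):
    conf = np.diag([4] * 8)
    rep = EvaluationReport(framework=2, confusion=conf, subject_ids=["S00"],
                           recording_ids=["R0", "R1"], seed=3)
    path = rep.write(tmp_path / "r.json")
    import json

    doc = json.loads(path.read_text())
    assert doc["framework"] == 2
    assert doc["macro_accuracy"] == 1.0
    assert np.array(doc["confusion"]).shape == (8, 8)
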