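"""Fold plans, confusion matrices, cross-validation aggregation, and
assistive-reader statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import otoshuffle as osh
from otoshuffle.evaluation import FoldPlan, simulate_readers
from otoshuffle.phantom import LABELS


def _clinical_style_labels(n=2272, seed=0):
    rng = np.random.default_rng(seed)
    return rng.choice(LABELS, size=n, p=[1180 / 2372, 400 / 2372, 627 / 2372, 165 / 2372])


class TestMakeFolds:
    def test_partition_arithmetic_2201_ids(self):
        """2272 ids minus a fixed 71-id test set: five folds whose sizes
        differ by at most one and sum to 2201."""
        ids = np.arange(2272)
        labels = _clinical_style_labels()
        test_ids = tuple(range(71))
        plan = osh.make_folds(ids, labels, k=5, test_ids=test_ids, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sum(sizes) == 2201
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_plan(self):
        ids = np.arange(200)
        labels = _clinical_style_labels(200, seed=1)
        a = osh.make_folds(ids, labels, k=5, seed=9)
        b = osh.make_folds(ids, labels, k=5, seed=9)
        assert a == b

    def test_stratification_within_two_percent(self):
        ids = np.arange(2272)
        labels = _clinical_style_labels()
        plan = osh.make_folds(ids, labels, k=5, seed=3)
        lab_of = dict(zip(ids, labels))
        global_prop = {l: np.mean(labels == l) for l in LABELS}
        for fold in plan.folds:
            fl = np.array([lab_of[i] for i in fold])
            for l in LABELS:
                assert abs(np.mean(fl == l) - global_prop[l]) < 0.02

    def test_thin_class_rejected(self):
        ids = np.arange(20)
        labels = ["normal"] * 18 + ["COM"] * 2
        with pytest.raises(ValueError, match="fewer than k"):
            osh.make_folds(ids, labels, k=5)

    def test_invariants_machine_checked_on_construction(self):
        with pytest.raises(ValueError, match="disjoint"):
            FoldPlan(2, ((1, 2), (2, 3)), ())
        with pytest.raises(ValueError, match="leaked"):
            FoldPlan(2, ((1, 2), (3, 4)), (3,))
        with pytest.raises(ValueError, match="differ"):
            FoldPlan(2, ((1, 2, 3, 4), (5,)), ())

    def test_train_val_split_ratio(self):
        ids = np.arange(100)
        labels = ["normal", "OME", "COM", "cholesteatoma"] * 25
        plan = osh.make_folds(ids, labels, k=5, seed=0)
        assert len(plan.val_ids(2)) == 20
        assert len(plan.train_ids(2)) == 80  # the 8:2 split at k = 5
        assert set(plan.train_ids(2)) | set(plan.val_ids(2)) == set(ids)


class TestConfusion:
    def test_sixty_nine_of_seventy_one(self):
        """69 diagonal cases of 71 is the 97.183% accuracy identity."""
        truths = np.repeat(LABELS, [19, 17, 17, 18])
        preds = truths.copy()
        preds[0] = "OME"
        preds[40] = "cholesteatoma"
        cm = osh.confusion(truths, preds, labels=LABELS)
        assert cm.total == 71
        assert np.trace(cm.counts) == 69
        assert round(cm.accuracy * 100, 3) == 97.183

    def test_perfect_predictions_identity_matrix(self):
        truths = np.array(["normal", "OME", "COM", "cholesteatoma"] * 3)
        cm = osh.confusion(truths, truths, labels=LABELS)
        assert cm.accuracy == 1.0
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int) * 3)

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        truths = np.repeat(LABELS, 2500)
        preds = rng.choice(LABELS, size=10_000)
        cm = osh.confusion(truths, preds, labels=LABELS)
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        assert abs(np.trace(cm.counts) - 2500) <= 3 * sigma

    def test_row_and_column_sums(self):
        rng = np.random.default_rng(4)
        truths = rng.choice(LABELS, 500)
        preds = rng.choice(LABELS, 500)
        cm = osh.confusion(truths, preds, labels=LABELS)
        for i, l in enumerate(LABELS):
            assert cm.counts[i].sum() == np.sum(truths == l)
            assert cm.counts[:, i].sum() == np.sum(preds == l)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            osh.confusion(["normal"], ["normal", "OME"])


class TestAssistiveStats:
    def _records(self, before, after, truth, advice):
        return pd.DataFrame({
            "reader_id": ["R0"] * len(truth),
            "case_id": [f"C{i}" for i in range(len(truth))],
            "truth": truth, "before": before, "after": after, "advice": advice,
        })

    def test_no_change_gives_zero_delta(self):
        truth = ["normal", "OME", "COM", "cholesteatoma"]
        before = ["normal", "COM", "COM", "cholesteatoma"]
        recs = self._records(before, before, truth, truth)
        out = osh.assistive_stats(recs)
        assert out["group"]["mean_delta_pp"] == 0.0
        assert out["group"]["correction_rate"] == 0.0

    def test_hand_counted_example(self):
        """10 cases, 4 wrong before, 2 corrected, none newly wrong:
        delta +20 pp and correction rate 50%."""
        truth = ["normal"] * 10
        before = ["OME", "OME", "COM", "COM"] + ["normal"] * 6
        after = ["normal", "normal", "COM", "COM"] + ["normal"] * 6
        recs = self._records(before, after, truth, ["normal"] * 10)
        out = osh.assistive_stats(recs)
        reader = out["per_reader"].iloc[0]
        assert reader["delta_pp"] == pytest.approx(20.0)
        assert reader["corrected"] == 2 and reader["newly_wrong"] == 0
        assert out["group"]["correction_rate"] == pytest.approx(0.5)

    def test_delta_decomposition_per_reader(self):
        rng = np.random.default_rng(8)
        truths = rng.choice(LABELS, 71)
        advice = truths.copy()
        recs = simulate_readers(truths, advice, n_readers=5, p_error=0.3, p_comply=0.5,
                                label_set=LABELS, seed=2)
        out = osh.assistive_stats(recs)
        for _, r in out["per_reader"].iterrows():
            assert r["delta_pp"] == pytest.approx(100 * (r["corrected"] - r["newly_wrong"]) / r["n_cases"])

    def test_missing_answers_rejected(self):
        recs = pd.DataFrame({
            "reader_id": ["R0", "R0", "R1"],
            "case_id": ["C0", "C1", "C0"],
            "truth": ["normal"] * 3, "before": ["normal"] * 3,
            "after": ["normal"] * 3, "advice": ["normal"] * 3,
        })
        with pytest.raises(ValueError, match="every reader"):
            osh.assistive_stats(recs)

    def test_parameter_recovery_from_simulated_readers(self):
        """Generator-specified error and compliance rates are recovered
        within 3-sigma binomial bands (10 readers x 71 cases)."""
        rng = np.random.default_rng(11)
        truths = rng.choice(LABELS, 71)
        advice = truths.copy()
        advice[:2] = ["OME" if t != "OME" else "COM" for t in advice[:2]]  # 69/71-accurate advice
        p_error, p_comply = 0.17, 0.45
        recs = simulate_readers(truths, advice, n_readers=10, p_error=p_error,
                                p_comply=p_comply, label_set=LABELS, seed=13)
        out = osh.assistive_stats(recs)
        n = 10 * 71
        err_hat = 1.0 - out["group"]["mean_before_acc"]
        assert abs(err_hat - p_error) <= 3 * np.sqrt(p_error * (1 - p_error) / n)
        discordant = (recs["advice"] != recs["before"]).sum()
        comp_hat = out["group"]["compliance_rate"]
        assert abs(comp_hat - p_comply) <= 3 * np.sqrt(p_comply * (1 - p_comply) / discordant)


@pytest.fixture(scope="module")
def small_cv():
    images, _ = osh.generate_dataset(48, osh.PhantomParams(seed=19), one_per_class=True)
    X = osh.standardize_batch([im.pixels for im in images], size=72)
    y = np.array([im.label for im in images])
    est = osh.OtoscopyClassifier(patch_size=64, epochs=1, batch_size=16, seed=0)
    plan = osh.make_folds(np.arange(48), y, k=2, seed=4)
    return X, y, plan, est


class TestCrossvalidate:
    def test_mean_equals_recomputed_mean(self, small_cv):
        X, y, plan, est = small_cv
        res = osh.crossvalidate(X, y, plan, est)
        assert res.mean == pytest.approx(np.mean(res.fold_accuracies), abs=1e-9)
        assert len(res.fold_accuracies) == 2

    def test_fold_order_invariance(self, small_cv):
        X, y, plan, est = small_cv
        res_a = osh.crossvalidate(X, y, plan, est)
        shuffled = FoldPlan(plan.k, plan.folds[::-1], plan.test_ids)
        res_b = osh.crossvalidate(X, y, shuffled, est)
        assert sorted(res_a.fold_accuracies) == sorted(res_b.fold_accuracies)
        assert res_a.mean == pytest.approx(res_b.mean)
        assert res_a.sd == pytest.approx(res_b.sd)
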