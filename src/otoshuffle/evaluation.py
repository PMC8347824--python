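"""Evaluation protocol: fixed test set, stratified k-fold plans, confusion
matrices, cross-validation, and assistive-reader statistics.

The validation scheme keeps a fixed held-out test set aside and partitions
the remaining ids into k stratified folds; each training session uses one
fold for validation (a 4:1 = 8:2 train/validation split for k = 5).
Assistive statistics summarise the two-pass reader protocol in which a
reader may revise an answer after seeing the network's advice.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Deterministic partition: k disjoint validation folds over the
    non-test ids plus a fixed held-out test set.  Invariants are checked on
    construction."""

    k: int
    folds: tuple[tuple, ...]  # fold -> validation ids
    test_ids: tuple

    def __post_init__(self):
        if self.k != len(self.folds):
            raise ValueError("k must equal the number of folds")
        seen: set = set()
        for fold in self.folds:
            ids = set(fold)
            if ids & seen:
                raise ValueError("folds are not pairwise disjoint")
            seen |= ids
        if seen & set(self.test_ids):
            raise ValueError("test ids leaked into a fold")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")

    @property
    def all_ids(self) -> tuple:
        return tuple(i for fold in self.folds for i in fold)

    def val_ids(self, fold: int) -> tuple:
        return self.folds[fold]

    def train_ids(self, fold: int) -> tuple:
        return tuple(i for f, ids in enumerate(self.folds) if f != fold for i in ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k,
            "folds": [list(f) for f in self.folds],
            "test_ids": list(self.test_ids),
        }, indent=2, default=int))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["k"], tuple(tuple(f) for f in d["folds"]), tuple(d["test_ids"]))


def make_folds(ids, labels, k: int = 5, test_ids=(), seed: int = 0) -> FoldPlan:
    """Stratified-by-label random k-fold plan over the non-test ids."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    test_set = set(test_ids)
    if not test_set <= set(ids):
        raise ValueError("test_ids must be a subset of ids")
    pool = [(i, l) for i, l in zip(ids, labels) if i not in test_set]
    pool_ids = np.array([i for i, _ in pool], dtype=object)
    pool_labels = np.array([l for _, l in pool], dtype=object)
    classes, counts = np.unique(pool_labels, return_counts=True)
    thin = classes[counts < k]
    if thin.size:
        raise ValueError(f"classes with fewer than k={k} members: {list(thin)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(tuple(pool_ids[val_idx].tolist()) for _, val_idx in skf.split(pool_ids, pool_labels))
    return FoldPlan(k=k, folds=folds, test_ids=tuple(test_ids))


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Count table with truth on rows and prediction on columns."""

    counts: np.ndarray
    labels: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        return np.divide(np.diag(self.counts), row, out=np.zeros(len(row)), where=row > 0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(truths, predictions, labels=None) -> ConfusionMatrix:
    """Tally a confusion matrix; accuracy is trace / total."""
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if truths.shape != predictions.shape:
        raise ValueError("truths and predictions must have equal length")
    if labels is None:
        labels = np.unique(np.concatenate([truths, predictions]))
    counts = _sk_confusion(truths, predictions, labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


# ---------------------------------------------------------------------------
# assistive-reader statistics
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ("reader_id", "case_id", "truth", "before", "after", "advice")


def assistive_stats(records: pd.DataFrame) -> dict:
    """Summarise two-pass reader records.

    Per reader: accuracy before/after advice and the delta in percentage
    points, decomposed as (corrected wrong answers) - (newly wrong
    answers).  Group level: mean delta and range, pooled correction rate
    (share of initially wrong answers fixed after advice), and advice
    compliance among answers that disagreed with the advice.
    """
    records = pd.DataFrame(records)
    missing_cols = set(RECORD_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    if records[list(RECORD_COLUMNS)].isna().any().any():
        raise ValueError("records contain missing answers")
    counts = records.groupby("reader_id")["case_id"].nunique()
    n_cases = records["case_id"].nunique()
    if (counts != n_cases).any() or (records.groupby("reader_id").size() != n_cases).any():
        raise ValueError("every reader must answer every case exactly once")

    per_reader = []
    for reader, g in records.groupby("reader_id"):
        before_ok = g["before"] == g["truth"]
        after_ok = g["after"] == g["truth"]
        wrong_before = ~before_ok
        corrected = int((wrong_before & after_ok).sum())
        newly_wrong = int((before_ok & ~after_ok).sum())
        per_reader.append({
            "reader_id": reader,
            "n_cases": len(g),
            "before_acc": float(before_ok.mean()),
            "after_acc": float(after_ok.mean()),
            "delta_pp": float((after_ok.mean() - before_ok.mean()) * 100),
            "wrong_before": int(wrong_before.sum()),
            "corrected": corrected,
            "newly_wrong": newly_wrong,
        })
    per_reader = pd.DataFrame(per_reader)

    wrong_before_total = int(per_reader["wrong_before"].sum())
    corrected_total = int(per_reader["corrected"].sum())
    discordant = records["advice"] != records["before"]
    complied = (records.loc[discordant, "after"] == records.loc[discordant, "advice"]).sum()
    group = {
        "mean_before_acc": float(per_reader["before_acc"].mean()),
        "mean_after_acc": float(per_reader["after_acc"].mean()),
        "mean_delta_pp": float(per_reader["delta_pp"].mean()),
        "delta_range_pp": (float(per_reader["delta_pp"].min()), float(per_reader["delta_pp"].max())),
        "correction_rate": corrected_total / wrong_before_total if wrong_before_total else 0.0,
        "compliance_rate": float(complied / discordant.sum()) if discordant.any() else 0.0,
    }
    return {"per_reader": per_reader, "group": group}


def simulate_readers(truths, advice, n_readers: int, p_error: float,
                     p_comply: float, label_set, seed: int = 0) -> pd.DataFrame:
    """Simulate two-pass readers for testing the assistive statistics.

    Each reader answers each case wrongly with probability ``p_error``
    (uniform over the wrong labels) and, when the advice disagrees with the
    initial answer, switches to it with probability ``p_comply``.
    """
    rng = np.random.default_rng(seed)
    truths = list(truths)
    advice = list(advice)
    label_set = list(label_set)
    rows = []
    for reader in range(n_readers):
        for case, (truth, adv) in enumerate(zip(truths, advice)):
            if rng.random() < p_error:
                wrong = [l for l in label_set if l != truth]
                before = wrong[rng.integers(len(wrong))]
            else:
                before = truth
            if adv != before and rng.random() < p_comply:
                after = adv
            else:
                after = before
            rows.append({"reader_id": f"R{reader:02d}", "case_id": f"C{case:03d}",
                         "truth": truth, "before": before, "after": after, "advice": adv})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CrossValResult:
    fold_accuracies: list[float]
    mean: float
    sd: float
    fold_confusions: list[ConfusionMatrix]
    test_accuracy: float | None = None
    test_confusion: ConfusionMatrix | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "fold_accuracies": self.fold_accuracies,
            "mean": self.mean,
            "sd": self.sd,
            "test_accuracy": self.test_accuracy,
        }, indent=2))


def crossvalidate(X, y, plan: FoldPlan, estimator, test_X=None, test_y=None,
                  refit_full: bool = False) -> CrossValResult:
    """Run one training session per fold and aggregate validation accuracy.

    ``X``/``y`` are indexed by the ids in ``plan`` (integer positions).
    Accuracy is reported per fold with mean and sample standard deviation
    (ddof=1).  If a fixed test set is supplied it is evaluated once, with
    the model from the last fold (or a refit on all non-test data when
    ``refit_full``).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    accs: list[float] = []
    confs: list[ConfusionMatrix] = []
    model = None
    for fold in range(plan.k):
        tr = np.asarray(plan.train_ids(fold), dtype=int)
        va = np.asarray(plan.val_ids(fold), dtype=int)
        model = clone(estimator)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        cm = confusion(y[va], pred, labels=np.unique(y))
        accs.append(cm.accuracy)
        confs.append(cm)
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    result = CrossValResult(accs, mean, sd, confs)
    if test_X is not None:
        if refit_full:
            model = clone(estimator)
            all_ids = np.asarray(plan.all_ids, dtype=int)
            model.fit(X[all_ids], y[all_ids])
        pred = model.predict(np.asarray(test_X))
        cm = confusion(np.asarray(test_y), pred, labels=np.unique(y))
        result.test_accuracy = cm.accuracy
        result.test_confusion = cm
    return result
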