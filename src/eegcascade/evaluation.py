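"""Train/validation/test frameworks, confusion matrices, and the metric.

Three evaluation regimes probe increasing levels of EEG variability:

* **Framework 1** — within-recording: one subject's single recording split
  60/20/20 (train/validation/test), stratified by class.
* **Framework 2** — cross-session: one recording of a subject supplies
  train (80%) and validation (20%); the subject's other recording is the
  test set.  With equal-sized recordings the overall fractions are
  40/10/50.
* **Framework 3** — cross-subject: the pooled rows of the best- and
  worst-performing subjects (by Framework 1) supply train/validation
  (82/18); every remaining subject is test.  With 9 equal subjects the
  overall fractions are roughly 18/4/78.

The headline metric is the mean of the per-activity accuracies — the
row-normalised diagonal of the 8x8 confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io_recordings import CLASS_NAMES

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "split_framework1",
    "split_framework2",
    "split_framework3",
    "confusion_matrix",
    "macro_activity_accuracy",
    "average_confusion",
    "best_worst_subjects",
]


@dataclass
class SplitPlan:
    """Row assignment of one framework split.

    ``table`` is the (possibly concatenated) feature table the integer
    position arrays index into.
    """

    framework: int
    table: pd.DataFrame = field(repr=False)
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        parts = [self.train_idx, self.val_idx, self.test_idx]
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != len(combined):
            raise ValueError("split subsets overlap")
        if len(combined) != len(self.table):
            raise ValueError("split subsets do not cover the table")

    @property
    def train(self) -> pd.DataFrame:
        return self.table.iloc[self.train_idx].reset_index(drop=True)

    @property
    def val(self) -> pd.DataFrame:
        return self.table.iloc[self.val_idx].reset_index(drop=True)

    @property
    def test(self) -> pd.DataFrame:
        return self.table.iloc[self.test_idx].reset_index(drop=True)


def _allocate(n: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n rows to len(fracs) bins."""
    raw = [f * n for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


def _stratified_assign(table: pd.DataFrame, fracs: Sequence[float],
                       seed: int, min_per_class: int = 1) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fracs]
    for cls in sorted(table["label"].unique()):
        pos = np.flatnonzero((table["label"] == cls).to_numpy())
        if len(pos) < min_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(pos)} rows; "
                f"need at least {min_per_class}"
            )
        pos = rng.permutation(pos)
        counts = _allocate(len(pos), fracs)
        start = 0
        for i, c in enumerate(counts):
            parts[i].extend(pos[start:start + c])
            start += c
    return [np.sort(np.array(p, dtype=np.intp)) for p in parts]


def split_framework1(table: pd.DataFrame, seed: int = 0,
                     fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     ) -> SplitPlan:
    """Stratified within-recording split (default 60/20/20)."""
    if table[["subject_id", "recording_id"]].drop_duplicates().shape[0] != 1:
        raise ValueError("Framework 1 expects a single (subject, recording)")
    tr, va, te = _stratified_assign(table, fractions, seed, min_per_class=3)
    return SplitPlan(framework=1, table=table.reset_index(drop=True),
                     train_idx=tr, val_idx=va, test_idx=te,
                     fractions=fractions, seed=seed)


def split_framework2(rec1: pd.DataFrame, rec2: pd.DataFrame,
                     seed: int = 0) -> SplitPlan:
    """Cross-session split: 80/20 of rec1 for train/val, all of rec2 as test."""
    s1 = rec1["subject_id"].unique()
    s2 = rec2["subject_id"].unique()
    if len(s1) != 1 or len(s2) != 1 or s1[0] != s2[0]:
        raise ValueError("Framework 2 requires two recordings of one subject")
    r1 = rec1["recording_id"].unique()
    r2 = rec2["recording_id"].unique()
    if len(r1) != 1 or len(r2) != 1 or r1[0] == r2[0]:
        raise ValueError("Framework 2 requires two distinct recordings")
    tr, va = _stratified_assign(rec1, (0.8, 0.2), seed, min_per_class=2)
    combined = pd.concat([rec1, rec2], ignore_index=True)
    test = np.arange(len(rec1), len(combined), dtype=np.intp)
    n = len(combined)
    return SplitPlan(framework=2, table=combined,
                     train_idx=tr, val_idx=va, test_idx=test,
                     fractions=(len(tr) / n, len(va) / n, len(test) / n),
                     seed=seed)


def split_framework3(subject_tables: Mapping[str, Sequence[pd.DataFrame]],
                     best_id: str, worst_id: str, seed: int = 0) -> SplitPlan:
    """Cross-subject split: best+worst subjects train/val, the rest test."""
    if best_id == worst_id:
        raise ValueError("best_id and worst_id must differ")
    for sid in (best_id, worst_id):
        if sid not in subject_tables:
            raise ValueError(f"unknown subject id {sid!r}")
    if len(subject_tables) < 3:
        raise ValueError("Framework 3 needs at least 3 subjects")

    train_pool = pd.concat(
        [t for sid in (best_id, worst_id) for t in subject_tables[sid]],
        ignore_index=True,
    )
    test_pool = pd.concat(
        [t for sid in sorted(subject_tables) if sid not in (best_id, worst_id)
         for t in subject_tables[sid]],
        ignore_index=True,
    )
    tr, va = _stratified_assign(train_pool, (0.82, 0.18), seed, min_per_class=2)
    combined = pd.concat([train_pool, test_pool], ignore_index=True)
    test = np.arange(len(train_pool), len(combined), dtype=np.intp)
    n = len(combined)
    return SplitPlan(framework=3, table=combined,
                     train_idx=tr, val_idx=va, test_idx=test,
                     fractions=(len(tr) / n, len(va) / n, len(test) / n),
                     seed=seed)


def confusion_matrix(truths: Sequence[str], preds: Sequence[str],
                     class_order: Sequence[str] = CLASS_NAMES) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    truths = np.asarray(truths)
    preds = np.asarray(preds)
    if truths.shape != preds.shape:
        raise ValueError("truths and preds must have equal length")
    known = set(class_order)
    unknown = (set(truths) | set(preds)) - known
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    return _sk_confusion(truths, preds, labels=list(class_order))


def macro_activity_accuracy(matrix: np.ndarray) -> float:
    """Mean of per-activity accuracies (row-normalised diagonal)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    row_sums = matrix.sum(axis=1)
    if np.any(row_sums == 0):
        empty = np.flatnonzero(row_sums == 0)
        raise ValueError(f"classes with no test rows: {empty.tolist()}")
    return float(np.mean(np.diag(matrix) / row_sums))


def average_confusion(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Entrywise mean of row-normalised matrices (rows of result sum to 1)."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    normed = []
    for m in matrices:
        m = np.asarray(m, dtype=np.float64)
        row_sums = m.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise ValueError("matrix has an all-zero row")
        normed.append(m / row_sums)
    return np.mean(normed, axis=0)


def best_worst_subjects(reports: Mapping[str, "EvaluationReport"],
                        ) -> tuple[str, str]:
    """Subjects with the highest and lowest macro accuracy (ties by id)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 subjects")
    best_id = worst_id = None
    best_acc, worst_acc = -np.inf, np.inf
    for sid in sorted(reports):
        acc = reports[sid].macro_accuracy
        if acc > best_acc:
            best_id, best_acc = sid, acc
        if acc < worst_acc:
            worst_id, worst_acc = sid, acc
    return best_id, worst_id


@dataclass
class EvaluationReport:
    """Confusion matrix, per-activity accuracies, and framework metadata."""

    framework: int
    confusion: np.ndarray
    subject_ids: list[str]
    recording_ids: list[str]
    seed: int
    class_order: tuple[str, ...] = CLASS_NAMES
    #: present for Framework 3: the entrywise mean of the per-subject
    #: row-normalised confusion matrices
    averaged_confusion: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def per_activity_accuracy(self) -> dict[str, float]:
        rows = self.confusion.sum(axis=1)
        return {
            cls: float(self.confusion[i, i] / rows[i]) if rows[i] else float("nan")
            for i, cls in enumerate(self.class_order)
        }

    @property
    def macro_accuracy(self) -> float:
        return macro_activity_accuracy(self.confusion)

    def to_dict(self) -> dict:
        out = {
            "framework": self.framework,
            "class_order": list(self.class_order),
            "confusion": np.asarray(self.confusion).tolist(),
            "per_activity_accuracy": self.per_activity_accuracy,
            "macro_accuracy": self.macro_accuracy,
            "subject_ids": self.subject_ids,
            "recording_ids": self.recording_ids,
            "seed": self.seed,
        }
        if self.averaged_confusion is not None:
            out["averaged_confusion"] = np.asarray(self.averaged_confusion).tolist()
        out.update(self.extra)
        return out

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def write_confusion_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.confusion, index=list(self.class_order),
                     columns=list(self.class_order)).to_csv(path)
        return path

    def plot_confusion(self, path: str | Path) -> Path:
        """Write a heatmap of the (row-normalised) confusion matrix."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = np.asarray(self.confusion, dtype=np.float64)
        m = m / m.sum(axis=1, keepdims=True)
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(self.class_order)))
        ax.set_yticks(range(len(self.class_order)))
        ax.set_xticklabels(self.class_order, rotation=60, ha="right", fontsize=7)
        ax.set_yticklabels(self.class_order, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
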