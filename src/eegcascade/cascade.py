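"""The three-level hierarchical classifier of seven binary machines.

Level A decides the body region (hand vs ankle).  Level B holds one machine
per region and decides the side (left vs right).  Level C holds one machine
per (region, side) and decides whether the movement was executed or
imagined.  Composing the three stage outputs yields one of the eight
activity classes.

Each machine is an ensemble of bootstrap-resampled decision trees whose
prediction is the most popular label among the per-tree outputs, with ties
broken lexicographically so inference is deterministic.  B- and C-level
machines are trained on ground-truth-filtered subsets of the training data
but routed by the *predicted* upstream outputs at inference time, the
standard hierarchical-classifier arrangement.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import feature_columns
from .io_recordings import TaskLabel

__all__ = [
    "MACHINE_IDS",
    "MachineSpec",
    "VotingForest",
    "CascadeModel",
    "majority_vote",
    "train_cascade",
    "predict_cascade",
]

#: Fixed machine order: level A, level B (hand, ankle), level C
#: (left-hand, right-hand, left-ankle, right-ankle).
MACHINE_IDS = ("A", "B0", "B1", "C0", "C1", "C2", "C3")

#: machine id -> (target column, ground-truth subset predicate)
MACHINE_DEFS: dict[str, tuple[str, dict[str, str]]] = {
    "A": ("region", {}),
    "B0": ("side", {"region": "hand"}),
    "B1": ("side", {"region": "ankle"}),
    "C0": ("mode", {"region": "hand", "side": "left"}),
    "C1": ("mode", {"region": "hand", "side": "right"}),
    "C2": ("mode", {"region": "ankle", "side": "left"}),
    "C3": ("mode", {"region": "ankle", "side": "right"}),
}

#: (region, side) -> the level-C machine that resolves real vs imagery.
C_ROUTING = {
    ("hand", "left"): "C0",
    ("hand", "right"): "C1",
    ("ankle", "left"): "C2",
    ("ankle", "right"): "C3",
}

DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": "sqrt",
}


def majority_vote(tree_outputs: Sequence[str]) -> str:
    """Most popular label; ties resolved to the lexicographically smallest."""
    if len(tree_outputs) == 0:
        raise ValueError("cannot vote over an empty list")
    counts = Counter(tree_outputs)
    top = max(counts.values())
    return min(lab for lab, c in counts.items() if c == top)


class VotingForest:
    """Random forest whose prediction is a hard per-tree majority vote.

    Trees are grown by scikit-learn on bootstrap resamples; prediction
    collects each tree's label and applies :func:`majority_vote` per row
    (lexicographic tie-break), rather than averaging class probabilities.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int | None = None,
                 max_features: str | int | float = "sqrt",
                 random_state: int = 0):
        self._rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            max_features=max_features,
            bootstrap=True,
            random_state=random_state,
            n_jobs=1,
        )

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "VotingForest":
        self._rf.fit(np.asarray(X, dtype=np.float64), np.asarray(y))
        return self

    @property
    def classes_(self) -> np.ndarray:
        return self._rf.classes_

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_rows) array of per-tree predicted labels."""
        X = np.asarray(X, dtype=np.float64)
        classes = self._rf.classes_
        return np.stack([
            classes[tree.predict(X).astype(np.intp)]
            for tree in self._rf.estimators_
        ])

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = self.tree_votes(X)
        out = np.empty(votes.shape[1], dtype=object)
        # np.unique returns labels sorted, so argmax lands on the
        # lexicographically smallest label among tied maxima.
        for j in range(votes.shape[1]):
            labs, counts = np.unique(votes[:, j], return_counts=True)
            out[j] = labs[np.argmax(counts)]
        return out.astype(str)


@dataclass
class MachineSpec:
    """Configuration and provenance of one trained machine."""

    machine_id: str
    target: str
    subset: dict[str, str]
    selected_features: list[str]
    params: dict
    n_train_rows: int = 0
    train_accuracy: float = float("nan")


@dataclass
class CascadeModel:
    """The seven trained machines plus routing metadata."""

    machines: dict[str, VotingForest]
    specs: dict[str, MachineSpec]
    seed: int = 0

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict_cascade(self, rows)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "routing": {f"{r}/{s}": m for (r, s), m in C_ROUTING.items()},
            "machines": {},
        }
        for mid in MACHINE_IDS:
            joblib.dump(self.machines[mid], directory / f"machine_{mid}.joblib")
            spec = self.specs[mid]
            manifest["machines"][mid] = {
                "target": spec.target,
                "subset": spec.subset,
                "selected_features": spec.selected_features,
                "params": spec.params,
                "n_train_rows": spec.n_train_rows,
            }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        machines, specs = {}, {}
        for mid in MACHINE_IDS:
            machines[mid] = joblib.load(directory / f"machine_{mid}.joblib")
            info = manifest["machines"][mid]
            specs[mid] = MachineSpec(
                machine_id=mid,
                target=info["target"],
                subset=info["subset"],
                selected_features=info["selected_features"],
                params=info["params"],
                n_train_rows=info["n_train_rows"],
            )
        return cls(machines=machines, specs=specs, seed=manifest["seed"])


def _canonical_order(table: pd.DataFrame) -> pd.DataFrame:
    """Sort rows by provenance so training ignores incoming row order."""
    return table.sort_values(
        ["subject_id", "recording_id", "task_index", "window_index"],
        kind="mergesort",
    ).reset_index(drop=True)


def _machine_seed(base: np.random.SeedSequence, idx: int) -> int:
    return int(base.spawn(idx + 1)[idx].generate_state(1)[0] % (2 ** 31))


def train_cascade(train: pd.DataFrame,
                  val: pd.DataFrame | None = None,
                  selection=None,
                  grid: Mapping[str, Sequence] | None = None,
                  learner_params: Mapping | None = None,
                  seed: int = 0) -> CascadeModel:
    """Train the seven machines on ground-truth-filtered subsets.

    ``selection`` is an optional :class:`~eegcascade.model_selection.SelectionConfig`
    enabling greedy forward feature selection per machine (requires ``val``);
    ``grid`` optionally grid-searches learner hyperparameters on the selected
    features.  With both off, every machine uses all features and
    ``learner_params``.
    """
    from . import model_selection as msel  # local import avoids a cycle

    base_params = dict(DEFAULT_LEARNER_PARAMS)
    if learner_params:
        base_params.update(learner_params)
    ss = np.random.SeedSequence(seed)

    machines: dict[str, VotingForest] = {}
    specs: dict[str, MachineSpec] = {}
    feat_cols = feature_columns(train)

    for idx, mid in enumerate(MACHINE_IDS):
        target, subset = MACHINE_DEFS[mid]
        sub_train = _subset_rows(train, subset)
        classes = sorted(sub_train[target].unique())
        if len(classes) < 2:
            raise ValueError(
                f"machine {mid} training subset is missing a class "
                f"(saw only {classes} for target {target!r})"
            )
        sub_train = _canonical_order(sub_train)
        mseed = _machine_seed(ss, idx)

        selected = list(feat_cols)
        params = dict(base_params)
        if selection is not None:
            if val is None:
                raise ValueError("feature selection requires a validation table")
            sub_val = _canonical_order(_subset_rows(val, subset))
            if sub_val[target].nunique() < 2:
                raise ValueError(
                    f"machine {mid} validation subset is missing a class"
                )
            res = msel.greedy_forward_selection(
                sub_train, sub_val,
                learner_config=selection.learner_params or params,
                max_k=selection.max_k, tol=selection.tol,
                target=target, seed=mseed,
            )
            selected = res.selected
            if grid is not None:
                gres = msel.grid_search(
                    sub_train[selected + [target] + _PROV],
                    sub_val[selected + [target] + _PROV],
                    grid=grid, target=target, seed=mseed,
                )
                params.update(gres.best_params)
        elif grid is not None:
            if val is None:
                raise ValueError("grid search requires a validation table")
            sub_val = _canonical_order(_subset_rows(val, subset))
            gres = msel.grid_search(sub_train, sub_val, grid=grid,
                                    target=target, seed=mseed)
            params.update(gres.best_params)

        forest = VotingForest(random_state=mseed, **params)
        forest.fit(sub_train[selected].to_numpy(), sub_train[target].to_numpy())
        train_acc = float(
            (forest.predict(sub_train[selected].to_numpy())
             == sub_train[target].to_numpy()).mean()
        )
        machines[mid] = forest
        specs[mid] = MachineSpec(
            machine_id=mid, target=target, subset=dict(subset),
            selected_features=list(selected), params=params,
            n_train_rows=len(sub_train), train_accuracy=train_acc,
        )
    return CascadeModel(machines=machines, specs=specs, seed=seed)


_PROV = ["subject_id", "recording_id", "task_index", "window_index"]


def _subset_rows(table: pd.DataFrame, subset: Mapping[str, str]) -> pd.DataFrame:
    mask = np.ones(len(table), dtype=bool)
    for col, value in subset.items():
        mask &= (table[col] == value).to_numpy()
    return table.loc[mask]


def _machine_X(model: CascadeModel, mid: str, rows: pd.DataFrame) -> np.ndarray:
    feats = model.specs[mid].selected_features
    missing = [f for f in feats if f not in rows.columns]
    if missing:
        raise KeyError(
            f"rows are missing features required by machine {mid}: {missing}"
        )
    return rows[feats].to_numpy()


def predict_cascade(model: CascadeModel, rows: pd.DataFrame) -> np.ndarray:
    """Predict the 8-way activity label for every row.

    Equivalent, by construction, to composing the three stage predictions:
    region from A, side from the routed B machine, mode from the routed C
    machine.
    """
    n = len(rows)
    regions = model.machines["A"].predict(_machine_X(model, "A", rows))
    sides = np.empty(n, dtype=object)
    modes = np.empty(n, dtype=object)

    b_preds = {
        mid: model.machines[mid].predict(_machine_X(model, mid, rows))
        for mid in ("B0", "B1")
    }
    sides[regions == "hand"] = b_preds["B0"][regions == "hand"]
    sides[regions == "ankle"] = b_preds["B1"][regions == "ankle"]

    c_preds = {
        mid: model.machines[mid].predict(_machine_X(model, mid, rows))
        for mid in ("C0", "C1", "C2", "C3")
    }
    for (region, side), mid in C_ROUTING.items():
        mask = (regions == region) & (sides == side)
        modes[mask] = c_preds[mid][mask]

    return np.array([
        TaskLabel(region=r, side=s, mode=m).name
        for r, s, m in zip(regions, sides, modes)
    ])
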