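"""Greedy forward feature selection and hyperparameter grid search.

Each of the seven machines selects its own inputs: starting from the empty
set, the feature whose addition maximises validation accuracy of a freshly
retrained learner is added, until the improvement drops below ``tol`` or
``max_k`` features are selected.  The resulting accuracy-vs-inputs curve
typically saturates after a handful of features.  A grid search over the
forest's hyperparameters can then be run on the selected set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import feature_columns

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "GridSearchResult",
    "greedy_forward_selection",
    "grid_search",
    "render_selection_report",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for per-machine greedy forward selection."""

    max_k: int = 10
    tol: float = 0.001
    #: learner hyperparameters used during selection (falls back to the
    #: cascade's learner parameters when None)
    learner_params: dict | None = None


@dataclass
class SelectionResult:
    """Ordered selected features and the validation-accuracy curve."""

    selected: list[str]
    accuracy_curve: list[float]
    stopping_reason: str

    @property
    def best_accuracy(self) -> float:
        return self.accuracy_curve[-1] if self.accuracy_curve else float("nan")


@dataclass
class GridSearchResult:
    best_params: dict
    results: list[tuple[dict, float]]


def _fit_and_score(train: pd.DataFrame, val: pd.DataFrame, feats: list[str],
                   target: str, params: Mapping, seed: int) -> float:
    from .cascade import VotingForest

    forest = VotingForest(random_state=seed, **dict(params))
    forest.fit(train[feats].to_numpy(), train[target].to_numpy())
    preds = forest.predict(val[feats].to_numpy())
    return float((preds == val[target].to_numpy()).mean())


def greedy_forward_selection(train: pd.DataFrame, val: pd.DataFrame,
                             learner_config: Mapping | None = None,
                             max_k: int = 10, tol: float = 0.001,
                             target: str = "label",
                             seed: int = 0) -> SelectionResult:
    """Select features one at a time by validation accuracy.

    Deterministic given ``seed``: candidate ties are resolved by column
    order and the learner is retrained with the same seed at every step.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    candidates = [c for c in feature_columns(train) if c in val.columns]
    if not candidates:
        raise ValueError("train and val share no feature columns")
    if max_k > len(candidates):
        warnings.warn(
            f"max_k={max_k} exceeds the {len(candidates)} available features; "
            "clamping", stacklevel=2,
        )
        max_k = len(candidates)

    from .cascade import DEFAULT_LEARNER_PARAMS

    params = dict(DEFAULT_LEARNER_PARAMS)
    if learner_config:
        params.update(learner_config)

    selected: list[str] = []
    curve: list[float] = []
    best_so_far = 0.0
    reason = f"reached max_k={max_k}"
    while len(selected) < max_k:
        scores = [
            _fit_and_score(train, val, selected + [c], target, params, seed)
            for c in candidates if c not in selected
        ]
        remaining = [c for c in candidates if c not in selected]
        j = int(np.argmax(scores))  # ties -> first in column order
        best_c, best_acc = remaining[j], scores[j]
        if best_acc - best_so_far < tol and selected:
            reason = f"improvement {best_acc - best_so_far:.4f} < tol={tol:g}"
            break
        selected.append(best_c)
        curve.append(best_acc)
        best_so_far = best_acc
    return SelectionResult(selected=selected, accuracy_curve=curve,
                           stopping_reason=reason)


def grid_search(train: pd.DataFrame, val: pd.DataFrame,
                grid: Mapping[str, Sequence], target: str = "label",
                base_params: Mapping | None = None,
                seed: int = 0) -> GridSearchResult:
    """Exhaustive search over a parameter lattice, ties to first-in-lattice.

    ``grid`` maps parameter names to candidate values; every point of the
    Cartesian product (in insertion order) is evaluated on the validation
    table with a learner retrained from scratch.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    feats = [c for c in feature_columns(train) if c in val.columns]

    from .cascade import DEFAULT_LEARNER_PARAMS

    base = dict(DEFAULT_LEARNER_PARAMS)
    if base_params:
        base.update(base_params)

    keys = list(grid.keys())
    results: list[tuple[dict, float]] = []
    best_params, best_acc = None, -1.0
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        params = {**base, **point}
        acc = _fit_and_score(train, val, feats, target, params, seed)
        results.append((point, acc))
        if acc > best_acc:  # strict: first-in-lattice wins ties
            best_params, best_acc = point, acc
    return GridSearchResult(best_params=dict(best_params), results=results)


def render_selection_report(specs: Mapping[str, "object"],
                            single_channel: bool = False) -> pd.DataFrame:
    """Summarise per-machine selections as (machine, moments[, channels]).

    Mirrors the shape of the study-style per-machine selection tables:
    which moment orders and which channels each machine ended up using.
    ``specs`` maps machine id to an object with ``selected_features`` named
    ``<channel>_m<order>``.
    """
    rows = []
    for mid in sorted(specs.keys()):
        feats = specs[mid].selected_features
        orders, channels = [], []
        for f in feats:
            ch, m = f.rsplit("_m", 1)
            orders.append(int(m))
            channels.append(ch)
        row = {
            "Machine": mid,
            "Moments": ", ".join(str(k) for k in sorted(set(orders))),
        }
        if not single_channel:
            row["Channels"] = ", ".join(sorted(set(channels)))
        rows.append(row)
    return pd.DataFrame(rows)
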