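"""End-to-end drivers: recording -> features -> framework -> report.

These functions wire the stage modules together the way the command-line
interface and the reproduction script use them: filter the continuous
recording, locate the trigger pulses, segment into labelled task epochs,
trim 5 s from each end, dice into windows, compute moment features, then
train and evaluate the cascade under one of the three frameworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from .cascade import CascadeModel, train_cascade, predict_cascade
from .features import MomentSpec, build_feature_table
from .io_recordings import Protocol, Recording, detect_trigger_pulses, segment_tasks
from .model_selection import SelectionConfig
from .preprocess import FilterSpec, bandpass_filter, trim_epoch, window_epoch
from .synthetic import SimulationConfig, simulate_recording

__all__ = [
    "PreprocessConfig",
    "CascadeConfig",
    "featurize_recording",
    "simulate_feature_tables",
    "run_framework1",
    "run_framework2",
    "run_framework3",
    "run_framework3_auto",
]


@dataclass(frozen=True)
class PreprocessConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    trim_s: float = 5.0
    win_len_s: float = 2.0
    overlap_frac: float = 0.5
    trigger_threshold: float = 0.5
    trigger_min_width_s: float = 0.25
    boundary_mode: str = "shared"


@dataclass(frozen=True)
class CascadeConfig:
    """Learner settings shared by all seven machines.

    ``selection`` / ``grid`` are optional; when off, each machine trains a
    fixed-parameter forest on all features, which is the desk-scale default
    for the framework comparisons (selection and grid search remain
    available and are exercised independently).
    """

    learner_params: dict = field(default_factory=dict)
    selection: SelectionConfig | None = None
    grid: dict | None = None


def featurize_recording(recording: Recording,
                        pp: PreprocessConfig = PreprocessConfig(),
                        moments: MomentSpec = MomentSpec(),
                        protocol: Protocol = Protocol()) -> pd.DataFrame:
    """Full preprocessing + feature extraction for one recording."""
    filtered = Recording(
        signals=bandpass_filter(recording.signals, recording.fs, pp.filter),
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        trigger=recording.trigger,
        subject_id=recording.subject_id,
        recording_id=recording.recording_id,
    )
    pulses = detect_trigger_pulses(filtered.trigger, filtered.fs,
                                   pp.trigger_threshold, pp.trigger_min_width_s)
    epochs = segment_tasks(filtered, pulses, protocol, pp.boundary_mode)
    windows = []
    for epoch in epochs:
        trimmed = trim_epoch(epoch, pp.trim_s)
        windows.extend(window_epoch(trimmed, pp.win_len_s, pp.overlap_frac))
    return build_feature_table(windows, moments)


def simulate_feature_tables(sim: SimulationConfig,
                            pp: PreprocessConfig = PreprocessConfig(),
                            moments: MomentSpec = MomentSpec(),
                            ) -> dict[str, list[pd.DataFrame]]:
    """Simulate the whole study and featurize it, keyed by subject id."""
    tables: dict[str, list[pd.DataFrame]] = {}
    for s in range(sim.n_subjects):
        per_subject = []
        for r in range(sim.n_recordings):
            rec = simulate_recording(sim, s, r)
            per_subject.append(featurize_recording(rec, pp, moments,
                                                   sim.protocol))
        tables[per_subject[0]["subject_id"].iloc[0]] = per_subject
    return tables


def _evaluate_plan(plan: ev.SplitPlan, cc: CascadeConfig, seed: int,
                   ) -> tuple[CascadeModel, ev.EvaluationReport]:
    model = train_cascade(plan.train, plan.val,
                          selection=cc.selection, grid=cc.grid,
                          learner_params=cc.learner_params, seed=seed)
    test = plan.test
    preds = predict_cascade(model, test)
    confusion = ev.confusion_matrix(test["label"].to_numpy(), preds)
    report = ev.EvaluationReport(
        framework=plan.framework,
        confusion=confusion,
        subject_ids=sorted(plan.table["subject_id"].unique()),
        recording_ids=sorted(plan.table["recording_id"].unique()),
        seed=seed,
        extra={"fractions": list(plan.fractions)},
    )
    return model, report


def run_framework1(tables: Mapping[str, Sequence[pd.DataFrame]],
                   cc: CascadeConfig = CascadeConfig(), seed: int = 0,
                   recording_index: int = 0,
                   ) -> dict[str, ev.EvaluationReport]:
    """Within-recording evaluation, one report per subject."""
    reports = {}
    for sid in sorted(tables):
        plan = ev.split_framework1(tables[sid][recording_index], seed=seed)
        _, reports[sid] = _evaluate_plan(plan, cc, seed)
    return reports


def run_framework2(tables: Mapping[str, Sequence[pd.DataFrame]],
                   cc: CascadeConfig = CascadeConfig(), seed: int = 0,
                   ) -> dict[str, ev.EvaluationReport]:
    """Cross-session evaluation (first recording trains, second tests)."""
    reports = {}
    for sid in sorted(tables):
        recs = tables[sid]
        if len(recs) < 2:
            raise ValueError(f"subject {sid} needs 2 recordings for Framework 2")
        plan = ev.split_framework2(recs[0], recs[1], seed=seed)
        _, reports[sid] = _evaluate_plan(plan, cc, seed)
    return reports


def run_framework3(tables: Mapping[str, Sequence[pd.DataFrame]],
                   best_id: str, worst_id: str,
                   cc: CascadeConfig = CascadeConfig(), seed: int = 0,
                   ) -> ev.EvaluationReport:
    """Cross-subject evaluation; also reports the averaged confusion matrix
    over the held-out subjects (entrywise mean of row-normalised
    per-subject matrices)."""
    plan = ev.split_framework3(tables, best_id, worst_id, seed=seed)
    model, report = _evaluate_plan(plan, cc, seed)
    test = plan.test
    per_subject = []
    for sid in sorted(test["subject_id"].unique()):
        sub = test[test["subject_id"] == sid]
        preds = predict_cascade(model, sub)
        per_subject.append(ev.confusion_matrix(sub["label"].to_numpy(), preds))
    report.averaged_confusion = ev.average_confusion(per_subject)
    report.extra["train_subjects"] = [best_id, worst_id]
    return report


def run_framework3_auto(tables: Mapping[str, Sequence[pd.DataFrame]],
                        cc: CascadeConfig = CascadeConfig(), seed: int = 0,
                        ) -> tuple[ev.EvaluationReport, dict[str, ev.EvaluationReport]]:
    """Framework 3 with best/worst subjects chosen by Framework 1 first."""
    fw1 = run_framework1(tables, cc, seed)
    best_id, worst_id = ev.best_worst_subjects(fw1)
    if best_id == worst_id:  # every subject tied; take the extreme ids
        worst_id = [s for s in sorted(fw1) if s != best_id][-1]
    return run_framework3(tables, best_id, worst_id, cc, seed), fw1
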