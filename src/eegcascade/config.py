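"""Single-file YAML configuration for the command-line pipeline.

One YAML document with per-stage blocks::

    io:
      dialect: csv            # or edf
      dataset_dir: data/
    preprocess:
      filter: {low_hz: 0.5, high_hz: 59, order: 3, application: zero_phase}
      trim_s: 5
      win_len_s: 2.0
      overlap_frac: 0.5
    features:
      orders: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      kind: central
    cascade:
      learner: {n_estimators: 100, max_depth: null, max_features: sqrt}
      selection: {max_k: 10, tol: 0.001}   # optional block
      grid: {n_estimators: [50, 100, 200]} # optional block
    simulation:
      n_subjects: 9
      n_recordings: 2
      montage: vamp16
    seed: 0

Unknown keys anywhere raise, so typos fail loudly.  All randomness flows
from the single master ``seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .features import MomentSpec
from .io_recordings import Protocol
from .model_selection import SelectionConfig
from .pipeline import CascadeConfig, PreprocessConfig
from .preprocess import FilterSpec
from .synthetic import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


def _strict(cls, mapping: Mapping[str, Any], context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context!r}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class IOConfig:
    dialect: str = "csv"
    dataset_dir: str = "dataset"


@dataclass(frozen=True)
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: MomentSpec = field(default_factory=MomentSpec)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    #: sha256 of the YAML source, for provenance blocks in reports
    config_hash: str = ""


def _build_preprocess(block: Mapping[str, Any]) -> PreprocessConfig:
    block = dict(block)
    filt = block.pop("filter", {})
    spec = _strict(FilterSpec, filt, "preprocess.filter")
    return _strict(PreprocessConfig, {**block, "filter": spec}, "preprocess")


def _build_features(block: Mapping[str, Any]) -> MomentSpec:
    block = dict(block)
    if "orders" in block:
        block["orders"] = tuple(block["orders"])
    return _strict(MomentSpec, block, "features")


def _build_cascade(block: Mapping[str, Any]) -> CascadeConfig:
    block = dict(block)
    learner = block.pop("learner", {})
    selection = block.pop("selection", None)
    grid = block.pop("grid", None)
    if block:
        raise ValueError(f"unknown keys in 'cascade': {sorted(block)}")
    sel = _strict(SelectionConfig, selection, "cascade.selection") \
        if selection is not None else None
    return CascadeConfig(learner_params=dict(learner), selection=sel,
                         grid=dict(grid) if grid else None)


def _build_simulation(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    block = dict(block)
    block.setdefault("seed", seed)
    proto = block.pop("protocol", None)
    if proto is not None:
        # only the per-task duration is configurable from YAML; the task
        # order is the fixed study protocol
        block["protocol"] = Protocol(
            task_duration_s=float(proto.get("task_duration_s", 30.0)))
    return _strict(SimulationConfig, block, "simulation")


def load_config(path: str | Path | None = None,
                seed_override: int | None = None) -> PipelineConfig:
    """Parse a YAML config file; ``None`` yields the package defaults."""
    if path is None:
        text = "{}"
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    known = {"io", "preprocess", "features", "cascade", "simulation", "seed"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    seed = int(doc.get("seed", 0))
    if seed_override is not None:
        seed = seed_override
    return PipelineConfig(
        io=_strict(IOConfig, doc.get("io", {}), "io"),
        preprocess=_build_preprocess(doc.get("preprocess", {})),
        features=_build_features(doc.get("features", {})),
        cascade=_build_cascade(doc.get("cascade", {})),
        simulation=_build_simulation(doc.get("simulation", {}), seed),
        seed=seed,
        config_hash=hashlib.sha256(text.encode()).hexdigest(),
    )
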