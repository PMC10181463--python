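"""Statistical-moment features.

Each analysis window is summarised, per channel, by its statistical moments
of orders 1 through 10.  Three conventions are supported:

* ``raw`` — E[x^k];
* ``central`` (default) — the mean for order 1, E[(x - mean)^k] for k >= 2;
* ``standardized`` — central moments divided by sigma^k (skewness at order
  3, kurtosis at order 4, and so on), scale-free.

Even central orders describe dispersion and tail weight, odd orders
asymmetry; together they characterise the per-window amplitude distribution
that the cascade's binary machines split on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import Window

__all__ = [
    "MomentSpec",
    "META_COLUMNS",
    "statistical_moments",
    "build_feature_table",
    "feature_columns",
]

#: Non-feature columns of a feature table (label + provenance).
META_COLUMNS = (
    "label", "region", "side", "mode",
    "subject_id", "recording_id", "task_index", "window_index",
)

_KINDS = ("raw", "central", "standardized")


@dataclass(frozen=True)
class MomentSpec:
    """Which moment orders to compute and under which convention."""

    orders: tuple[int, ...] = tuple(range(1, 11))
    kind: str = "central"
    #: z-score each window before computing central moments (literal-definition
    #: preserving when off; see the methods note for why off is the default).
    normalize_input: bool = False

    def __post_init__(self) -> None:
        if len(self.orders) == 0:
            raise ValueError("orders must be non-empty")
        if any(k < 1 or k > 10 for k in self.orders):
            raise ValueError("orders must lie in 1..10")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")


def _moment_block(x: np.ndarray, spec: MomentSpec) -> np.ndarray:
    """Moments along the last axis; output shape = x.shape[:-1] + (n_orders,)."""
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples per window")
    mean = x.mean(axis=-1, keepdims=True)
    if spec.kind == "raw":
        base = x
    else:
        base = x - mean
        if spec.normalize_input and spec.kind == "central":
            sd = base.std(axis=-1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError("zero-variance window cannot be normalized")
            base = base / sd
    max_order = max(spec.orders)
    powers = np.empty(x.shape[:-1] + (max_order,), dtype=np.float64)
    p = base.copy()
    powers[..., 0] = p.mean(axis=-1)
    for k in range(2, max_order + 1):
        p = p * base
        powers[..., k - 1] = p.mean(axis=-1)

    out = np.empty(x.shape[:-1] + (len(spec.orders),), dtype=np.float64)
    m2 = powers[..., 1] if max_order >= 2 else None
    for j, k in enumerate(spec.orders):
        if k == 1:
            out[..., j] = mean[..., 0]
        elif spec.kind == "standardized":
            if np.any(m2 == 0):
                raise ValueError("zero-variance window has no standardized moments")
            out[..., j] = powers[..., k - 1] / m2 ** (k / 2.0)
        else:
            out[..., j] = powers[..., k - 1]
    return out


def statistical_moments(window: np.ndarray,
                        spec: MomentSpec = MomentSpec()) -> np.ndarray:
    """Per-order moments of a single-channel series (1-D input, 1-D output)."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("statistical_moments expects a 1-D series")
    return _moment_block(x, spec)


def build_feature_table(windows: Sequence[Window],
                        spec: MomentSpec = MomentSpec()) -> pd.DataFrame:
    """Assemble windows into a (windows x (channel, order)) feature table.

    Columns are channel-major (all orders of channel 1, then channel 2, ...)
    and named ``<channel>_m<order>``; label and provenance columns follow.
    """
    if len(windows) == 0:
        raise ValueError("cannot build a feature table from 0 windows")
    labels0 = tuple(windows[0].channel_labels)
    n0 = windows[0].n_samples
    for w in windows:
        if tuple(w.channel_labels) != labels0:
            raise ValueError("windows have heterogeneous channel sets")
        if w.n_samples != n0:
            raise ValueError("windows have heterogeneous lengths")

    stack = np.stack([w.signals for w in windows])  # (n_win, n_ch, n_samp)
    moments = _moment_block(stack, spec)  # (n_win, n_ch, n_orders)
    n_win = moments.shape[0]
    feat = moments.reshape(n_win, -1)
    names = [f"{ch}_m{k}" for ch in labels0 for k in spec.orders]

    table = pd.DataFrame(feat, columns=names)
    table["label"] = [w.label.name for w in windows]
    table["region"] = [w.label.region for w in windows]
    table["side"] = [w.label.side for w in windows]
    table["mode"] = [w.label.mode for w in windows]
    table["subject_id"] = [w.subject_id for w in windows]
    table["recording_id"] = [w.recording_id for w in windows]
    table["task_index"] = [w.task_index for w in windows]
    table["window_index"] = [w.window_index for w in windows]
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature (non-metadata) columns of a feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]
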