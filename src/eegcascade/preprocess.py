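"""Band-pass filtering, epoch trimming, and fixed-length windowing.

The study's preprocessing is a 3rd-order Butterworth band-pass from 0.5 Hz
to 59 Hz: the low edge removes baseline drift (eye movement, breathing,
sweat), the high edge rejects 60 Hz powerline hum while keeping delta
through low-gamma rhythms.  Each 30 s task epoch is then trimmed by 5 s at
both ends (transition effects around the instruction change) and diced into
fixed-length windows, each of which becomes one classification example.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_recordings import TaskEpoch, TaskLabel

__all__ = [
    "FilterSpec",
    "Window",
    "DEFAULT_MONTAGE_16",
    "bandpass_filter",
    "frequency_response",
    "trim_epoch",
    "window_epoch",
]

#: Default 10–20 labels for the 16-channel research montage.
DEFAULT_MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3",
    "C4", "Cz", "P3", "P4", "Pz", "O1", "O2", "T8",
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design parameters.

    ``application="zero_phase"`` filters forward and backward (no group
    delay, squared magnitude response); ``"causal"`` is a single forward
    pass.  Offline analysis defaults to zero-phase so moment features are
    not distorted by phase shifts.
    """

    low_hz: float = 0.5
    high_hz: float = 59.0
    order: int = 3
    application: str = "zero_phase"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below Nyquist ({fs / 2:g} Hz)"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.application not in ("causal", "zero_phase"):
            raise ValueError(f"unknown application {self.application!r}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, [self.low_hz, self.high_hz],
                          btype="bandpass", fs=fs, output="sos")


def bandpass_filter(signals: np.ndarray, fs: float,
                    spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Filter each channel independently along the last axis."""
    signals = np.asarray(signals, dtype=np.float64)
    sos = spec.sos(fs)
    if spec.application == "zero_phase":
        return sps.sosfiltfilt(sos, signals, axis=-1)
    return sps.sosfilt(sos, signals, axis=-1)


def frequency_response(spec: FilterSpec, fs: float,
                       freqs: Sequence[float]) -> np.ndarray:
    """Magnitude response of the designed filter at ``freqs`` (Hz).

    For zero-phase application the effective magnitude is squared (the
    forward-backward pass applies the filter twice).
    """
    sos = spec.sos(fs)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
    mag = np.abs(h)
    if spec.application == "zero_phase":
        mag = mag ** 2
    return mag


def trim_epoch(epoch: TaskEpoch, trim_s: float = 5.0) -> TaskEpoch:
    """Discard ``trim_s`` seconds from both ends of an epoch."""
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    n_trim = int(round(trim_s * epoch.fs))
    if epoch.n_samples <= 2 * n_trim:
        raise ValueError(
            f"epoch of {epoch.duration_s:.2f} s too short to trim "
            f"{trim_s:g} s from each end"
        )
    if n_trim == 0:
        return epoch
    return TaskEpoch(
        signals=epoch.signals[:, n_trim:epoch.n_samples - n_trim],
        fs=epoch.fs,
        channel_labels=list(epoch.channel_labels),
        label=epoch.label,
        subject_id=epoch.subject_id,
        recording_id=epoch.recording_id,
        task_index=epoch.task_index,
    )


@dataclass
class Window:
    """One fixed-length analysis window: a single classification example."""

    signals: np.ndarray
    fs: float
    channel_labels: list[str]
    label: TaskLabel
    subject_id: str
    recording_id: str
    task_index: int
    window_index: int

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def window_epoch(epoch: TaskEpoch, win_len_s: float = 2.0,
                 overlap_frac: float = 0.5) -> list[Window]:
    """Slice an epoch into fixed-length windows.

    Yields ``floor((N - w) / step) + 1`` windows where ``w`` is the window
    length and ``step = w * (1 - overlap_frac)`` (both in samples).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    w = int(round(win_len_s * epoch.fs))
    if w < 2:
        raise ValueError("window too short")
    if w > epoch.n_samples:
        raise ValueError(
            f"window of {win_len_s:g} s exceeds epoch duration "
            f"{epoch.duration_s:.2f} s"
        )
    step = max(1, int(round(w * (1 - overlap_frac))))
    count = (epoch.n_samples - w) // step + 1
    return [
        Window(
            signals=epoch.signals[:, i * step:i * step + w],
            fs=epoch.fs,
            channel_labels=list(epoch.channel_labels),
            label=epoch.label,
            subject_id=epoch.subject_id,
            recording_id=epoch.recording_id,
            task_index=epoch.task_index,
            window_index=i,
        )
        for i in range(count)
    ]
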