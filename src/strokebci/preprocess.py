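"""Channel-set resolution, epoching, and band-pass / filter-bank filtering.

The decoding pipelines restrict the montage to hemisphere-specific channel
sets (nine electrodes over each sensorimotor cortex, or their 14-channel
bilateral union), cut task and baseline epochs around cue events, and apply
zero-phase Butterworth band-pass filters — either a single 8–30 Hz band
(CSP, band power) or a nine-band 4–40 Hz filter bank (FBCSP).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .montage import normalize_label
from .simulate import ContinuousRecording

__all__ = [
    "LEFT_SET", "RIGHT_SET", "ChannelSets", "EpochSet", "FilterBankSpec",
    "resolve_channel_sets", "epoch_session", "bandpass_filter",
    "apply_filter_bank",
]

#: nine channels covering the left sensorimotor cortex
LEFT_SET: tuple[str, ...] = ("FC3", "FCz", "T7", "C3", "Cz", "CP3", "CPz", "P3", "Pz")
#: nine channels covering the right sensorimotor cortex
RIGHT_SET: tuple[str, ...] = ("FCz", "FC4", "Cz", "C4", "T8", "CPz", "CP4", "Pz", "P4")


@dataclass(frozen=True)
class ChannelSets:
    """Ipsilesional / contralesional / bilateral channel lists for a patient.

    The bilateral set is the 14-channel union of the left and right sets
    (midline channels FCz, Cz, CPz, Pz appear once).
    """

    lesion_side: Literal["left", "right"]
    ipsilesional: tuple[str, ...]
    contralesional: tuple[str, ...]
    bilateral: tuple[str, ...]

    def get(self, name: str) -> tuple[str, ...]:
        if name not in ("ipsilesional", "contralesional", "bilateral"):
            raise KeyError(f"unknown channel set {name!r}")
        return getattr(self, name)


def resolve_channel_sets(lesion_side: Literal["left", "right"],
                         available_channels: Sequence[str]) -> ChannelSets:
    """Map a lesion side onto ipsilesional/contralesional/bilateral sets.

    A left lesion makes the left-hemisphere set ipsilesional. Raises
    ``KeyError`` naming the first required channel missing from
    ``available_channels``.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be 'left' or 'right', got {lesion_side!r}")
    have = {normalize_label(c) for c in available_channels}
    bilateral = LEFT_SET + tuple(c for c in RIGHT_SET if c not in LEFT_SET)
    for ch in bilateral:
        if normalize_label(ch) not in have:
            raise KeyError(f"required channel {ch!r} not in available_channels")
    if lesion_side == "left":
        ipsi, contra = LEFT_SET, RIGHT_SET
    else:
        ipsi, contra = RIGHT_SET, LEFT_SET
    return ChannelSets(lesion_side=lesion_side, ipsilesional=ipsi,
                       contralesional=contra, bilateral=bilateral)


@dataclass
class EpochSet:
    """Fixed-length trials cut around cue events.

    ``data`` is trials x channels x samples (µV); ``window`` is
    ``(start_s, end_s)`` relative to the cue with half-open sample
    convention ``[start, end)``; ``role`` marks task vs baseline epochs;
    ``band`` tags the band-pass applied, if any.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    window: tuple[float, float]
    role: Literal["task", "baseline"] = "task"
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), "
                             f"got shape {self.data.shape}")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must equal channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate_hz

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        """Subset and reorder channels by name (case-insensitive)."""
        lookup = {normalize_label(c): i for i, c in enumerate(self.channel_names)}
        idx = []
        for name in names:
            key = normalize_label(name)
            if key not in lookup:
                raise KeyError(f"channel {name!r} not present in epochs")
            idx.append(lookup[key])
        return replace(self, data=self.data[:, idx, :],
                       channel_names=tuple(names))

    def select_trials(self, indices: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return replace(self, data=self.data[idx], labels=self.labels[idx])


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered list of (low_hz, high_hz) band edges."""

    bands: tuple[tuple[float, float], ...] = tuple(
        (low, low + 4.0) for low in np.arange(4.0, 40.0, 4.0)
    )

    def __post_init__(self) -> None:
        for low, high in self.bands:
            if not low < high:
                raise ValueError(f"degenerate band ({low}, {high})")

    def __len__(self) -> int:
        return len(self.bands)


def epoch_session(recording: ContinuousRecording,
                  window: tuple[float, float],
                  role: Literal["task", "baseline"] = "task") -> EpochSet:
    """Cut one epoch per event over ``[onset + start_s, onset + end_s)``.

    Sample counts are exact: ``round((end_s - start_s) * rate)`` samples per
    trial, half-open so adjacent windows never share a sample. Raises
    ``IndexError`` reporting the first event whose window leaves the
    recording.
    """
    start_s, end_s = window
    if not end_s > start_s:
        raise ValueError(f"window end {end_s} must exceed start {start_s}")
    fs = recording.sampling_rate_hz
    n_samp = int(round((end_s - start_s) * fs))
    start_off = int(round(start_s * fs))

    n_events = len(recording.events)
    data = np.empty((n_events, len(recording.channel_names), n_samp))
    labels = np.empty(n_events, dtype=int)
    for i, (onset, label) in enumerate(recording.events):
        lo = onset + start_off
        hi = lo + n_samp
        if lo < 0 or hi > recording.n_samples:
            raise IndexError(
                f"event {i} (onset sample {onset}) window [{lo}, {hi}) lies "
                f"outside the recording of {recording.n_samples} samples")
        data[i] = recording.data[:, lo:hi]
        labels[i] = label
    return EpochSet(data=data, labels=labels,
                    channel_names=tuple(recording.channel_names),
                    sampling_rate_hz=fs, window=(start_s, end_s), role=role)


def _design_bandpass(low_hz: float, high_hz: float, fs: float,
                     order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(epochs: EpochSet, low_hz: float, high_hz: float) -> EpochSet:
    """Zero-phase Butterworth band-pass, applied per trial and channel.

    4th-order design run forward–backward (``sosfiltfilt``, effective 8th
    order) with odd-reflection padding, so the net group delay is zero and
    ERD/ERS timing is preserved.
    """
    sos = _design_bandpass(low_hz, high_hz, epochs.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=filtered, band=(low_hz, high_hz))


def apply_filter_bank(epochs: EpochSet,
                      spec: FilterBankSpec | None = None) -> list[EpochSet]:
    """Filter the epochs through each band of the bank, in spec order."""
    if spec is None:
        spec = FilterBankSpec()
    return [bandpass_filter(epochs, low, high) for low, high in spec.bands]
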