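"""Event-related desynchronization/synchronization mapping.

Two baseline-referenced quantities: a time–frequency map of percent power
change (sliding tapered periodograms, trial-averaged, each frequency row
referenced to its pre-cue baseline mean) and a broadband ERD/ERS time
course (8–30 Hz power, trial-averaged, smoothed, percent change vs the
1.5 s preparation period). Both are scale-invariant — multiplying the raw
EEG by any positive constant leaves them unchanged — so maps from
different patients can be pooled into grand averages at the C3/C4 channel
resolved through each patient's lesion side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .montage import normalize_label
from .preprocess import EpochSet, bandpass_filter

__all__ = [
    "TFMap", "ERDCurve", "time_frequency_map", "erd_ers_curve",
    "grand_average", "hemisphere_channel",
]

DEFAULT_BASELINE = (-1.5, 0.0)


@dataclass
class TFMap:
    """Trial-averaged percent power change, times × freqs, one channel."""

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    baseline_window: tuple[float, float]
    channel: str
    n: int = 1


@dataclass
class ERDCurve:
    """Broadband percent power change over time, one channel."""

    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    baseline_window: tuple[float, float]
    channel: str
    n: int = 1


def hemisphere_channel(lesion_side: Literal["left", "right"],
                       side: Literal["ipsilesional", "contralesional"]) -> str:
    """Sensorimotor channel (C3/C4) of the requested hemisphere.

    C3 sits over the left hemisphere, so a left lesion puts the
    ipsilesional electrode at C3.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be 'left' or 'right', got {lesion_side!r}")
    if side not in ("ipsilesional", "contralesional"):
        raise ValueError(f"side must be 'ipsilesional' or 'contralesional', "
                         f"got {side!r}")
    ipsi_is_left = lesion_side == "left"
    want_left = ipsi_is_left if side == "ipsilesional" else not ipsi_is_left
    return "C3" if want_left else "C4"


def _channel_index(epochs: EpochSet, channel: str) -> int:
    lookup = {normalize_label(c): i for i, c in enumerate(epochs.channel_names)}
    key = normalize_label(channel)
    if key not in lookup:
        raise KeyError(f"channel {channel!r} not present in epochs")
    return lookup[key]


def time_frequency_map(epochs: EpochSet,
                       channel: str,
                       window_s: float = 1.0,
                       step_s: float = 0.1,
                       freq_range: tuple[float, float] = (4.0, 40.0),
                       baseline_window: tuple[float, float] = DEFAULT_BASELINE,
                       ) -> TFMap:
    """Sliding-window power spectra, trial-averaged, baseline-referenced.

    Per trial, Hann-tapered periodograms are computed in windows of
    ``window_s`` advanced by ``step_s``; powers are averaged across trials,
    and every frequency row is expressed as 100·(P − P_base)/P_base where
    P_base is that row's mean over the windows fully inside
    ``baseline_window``. Times index window centres.
    """
    fs = epochs.sampling_rate_hz
    n_win = int(round(window_s * fs))
    if n_win >= epochs.n_samples:
        raise ValueError("window_s must be shorter than the epoch")
    if epochs.n_trials == 0:
        raise ValueError("no trials to average")
    ch = _channel_index(epochs, channel)
    x = epochs.data[:, ch, :]

    step = max(1, int(round(step_s * fs)))
    starts = np.arange(0, epochs.n_samples - n_win + 1, step)
    t0 = epochs.window[0]
    centres = t0 + (starts + n_win / 2.0) / fs

    taper = sps.windows.hann(n_win, sym=False)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    fmask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    if not fmask.any():
        raise ValueError(f"freq_range {freq_range} contains no FFT bins at "
                         f"window {window_s}s, rate {fs} Hz")

    # trials x windows x samples -> mean power over trials
    segs = np.stack([x[:, s:s + n_win] for s in starts], axis=1) * taper
    power = np.abs(np.fft.rfft(segs, axis=-1)) ** 2
    mean_power = power.mean(axis=0)[:, fmask]        # windows x freqs

    base_lo, base_hi = baseline_window
    base_mask = ((centres - window_s / 2.0 >= base_lo - 1e-9)
                 & (centres + window_s / 2.0 <= base_hi + 1e-9))
    if not base_mask.any():
        raise ValueError(
            f"no sliding window fits inside the baseline {baseline_window}; "
            f"epochs start at {t0} s")
    p_base = mean_power[base_mask].mean(axis=0)
    values = 100.0 * (mean_power - p_base) / p_base
    return TFMap(times=centres, freqs=freqs[fmask], values=values,
                 baseline_window=baseline_window, channel=channel,
                 n=epochs.n_trials)


def erd_ers_curve(epochs: EpochSet,
                  channel: str,
                  band: tuple[float, float] = (8.0, 30.0),
                  baseline_window: tuple[float, float] = DEFAULT_BASELINE,
                  smooth_s: float = 0.25) -> ERDCurve:
    """Broadband ERD/ERS time course at one channel.

    Band-pass the epochs, square the samples, average across trials,
    smooth with a ``smooth_s`` moving average, and express as percent
    change relative to the mean over ``baseline_window``. Negative values
    are ERD (power suppression), positive ERS.
    """
    single = epochs.select_channels([channel])
    filtered = bandpass_filter(single, band[0], band[1])
    power = (filtered.data[:, 0, :] ** 2).mean(axis=0)

    n_smooth = max(1, int(round(smooth_s * epochs.sampling_rate_hz)))
    kernel = np.ones(n_smooth) / n_smooth
    smoothed = np.convolve(power, kernel, mode="same")

    times = epochs.times
    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not base_mask.any():
        raise ValueError(
            f"epochs (window {epochs.window}) do not cover the baseline "
            f"{baseline_window}")
    p_base = smoothed[base_mask].mean()
    values = 100.0 * (smoothed - p_base) / p_base
    return ERDCurve(times=times, values=values, band=band,
                    baseline_window=baseline_window, channel=channel,
                    n=epochs.n_trials)


def grand_average(items: Sequence[TFMap] | Sequence[ERDCurve],
                  side: str = "") -> TFMap | ERDCurve:
    """Element-wise mean of per-patient maps or curves on a common grid.

    Callers resolve each patient's channel (C3 or C4) through the lesion
    side first — see :func:`hemisphere_channel`; ``side`` only labels the
    result. Raises on mismatched time/frequency axes.
    """
    if not items:
        raise ValueError("nothing to average")
    first = items[0]
    for it in items[1:]:
        if type(it) is not type(first):
            raise TypeError("cannot mix TFMap and ERDCurve in one average")
        if it.times.shape != first.times.shape or not np.allclose(
                it.times, first.times):
            raise ValueError("time axes differ across items")
        if isinstance(first, TFMap) and (
                it.freqs.shape != first.freqs.shape
                or not np.allclose(it.freqs, first.freqs)):
            raise ValueError("frequency axes differ across items")
    values = np.mean([it.values for it in items], axis=0)
    label = side or first.channel
    return replace(first, values=values, channel=label, n=len(items))
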