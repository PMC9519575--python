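"""Synthetic motor-imagery EEG sessions and cohorts.

Emulates a screening-session protocol: 4 runs of 20 motor-imagery (MI) and
20 idle trials in random order, 27-channel 10-20 montage sampled at 250 Hz.
Each channel mixes a 1/f^alpha background, white sensor noise, and mu/beta
oscillators radiating from left (C3) and right (C4) sensorimotor sources
through a Gaussian spatial topography. During MI trials the oscillator
amplitude over each hemisphere drops by a configurable event-related
desynchronization (ERD) depth from 0.5 s after the cue until the end of the
task window, then rebounds (ERS) for 1 s; idle trials are unmodulated.

The generator is the ground truth for every downstream stage: the configured
ERD depths imply analytic band-power changes (amplitude scale ``1 - d`` means
power scale ``(1 - d)^2``), and the lesion side decides which hemisphere is
ipsilesional.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .montage import DEFAULT_CHANNELS, normalize_label, positions_array

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "ContinuousRecording",
    "PatientRecord",
    "generate_session",
    "generate_cohort",
    "ground_truth_effect",
    "EFFECT_PROFILES",
]

IDLE, MOTOR_IMAGERY = 0, 1
LABEL_NAMES = {IDLE: "idle", MOTOR_IMAGERY: "motor_imagery"}

#: seconds between the cue and ERD onset (known ERD latency)
ERD_ONSET_S = 0.5
#: duration of the post-task ERS rebound window, seconds
ERS_DURATION_S = 1.0


class ConfigurationError(ValueError):
    """A simulation parameter is out of its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic patient session.

    Amplitudes are in microvolts at the source-peak channel; ERD depths are
    fractional amplitude reductions in [0, 1] (0 = no modulation, 1 = full
    suppression); ``ers_rebound`` is the fractional amplitude overshoot after
    the task window.
    """

    seed: int = 0
    n_runs: int = 4
    trials_per_class_per_run: int = 20
    sampling_rate_hz: float = 250.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    baseline_s: float = 1.5
    task_s: float = 4.0
    trial_total_s: float = 12.0
    mu_hz: float = 10.0
    beta_hz: float = 22.0
    erd_depth_left: float = 0.5
    erd_depth_right: float = 0.5
    ers_rebound: float = 0.2
    background_exponent: float = 1.0
    sensor_noise_sd: float = 1.0
    topography_width: float = 0.35
    mu_amp_uv: float = 6.0
    beta_amp_uv: float = 3.0
    background_rms_uv: float = 8.0
    amplitude_mod: float = 0.2

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if self.trials_per_class_per_run < 1:
            raise ConfigurationError("trials_per_class_per_run must be >= 1")
        for name in ("baseline_s", "task_s", "trial_total_s", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("erd_depth_left", "erd_depth_right"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {d}")
        for name in ("ers_rebound", "sensor_noise_sd", "mu_amp_uv", "beta_amp_uv",
                     "background_rms_uv", "amplitude_mod"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.topography_width <= 0:
            raise ConfigurationError("topography_width must be > 0")
        if self.sampling_rate_hz <= 2 * max(self.mu_hz, self.beta_hz):
            raise ConfigurationError(
                "sampling_rate_hz must exceed twice the highest oscillator "
                f"frequency ({max(self.mu_hz, self.beta_hz)} Hz)")
        if self.trial_total_s < self.baseline_s + self.task_s + ERS_DURATION_S + 0.5:
            raise ConfigurationError(
                "trial_total_s too short for baseline + task + rebound")
        required = {"FC3", "FCZ", "FC4", "T7", "C3", "CZ", "C4", "T8",
                    "CP3", "CPZ", "CP4", "P3", "PZ", "P4"}
        have = {normalize_label(c) for c in self.channel_names}
        missing = sorted(required - have)
        if missing:
            raise ConfigurationError(
                f"channel_names is missing required sensorimotor channels: {missing}")

    @property
    def trials_per_session(self) -> int:
        return self.n_runs * self.trials_per_class_per_run * 2


@dataclass
class ContinuousRecording:
    """A continuous multi-channel EEG session with cue events.

    ``data`` is channels x samples in microvolts; ``events`` holds
    ``(onset_sample, label)`` pairs sorted by onset, label 1 = motor imagery,
    0 = idle. The onset marks the visual cue; the task window follows it and
    the preparation baseline precedes it.
    """

    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    data: np.ndarray
    events: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data must be (n_channels={len(self.channel_names)}, n_samples), "
                f"got {self.data.shape}")
        onsets = [int(on) for on, _ in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class PatientRecord:
    """A synthetic patient: lesion side, clinical metadata, and session."""

    patient_id: str
    lesion_side: Literal["left", "right"]
    fugl_meyer: int
    months_since_stroke: float
    sim_config: SimConfig | None = None
    recording: ContinuousRecording | None = None

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"lesion_side must be 'left' or 'right', got "
                             f"{self.lesion_side!r}")
        if not 0 <= int(self.fugl_meyer) <= 66:
            raise ValueError(f"fugl_meyer must be in [0, 66], got {self.fugl_meyer}")
        if self.months_since_stroke < 0:
            raise ValueError("months_since_stroke must be >= 0")

    def materialize(self) -> ContinuousRecording:
        """Generate (and cache) the session for this patient's config."""
        if self.recording is None:
            if self.sim_config is None:
                raise ValueError(f"patient {self.patient_id} has no sim_config")
            self.recording = generate_session(self.sim_config)
        return self.recording


def _pink_noise(rng: np.random.Generator, n: int, exponent: float,
                rms: float) -> np.ndarray:
    """1/f^alpha noise of length n with expected RMS ``rms``.

    The scale factor is computed analytically from the spectral shape, not
    from the realized sample variance: normalizing each run to its sample
    RMS would constrain the total power of the run and induce a spurious
    negative correlation between trial powers, which biases null
    cross-validation below chance.
    """
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    # E[var] of irfft(rfft(white)*shape): Parseval with hermitian weights
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    expected_var = float(np.sum(weights * shape ** 2)) / n
    x = np.fft.irfft(spec * shape, n=n)
    return x * (rms / np.sqrt(expected_var))


def _am_envelope(rng: np.random.Generator, n: int, fs: float,
                 mod_depth: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Slow multiplicative amplitude envelope, mean 1, sd ``mod_depth``.

    Real sensorimotor rhythms wax and wane over seconds; without this
    modulation every trial would carry an identical, deterministic
    oscillator power and the only across-trial variability would come from
    the broadband noise.
    """
    if mod_depth == 0:
        return np.ones(n)
    from scipy import signal as sps
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = z.std()
    if sd > 0:
        z = z / sd
    return np.clip(1.0 + mod_depth * z, 0.05, None)


def _source_gains(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Gaussian gains of the left (C3) and right (C4) sources."""
    pos = positions_array(config.channel_names)
    out = []
    for centre in ("C3", "C4"):
        c = positions_array([centre])[0]
        d2 = np.sum((pos - c) ** 2, axis=1)
        out.append(np.exp(-d2 / (2.0 * config.topography_width ** 2)))
    return out[0], out[1]


def _run_layout(config: SimConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Cue onsets (samples), labels, and total sample count for one run.

    Cue-to-cue intervals are jittered uniformly within +/- 1 s of the nominal
    trial duration; a lead-in of 2.5 s precedes the first cue (room for a
    -2 s visualization window) and the last trial keeps its full task +
    rebound tail.
    """
    fs = config.sampling_rate_hz
    n_per_class = config.trials_per_class_per_run
    labels = np.array([MOTOR_IMAGERY] * n_per_class + [IDLE] * n_per_class)
    rng.shuffle(labels)

    lead_in = max(2.5, config.baseline_s + 1.0)
    min_gap = config.task_s + ERS_DURATION_S + config.baseline_s + 0.5
    gaps = rng.uniform(max(min_gap, config.trial_total_s - 1.0),
                       config.trial_total_s + 1.0, size=labels.size - 1)
    cue_times = lead_in + np.concatenate([[0.0], np.cumsum(gaps)])
    onsets = np.round(cue_times * fs).astype(int)
    tail = config.task_s + ERS_DURATION_S + 1.0
    n_samples = int(np.ceil((cue_times[-1] + tail) * fs))
    return onsets, labels, n_samples


def _hemisphere_envelope(config: SimConfig, onsets: np.ndarray,
                         labels: np.ndarray, n_samples: int,
                         depth: float) -> np.ndarray:
    """Amplitude gain over time for one hemisphere's oscillatory source."""
    fs = config.sampling_rate_hz
    env = np.ones(n_samples)
    erd_on = int(round(ERD_ONSET_S * fs))
    task_end = int(round(config.task_s * fs))
    ers_end = task_end + int(round(ERS_DURATION_S * fs))
    for onset, label in zip(onsets, labels):
        if label != MOTOR_IMAGERY:
            continue
        env[onset + erd_on:onset + task_end] = 1.0 - depth
        env[onset + task_end:onset + ers_end] = 1.0 + config.ers_rebound
    return env


def generate_session(config: SimConfig) -> ContinuousRecording:
    """Simulate one continuous screening session.

    Runs are generated from independent random streams (split from
    ``config.seed``) and concatenated; events are reported at cue onsets.
    Identical config (including seed) yields bit-identical output.
    """
    fs = config.sampling_rate_hz
    gain_left, gain_right = _source_gains(config)
    run_seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)

    run_blocks: list[np.ndarray] = []
    events: list[tuple[int, int]] = []
    offset = 0
    for run_ss in run_seeds:
        rng = np.random.Generator(np.random.PCG64(run_ss))
        onsets, labels, n_samples = _run_layout(config, rng)
        t = np.arange(n_samples) / fs

        env_l = _hemisphere_envelope(config, onsets, labels, n_samples,
                                     config.erd_depth_left)
        env_r = _hemisphere_envelope(config, onsets, labels, n_samples,
                                     config.erd_depth_right)

        # one random phase and one slow amplitude envelope per (side, band);
        # narrow tones keep the spectral content within +-1 Hz of mu/beta
        phases = rng.uniform(0, 2 * np.pi, size=4)
        ams = [_am_envelope(rng, n_samples, fs, config.amplitude_mod)
               for _ in range(4)]
        osc_l = (config.mu_amp_uv * ams[0]
                 * np.sin(2 * np.pi * config.mu_hz * t + phases[0])
                 + config.beta_amp_uv * ams[1]
                 * np.sin(2 * np.pi * config.beta_hz * t + phases[1])) * env_l
        osc_r = (config.mu_amp_uv * ams[2]
                 * np.sin(2 * np.pi * config.mu_hz * t + phases[2])
                 + config.beta_amp_uv * ams[3]
                 * np.sin(2 * np.pi * config.beta_hz * t + phases[3])) * env_r

        n_ch = len(config.channel_names)
        block = np.outer(gain_left, osc_l) + np.outer(gain_right, osc_r)
        for ch in range(n_ch):
            block[ch] += _pink_noise(rng, n_samples, config.background_exponent,
                                     config.background_rms_uv)
        if config.sensor_noise_sd > 0:
            block += rng.normal(0.0, config.sensor_noise_sd, size=block.shape)

        events.extend((offset + int(on), int(lab))
                      for on, lab in zip(onsets, labels))
        run_blocks.append(block)
        offset += n_samples

    return ContinuousRecording(
        channel_names=tuple(config.channel_names),
        sampling_rate_hz=fs,
        data=np.concatenate(run_blocks, axis=1),
        events=events,
    )


# ---------------------------------------------------------------------------
# cohorts

EFFECT_PROFILES = ("ipsi_dominant", "contra_dominant", "balanced", "null")


def _draw_depths(profile: str, rng: np.random.Generator) -> tuple[float, float]:
    """(ipsilesional, contralesional) ERD depths for one patient."""
    if profile == "null":
        return 0.0, 0.0
    if profile == "balanced":
        base = rng.uniform(0.35, 0.6)
        jitter = rng.uniform(-0.05, 0.05, size=2)
        return float(np.clip(base + jitter[0], 0, 1)), \
            float(np.clip(base + jitter[1], 0, 1))
    strong = rng.uniform(0.45, 0.65)
    weak = rng.uniform(0.05, 0.2)
    if profile == "ipsi_dominant":
        return float(strong), float(weak)
    return float(weak), float(strong)  # contra_dominant


def _draw_fugl_meyer(profile: str, rng: np.random.Generator) -> int:
    # contra-dominant modulation is associated with greater impairment
    if profile == "contra_dominant":
        mean, sd, lo, hi = 17.0, 9.0, 0, 50
    elif profile == "ipsi_dominant":
        mean, sd, lo, hi = 33.0, 12.0, 5, 66
    else:
        mean, sd, lo, hi = 28.64, 12.92, 0, 66
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def _draw_months(rng: np.random.Generator) -> float:
    # ~1/8 subacute (3.3 +/- 1.5 months), rest chronic (23.7 +/- 17.7)
    if rng.random() < 17 / 136:
        return float(max(0.5, rng.normal(3.32, 1.5)))
    return float(max(1.0, rng.normal(23.68, 17.72)))


def generate_cohort(n_patients: int,
                    effect_profile: str,
                    seed: int,
                    base_config: SimConfig | None = None,
                    with_recordings: bool = False) -> list[PatientRecord]:
    """Draw a synthetic cohort with a controlled ipsi/contra effect balance.

    ``effect_profile`` sets which hemisphere carries the stronger ERD:
    ``ipsi_dominant``, ``contra_dominant``, ``balanced`` or ``null`` (no
    effect anywhere, ERS disabled). Lesion sides are balanced across the
    cohort. Patient random streams are split from ``seed``, so patient k is
    identical regardless of ``n_patients >= k``. Recordings are generated
    lazily via :meth:`PatientRecord.materialize` unless ``with_recordings``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if effect_profile not in EFFECT_PROFILES:
        raise ValueError(
            f"unknown effect_profile {effect_profile!r}; "
            f"valid values: {', '.join(EFFECT_PROFILES)}")
    base = base_config if base_config is not None else SimConfig()

    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n_patients)
    records = []
    for i, ss in enumerate(patient_seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        lesion_side = ("left", "right")[i % 2]
        depth_ipsi, depth_contra = _draw_depths(effect_profile, rng)
        if lesion_side == "left":
            left, right = depth_ipsi, depth_contra
        else:
            left, right = depth_contra, depth_ipsi
        cfg = replace(
            base,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            erd_depth_left=left,
            erd_depth_right=right,
            ers_rebound=0.0 if effect_profile == "null" else base.ers_rebound,
        )
        rec = PatientRecord(
            patient_id=f"S{i + 1:03d}",
            lesion_side=lesion_side,
            fugl_meyer=_draw_fugl_meyer(effect_profile, rng),
            months_since_stroke=_draw_months(rng),
            sim_config=cfg,
        )
        if with_recordings:
            rec.materialize()
        records.append(rec)
    return records


def ground_truth_effect(record: PatientRecord) -> tuple[float, float]:
    """(ipsilesional, contralesional) ERD depths actually simulated.

    Resolved through the lesion side: a left-hemisphere lesion makes the
    left (C3) source ipsilesional.
    """
    if record.sim_config is None:
        raise ValueError(
            f"patient {record.patient_id} was not generated by this module "
            "(no sim_config attached)")
    cfg = record.sim_config
    if record.lesion_side == "left":
        return cfg.erd_depth_left, cfg.erd_depth_right
    return cfg.erd_depth_right, cfg.erd_depth_left
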