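"""Reading and writing the pipeline's on-disk formats.

CSV carries event tables, cohort metadata, feature matrices and tidy
cross-validation results; HDF5 carries recordings and epochs; YAML carries
simulation configs. EDF+ recordings are read through :mod:`mne` (an
optional dependency); EDF export additionally needs mne's ``edfio``
backend and raises a clear error when it is absent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import yaml

from .evaluation import CVReport, MethodStrata, StatResult
from .features import FeatureMatrix
from .preprocess import EpochSet
from .simulate import LABEL_NAMES, ContinuousRecording, PatientRecord, SimConfig

__all__ = [
    "write_events_csv", "read_events_csv",
    "write_cohort_csv", "read_cohort_csv",
    "save_recording_hdf5", "load_recording_hdf5",
    "save_epochs_hdf5", "load_epochs_hdf5",
    "feature_matrix_to_dataframe", "write_feature_matrix_csv",
    "reports_to_dataframe", "write_reports_csv",
    "strata_to_dict", "write_strata_json",
    "sim_config_to_yaml", "sim_config_from_yaml",
    "read_recording_edf", "write_recording_edf",
]

_LABEL_CODES = {name: code for code, name in LABEL_NAMES.items()}


def write_events_csv(recording: ContinuousRecording, path) -> None:
    """Sidecar event table: onset_sample, label (text)."""
    df = pd.DataFrame(
        [(onset, LABEL_NAMES[label]) for onset, label in recording.events],
        columns=["onset_sample", "label"])
    df.to_csv(path, index=False)


def read_events_csv(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(int(row.onset_sample), _LABEL_CODES[str(row.label)])
            for row in df.itertuples()]


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "lesion_side": rec.lesion_side,
            "fugl_meyer": rec.fugl_meyer,
            "months_since_stroke": rec.months_since_stroke,
            "seed": rec.sim_config.seed if rec.sim_config else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_recording_hdf5(recording: ContinuousRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("events",
                         data=np.array([(o, l) for o, l in recording.events],
                                       dtype=np.int64).reshape(-1, 2))
        f.create_dataset("channel_names",
                         data=np.array(recording.channel_names, dtype="S"))
        f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz


def load_recording_hdf5(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        return ContinuousRecording(
            channel_names=tuple(n.decode() for n in f["channel_names"][()]),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            data=f["data"][()],
            events=[(int(o), int(l)) for o, l in f["events"][()]],
        )


def save_epochs_hdf5(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate_hz
        f.attrs["window"] = epochs.window
        f.attrs["role"] = epochs.role
        if epochs.band is not None:
            f.attrs["band"] = epochs.band


def load_epochs_hdf5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        band = tuple(f.attrs["band"]) if "band" in f.attrs else None
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            channel_names=tuple(n.decode() for n in f["channel_names"][()]),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            window=tuple(f.attrs["window"]),
            role=str(f.attrs["role"]),
            band=band,
        )


def feature_matrix_to_dataframe(features: FeatureMatrix) -> pd.DataFrame:
    cols = []
    for d in features.descriptors:
        band = f"{d.band[0]:g}-{d.band[1]:g}Hz" if d.band else "broadband"
        cols.append(f"{d.method}:{band}:{d.source}")
    df = pd.DataFrame(features.values, columns=cols)
    df.insert(0, "label", features.labels)
    return df


def write_feature_matrix_csv(features: FeatureMatrix, path) -> None:
    feature_matrix_to_dataframe(features).to_csv(path, index=False)


def reports_to_dataframe(reports: Iterable[CVReport]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of cross-validation outcomes."""
    return pd.DataFrame([{
        "patient_id": r.patient_id,
        "channel_set": r.channel_set,
        "method": r.method,
        "mean_accuracy": r.mean_accuracy,
        "sd": r.sd,
    } for r in reports])


def write_reports_csv(reports: Iterable[CVReport], path) -> None:
    reports_to_dataframe(reports).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, StatResult):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def strata_to_dict(strata: dict[str, MethodStrata]) -> dict:
    return {method: _jsonable(summary) for method, summary in strata.items()}


def write_strata_json(strata: dict[str, MethodStrata], path) -> None:
    Path(path).write_text(json.dumps(strata_to_dict(strata), indent=2))


def sim_config_to_yaml(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["channel_names"] = list(d["channel_names"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def sim_config_from_yaml(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "channel_names" in d:
        d["channel_names"] = tuple(d["channel_names"])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# EDF+ (optional mne backend)


def read_recording_edf(path) -> ContinuousRecording:
    """Read a continuous EDF+ recording, mapping annotations to cue events.

    Annotation descriptions matching ``motor_imagery``/``idle`` (or the MI
    trigger shorthand ``769``/``770``-style labels do NOT apply here — the
    writer uses the text labels) become events.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF reading requires the optional 'mne' "
                          "dependency (pip install strokebci[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        key = desc.strip().lower()
        if key in _LABEL_CODES:
            events.append((int(round(onset * fs)), _LABEL_CODES[key]))
    data = raw.get_data() * 1e6  # mne uses volts internally
    return ContinuousRecording(channel_names=tuple(raw.ch_names),
                               sampling_rate_hz=fs, data=data,
                               events=sorted(events))


def write_recording_edf(recording: ContinuousRecording, path) -> None:
    """Export to EDF+ with event annotations (needs mne + edfio)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF export requires the optional 'mne' "
                          "dependency (pip install strokebci[edf])") from exc
    info = mne.create_info(list(recording.channel_names),
                           recording.sampling_rate_hz, ch_types="eeg")
    raw = mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
    fs = recording.sampling_rate_hz
    onsets = [onset / fs for onset, _ in recording.events]
    descs = [LABEL_NAMES[label] for _, label in recording.events]
    raw.set_annotations(mne.Annotations(onset=onsets,
                                        duration=[0.0] * len(onsets),
                                        description=descs))
    try:
        mne.export.export_raw(str(path), raw, fmt="edf", verbose="error")
    except (ImportError, RuntimeError) as exc:
        raise ImportError(
            "mne's EDF exporter needs the 'edfio' package; install it or "
            "persist via save_recording_hdf5 instead") from exc
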