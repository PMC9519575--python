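"""Feature extraction: common spatial patterns, filter-bank CSP, band power.

CSP learns spatial filters w maximizing the Rayleigh quotient
wᵀC₁w / wᵀ(C₁+C₂)w of the class-mean trace-normalized covariances, solved
as the generalized eigenproblem C₁w = λ(C₁+C₂)w. Trials are summarized by
the normalized log variance of the projections through the first and last
``n_pairs`` filters (4 features by default). FBCSP repeats this per
filter-bank band and concatenates (9 × 4 = 36 features). Band-power (BP)
features express the task-window mean power of each channel relative to the
pre-cue baseline as a signed-log percent change — the per-trial ERD/ERS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .preprocess import EpochSet

__all__ = [
    "SpatialFilters", "FeatureDescriptor", "FeatureMatrix",
    "fit_csp", "csp_features", "fbcsp_features", "bp_features",
]

#: ridge added to the composite covariance for numerical rank safety
_COV_RIDGE = 1e-8


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature column."""

    method: str                     # "CSP", "FBCSP" or "BP"
    band: tuple[float, float] | None
    source: int | str               # spatial-filter index or channel name


@dataclass
class SpatialFilters:
    """A fitted CSP projection.

    Rows of ``weights`` are spatial filters sorted by descending generalized
    eigenvalue λ ∈ [0, 1] (λ near 1: variance concentrated in the motor-
    imagery class; near 0: in the idle class). ``selected_rows`` are the
    retained filters — the first and last ``n_pairs`` rows.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray
    selected_rows: tuple[int, ...]
    band: tuple[float, float] | None = None
    channel_names: tuple[str, ...] = ()

    @property
    def selected_weights(self) -> np.ndarray:
        return self.weights[list(self.selected_rows)]


@dataclass
class FeatureMatrix:
    """Trials × features values with per-feature provenance."""

    values: np.ndarray
    labels: np.ndarray
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials, features)")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must equal feature count")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(values=self.values[:, idx], labels=self.labels,
                             descriptors=tuple(self.descriptors[i] for i in idx))

    def select_trials(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(values=self.values[idx], labels=self.labels[idx],
                             descriptors=self.descriptors)


def _class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Trace-normalized per-trial covariances averaged within class."""
    X = epochs.data
    covs = np.einsum("tcs,tds->tcd", X, X)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("a trial has zero power; cannot normalize covariance")
    covs = covs / traces[:, None, None]
    mi = epochs.labels == 1
    idle = epochs.labels == 0
    if mi.sum() < 2 or idle.sum() < 2:
        raise ValueError(
            "CSP requires at least 2 trials of each class "
            f"(got {int(mi.sum())} motor imagery, {int(idle.sum())} idle)")
    return covs[mi].mean(axis=0), covs[idle].mean(axis=0)


def fit_csp(epochs: EpochSet, n_pairs: int = 2) -> SpatialFilters:
    """Fit CSP filters discriminating motor imagery (label 1) vs idle (0).

    Solves C₁w = λ(C₁+C₂)w; rows of the returned matrix are sorted by
    descending λ and normalized so wᵀ(C₁+C₂)w = 1. Eigenvector signs are
    fixed so each filter's largest-magnitude weight is positive. The
    composite covariance receives a tiny ridge; if it is still numerically
    singular a ``LinAlgError`` suggesting stronger regularization is raised.
    """
    n_ch = epochs.n_channels
    if n_ch < 2 * n_pairs:
        raise ValueError(f"need at least {2 * n_pairs} channels for "
                         f"n_pairs={n_pairs}, got {n_ch}")
    c1, c2 = _class_covariances(epochs)
    composite = c1 + c2 + _COV_RIDGE * np.eye(n_ch)
    try:
        eigvals, eigvecs = linalg.eigh(c1, composite)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "composite covariance is singular despite ridge; consider "
            "stronger regularization or fewer channels") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, 1.0)
    W = eigvecs[:, order].T
    # reproducible sign: largest-|w| entry positive per filter
    flips = np.sign(W[np.arange(n_ch), np.argmax(np.abs(W), axis=1)])
    W = W * flips[:, None]
    selected = tuple(range(n_pairs)) + tuple(range(n_ch - n_pairs, n_ch))
    return SpatialFilters(weights=W, eigenvalues=eigvals,
                          selected_rows=selected, band=epochs.band,
                          channel_names=epochs.channel_names)


def csp_features(epochs: EpochSet, filters: SpatialFilters,
                 method: str = "CSP") -> FeatureMatrix:
    """Normalized log variance of each trial through the selected filters.

    Feature k of a trial is log(v_k / Σv) over the selected projections'
    variances, so features are invariant to a global amplitude rescaling of
    the trial and Σ exp(feature) = 1.
    """
    if filters.channel_names and tuple(epochs.channel_names) != tuple(
            filters.channel_names):
        raise ValueError(
            "channel mismatch between epochs and filters: "
            f"{list(epochs.channel_names)} vs {list(filters.channel_names)}")
    W = filters.selected_weights
    projected = np.einsum("fc,tcs->tfs", W, epochs.data)
    var = projected.var(axis=-1)
    total = var.sum(axis=1, keepdims=True)
    feats = np.log(var / total)
    desc = tuple(FeatureDescriptor(method=method, band=filters.band, source=r)
                 for r in filters.selected_rows)
    return FeatureMatrix(values=feats, labels=epochs.labels, descriptors=desc)


def fbcsp_features(banded: Sequence[EpochSet], n_pairs: int = 2
                   ) -> tuple[FeatureMatrix, list[SpatialFilters]]:
    """Per-band CSP, features concatenated in band order (9 × 4 = 36)."""
    if not banded:
        raise ValueError("need at least one band")
    n_trials = banded[0].n_trials
    for b in banded:
        if b.n_trials != n_trials:
            raise ValueError("inconsistent trial counts across bands")
        if not np.array_equal(b.labels, banded[0].labels):
            raise ValueError("inconsistent labels across bands")
        if tuple(b.channel_names) != tuple(banded[0].channel_names):
            raise ValueError("inconsistent channel layout across bands")
    all_filters: list[SpatialFilters] = []
    blocks: list[FeatureMatrix] = []
    for band_epochs in banded:
        filt = fit_csp(band_epochs, n_pairs=n_pairs)
        all_filters.append(filt)
        blocks.append(csp_features(band_epochs, filt, method="FBCSP"))
    values = np.hstack([b.values for b in blocks])
    desc = tuple(d for b in blocks for d in b.descriptors)
    return FeatureMatrix(values=values, labels=banded[0].labels,
                         descriptors=desc), all_filters


def fbcsp_transform(banded: Sequence[EpochSet],
                    filters: Sequence[SpatialFilters]) -> FeatureMatrix:
    """Apply previously fitted per-band CSP filters (for held-out trials)."""
    if len(banded) != len(filters):
        raise ValueError("one SpatialFilters per band required")
    blocks = [csp_features(e, f, method="FBCSP") for e, f in zip(banded, filters)]
    values = np.hstack([b.values for b in blocks])
    desc = tuple(d for b in blocks for d in b.descriptors)
    return FeatureMatrix(values=values, labels=banded[0].labels,
                         descriptors=desc)


def bp_features(task: EpochSet, baseline: EpochSet,
                strict: bool = False) -> FeatureMatrix:
    """Baseline-referenced band-power change per channel and trial.

    For channel i, trial j: T = mean squared amplitude over the task window,
    B over the baseline window, r = 100·(T−B)/B. The default feature is the
    signed-log transform sign(r)·ln(1+|r|), defined for ERD (r < 0) as well
    as ERS; ``strict=True`` computes the literal ln(r) and raises on r ≤ 0.
    Inputs are expected already band-passed to the rhythm of interest
    (8–30 Hz in the standard pipeline).
    """
    if task.role != "task" or baseline.role != "baseline":
        raise ValueError(
            f"window-role mismatch: got task.role={task.role!r}, "
            f"baseline.role={baseline.role!r}")
    if task.n_trials != baseline.n_trials:
        raise ValueError("task and baseline must cover the same trials")
    if tuple(task.channel_names) != tuple(baseline.channel_names):
        raise ValueError("task and baseline must share the channel layout")
    T = np.mean(task.data ** 2, axis=-1)        # trials x channels
    B = np.mean(baseline.data ** 2, axis=-1)
    if np.any(B == 0):
        t, c = np.argwhere(B == 0)[0]
        raise ValueError(f"degenerate zero-power baseline at trial {t}, "
                         f"channel {task.channel_names[c]}")
    r = 100.0 * (T - B) / B
    if strict:
        if np.any(r <= 0):
            raise ValueError(
                "strict mode: ln(100·(T−B)/B) undefined for r <= 0 "
                "(ERD yields negative r); use the default signed-log")
        feats = np.log(r)
    else:
        feats = np.sign(r) * np.log1p(np.abs(r))
    desc = tuple(FeatureDescriptor(method="BP", band=task.band, source=ch)
                 for ch in task.channel_names)
    return FeatureMatrix(values=feats, labels=task.labels, descriptors=desc)
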