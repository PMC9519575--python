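"""Feature selection (MIBIF) and the naive Bayesian Parzen-window classifier.

Both stages share one density machinery: Gaussian-kernel Parzen estimates of
the class-conditional density of each feature, with per-(class, feature)
Silverman bandwidths. MIBIF scores each feature by the mutual information
I(feature; class) = H(class) − H(class | feature), the conditional entropy
estimated as the sample average of the posterior entropy, and keeps the
top-k features. NBPW classifies by the naive-Bayes product of the per-
feature Parzen likelihoods times the class priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .features import FeatureMatrix

__all__ = [
    "SelectionResult", "NBPWModel",
    "mutual_information", "mibif_select", "fit_nbpw", "predict_nbpw",
]

#: bandwidth floor as a fraction of the global feature scale
_BANDWIDTH_FLOOR_FRAC = 1e-6


def _silverman_bandwidth(values: np.ndarray, global_scale: float) -> float:
    """Silverman's rule h = σ̂·(4/(3n))^(1/5), floored for degenerate spreads."""
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    h = sd * (4.0 / (3.0 * n)) ** 0.2
    floor = _BANDWIDTH_FLOOR_FRAC * max(global_scale, 1e-12)
    return max(h, floor, 1e-12)


def _log_parzen(train: np.ndarray, h: float, query: np.ndarray) -> np.ndarray:
    """log of the Parzen (Gaussian-kernel) density at each query point."""
    z = (query[:, None] - train[None, :]) / h
    log_k = -0.5 * z ** 2 - 0.5 * np.log(2.0 * np.pi) - np.log(h)
    return logsumexp(log_k, axis=1) - np.log(train.size)


def _posteriors_1d(values: np.ndarray, labels: np.ndarray,
                   classes: np.ndarray, query: np.ndarray) -> np.ndarray:
    """P(class | feature value) for one feature, query x classes."""
    log_joint = np.empty((query.size, classes.size))
    scale = float(values.std(ddof=1)) if values.size > 1 else 0.0
    for j, c in enumerate(classes):
        vals_c = values[labels == c]
        h = _silverman_bandwidth(vals_c, scale)
        prior = vals_c.size / values.size
        log_joint[:, j] = np.log(prior) + _log_parzen(vals_c, h, query)
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_post)


def mutual_information(values: np.ndarray, labels: np.ndarray) -> float:
    """Estimate I(feature; class) in bits.

    H(class) comes from empirical class frequencies; H(class | feature) is
    the average, over the training samples, of the entropy of the Parzen
    posterior P(class | value). Clipped at zero (the estimator can go
    slightly negative for independent features).
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("mutual information undefined for constant labels")
    if np.any(counts < 2):
        raise ValueError("need at least 2 samples per class")
    priors = counts / counts.sum()
    h_class = -np.sum(priors * np.log2(priors))
    post = _posteriors_1d(values, labels, classes, values)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log2(post), 0.0)
    h_cond = float(-plogp.sum(axis=1).mean())
    return max(h_class - h_cond, 0.0)


@dataclass
class SelectionResult:
    """Outcome of MIBIF: per-feature MI scores and the retained indices."""

    mi_bits: np.ndarray
    ranking: np.ndarray
    selected: tuple[int, ...]


def mibif_select(features: FeatureMatrix, k: int = 4) -> SelectionResult:
    """Rank features by individual mutual information with the label.

    Keeps the top ``min(k, n_features)``; ties broken toward the lower
    original feature index (stable sort on negated scores).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if features.n_features == 0:
        raise ValueError("empty feature matrix")
    mi = np.array([mutual_information(features.values[:, d], features.labels)
                   for d in range(features.n_features)])
    ranking = np.argsort(-mi, kind="stable")
    selected = tuple(int(i) for i in ranking[:min(k, features.n_features)])
    return SelectionResult(mi_bits=mi, ranking=ranking, selected=selected)


@dataclass
class NBPWModel:
    """Fitted naive Bayesian Parzen-window classifier.

    Stores the training values per class, per-(class, feature) bandwidths,
    and class priors; prediction multiplies the per-feature kernel-density
    likelihoods under the naive (feature-independence) assumption.
    """

    classes: np.ndarray
    log_priors: np.ndarray
    train_values: dict[int, np.ndarray]     # class -> (n_c, n_features)
    bandwidths: np.ndarray                  # classes x features
    n_features: int


def fit_nbpw(features: FeatureMatrix) -> NBPWModel:
    """Fit NBPW: priors = class frequencies, Silverman bandwidths per cell."""
    X, y = features.values, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present in the training set")
    if np.any(counts < 2):
        c = classes[np.argmin(counts)]
        raise ValueError(f"class {c} has fewer than 2 training samples")
    scales = X.std(axis=0, ddof=1)
    bandwidths = np.empty((classes.size, X.shape[1]))
    train_values: dict[int, np.ndarray] = {}
    for i, c in enumerate(classes):
        Xc = X[y == c]
        train_values[int(c)] = Xc
        for d in range(X.shape[1]):
            bandwidths[i, d] = _silverman_bandwidth(Xc[:, d], float(scales[d]))
    log_priors = np.log(counts / counts.sum())
    return NBPWModel(classes=classes, log_priors=log_priors,
                     train_values=train_values, bandwidths=bandwidths,
                     n_features=X.shape[1])


def predict_nbpw(model: NBPWModel, features: FeatureMatrix
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and normalized posteriors for each trial.

    P(c|x) ∝ P(c)·Π_d Parzen(x_d | c, d), computed in log space. Exact
    posterior ties resolve to the lower class label (idle).
    """
    X = features.values
    if X.shape[1] != model.n_features:
        raise ValueError(f"model expects {model.n_features} features, "
                         f"got {X.shape[1]}")
    bad = ~np.isfinite(X)
    if np.any(bad):
        raise ValueError(f"non-finite feature at trial {int(np.argwhere(bad)[0, 0])}")
    log_post = np.tile(model.log_priors, (X.shape[0], 1))
    for i, c in enumerate(model.classes):
        Xc = model.train_values[int(c)]
        for d in range(model.n_features):
            log_post[:, i] += _log_parzen(Xc[:, d], float(model.bandwidths[i, d]),
                                          X[:, d])
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    # argmax with ties toward the lower class label: reverse-argmax trick
    # is unnecessary since np.argmax already takes the first maximum and
    # classes are sorted ascending
    pred = model.classes[np.argmax(post, axis=1)]
    return pred, post
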