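"""Cross-validated decoding accuracy and cohort-level statistics.

Each (patient, channel set, feature method) cell is scored by 10 runs of
stratified 10-fold cross-validation: per fold the whole pipeline — CSP /
FBCSP fitting, MIBIF selection where applicable, NBPW — is fitted on the
nine training portions only, so no information leaks from the held-out
fold. Cohort statistics mirror a screening-study analysis: an inverse-
binomial 99% chance threshold (≈60% for 160 trials), a <60% chance-level
stratum and a >80% high-performer stratum, paired Wilcoxon signed-rank
comparisons of ipsilesional vs contralesional accuracy within strata,
rank-sum comparison of Fugl-Meyer scores between strata, and Kendall tau-b
correlations of accuracy with the clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .decoding import fit_nbpw, mibif_select, predict_nbpw
from .features import bp_features, csp_features, fbcsp_features, fbcsp_transform, fit_csp
from .preprocess import EpochSet, FilterBankSpec, apply_filter_bank, bandpass_filter, epoch_session
from .simulate import ContinuousRecording, PatientRecord

__all__ = [
    "EpochsBundle", "CVReport", "StatResult", "StratumComparison",
    "MethodStrata", "prepare_bundle", "cross_validate", "chance_threshold",
    "wilcoxon_signed_rank", "kendall_tau", "mann_whitney",
    "stratify_and_compare", "evaluate_patient", "METHODS",
    "CHANNEL_SET_NAMES",
]

METHODS = ("CSP", "FBCSP", "BP")
CHANNEL_SET_NAMES = ("ipsilesional", "contralesional", "bilateral")

#: broadband mu+beta range used by the CSP and BP pipelines, Hz
BROADBAND = (8.0, 30.0)


@dataclass
class EpochsBundle:
    """Task and baseline epochs cut from one session, full montage, unfiltered."""

    task: EpochSet
    baseline: EpochSet


def prepare_bundle(recording: ContinuousRecording,
                   task_window: tuple[float, float] = (0.0, 4.0),
                   baseline_window: tuple[float, float] = (-1.5, 0.0)
                   ) -> EpochsBundle:
    """Epoch a continuous session into the default task/baseline windows."""
    return EpochsBundle(
        task=epoch_session(recording, task_window, role="task"),
        baseline=epoch_session(recording, baseline_window, role="baseline"),
    )


@dataclass
class CVReport:
    """10 × 10-fold cross-validation outcome for one pipeline cell."""

    patient_id: str
    channel_set: str
    method: str
    accuracies: np.ndarray          # runs x folds, percent correct
    mean_accuracy: float
    sd: float

    @classmethod
    def from_grid(cls, grid: np.ndarray, patient_id: str, channel_set: str,
                  method: str) -> "CVReport":
        grid = np.asarray(grid, dtype=float)
        return cls(patient_id=patient_id, channel_set=channel_set,
                   method=method, accuracies=grid,
                   mean_accuracy=float(grid.mean()),
                   sd=float(grid.std(ddof=1)))


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    p_value: float
    n: int
    direction: Literal["x>y", "x<y", "none"] = "none"
    degenerate: bool = False


def _stratified_fold_assignment(labels: np.ndarray, folds: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Fold index per trial, class counts balanced across folds."""
    assign = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _fold_accuracy_csp(task_f: EpochSet, train: np.ndarray, test: np.ndarray,
                       n_pairs: int) -> float:
    tr, te = task_f.select_trials(train), task_f.select_trials(test)
    filters = fit_csp(tr, n_pairs=n_pairs)
    model = fit_nbpw(csp_features(tr, filters))
    pred, _ = predict_nbpw(model, csp_features(te, filters))
    return 100.0 * float(np.mean(pred == te.labels))


def _fold_accuracy_fbcsp(banded: list[EpochSet], train: np.ndarray,
                         test: np.ndarray, n_pairs: int, k_select: int) -> float:
    tr_banded = [b.select_trials(train) for b in banded]
    te_banded = [b.select_trials(test) for b in banded]
    f_train, filters = fbcsp_features(tr_banded, n_pairs=n_pairs)
    f_test = fbcsp_transform(te_banded, filters)
    sel = mibif_select(f_train, k=k_select)
    model = fit_nbpw(f_train.select_features(sel.selected))
    pred, _ = predict_nbpw(model, f_test.select_features(sel.selected))
    return 100.0 * float(np.mean(pred == f_test.labels))


def _fold_accuracy_bp(feats, train: np.ndarray, test: np.ndarray,
                      k_select: int) -> float:
    f_train = feats.select_trials(train)
    f_test = feats.select_trials(test)
    sel = mibif_select(f_train, k=k_select)
    model = fit_nbpw(f_train.select_features(sel.selected))
    pred, _ = predict_nbpw(model, f_test.select_features(sel.selected))
    return 100.0 * float(np.mean(pred == f_test.labels))


def cross_validate(bundle: EpochsBundle,
                   method: str,
                   channels: Sequence[str],
                   runs: int = 10,
                   folds: int = 10,
                   seed: int = 0,
                   patient_id: str = "",
                   channel_set: str = "",
                   n_pairs: int = 2,
                   k_select: int = 4,
                   filter_bank: FilterBankSpec | None = None) -> CVReport:
    """Score one (channel set, feature method) cell by runs × folds CV.

    ``method`` is ``"CSP"`` (8–30 Hz band-pass, 4 CSP features, no
    selection), ``"FBCSP"`` (9-band filter bank, 36 features, MIBIF top 4)
    or ``"BP"`` (8–30 Hz per-channel band-power change, MIBIF top 4); all
    three feed the NBPW classifier. Each of the ``runs`` shufflings uses a
    seed split from ``seed``; folds are stratified by class. Filtering and
    per-trial BP features are precomputed once — they involve no
    cross-trial fitting — while CSP, MIBIF and NBPW are refitted per fold
    on training trials only.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    task = bundle.task.select_channels(channels)
    labels = task.labels
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2 or counts.min() < folds:
        raise ValueError(
            f"need at least {folds} trials per class for {folds}-fold CV, "
            f"got class counts {counts.tolist()}")

    if method == "CSP":
        task_f = bandpass_filter(task, *BROADBAND)
        fold_fn = lambda tr, te: _fold_accuracy_csp(task_f, tr, te, n_pairs)
    elif method == "FBCSP":
        banded = apply_filter_bank(task, filter_bank)
        fold_fn = lambda tr, te: _fold_accuracy_fbcsp(banded, tr, te,
                                                      n_pairs, k_select)
    else:  # BP
        baseline = bundle.baseline.select_channels(channels)
        task_f = bandpass_filter(task, *BROADBAND)
        base_f = bandpass_filter(baseline, *BROADBAND)
        feats = bp_features(task_f, base_f)
        fold_fn = lambda tr, te: _fold_accuracy_bp(feats, tr, te, k_select)

    grid = np.empty((runs, folds))
    run_seeds = np.random.SeedSequence(seed).spawn(runs)
    for r, ss in enumerate(run_seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        assign = _stratified_fold_assignment(labels, folds, rng)
        for f in range(folds):
            test = np.flatnonzero(assign == f)
            train = np.flatnonzero(assign != f)
            grid[r, f] = fold_fn(train, test)
    return CVReport.from_grid(grid, patient_id=patient_id,
                              channel_set=channel_set, method=method)


def chance_threshold(n_trials: int, confidence: float = 0.99) -> float:
    """Guessing-accuracy upper bound, percent, via the inverse binomial CDF.

    Smallest k with BinomialCDF(k; n, 0.5) >= confidence, returned as
    100·k/n. For 160 trials at 99% confidence this is 59.375% — the
    conventional "around 60%" chance level.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    k = int(stats.binom.ppf(confidence, n_trials, 0.5))
    while stats.binom.cdf(k, n_trials, 0.5) < confidence:  # ppf edge guard
        k += 1
    return 100.0 * k / n_trials


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped; ranks of tied |differences| are averaged.
    The null distribution is exact for n <= 25 untied differences, and a
    continuity-corrected normal approximation otherwise. All-zero
    differences yield a degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired samples of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult(method="wilcoxon_signed_rank", statistic=0.0,
                          p_value=1.0, n=0, direction="none", degenerate=True)
    if n < 5:
        raise ValueError(
            f"need at least 5 non-zero paired differences, got {n}")
    exact_ok = n <= 25 and np.unique(np.abs(d)).size == n
    res = stats.wilcoxon(d, zero_method="wilcox",
                         method="exact" if exact_ok else "approx",
                         correction=not exact_ok)
    direction = "x>y" if np.sum(d > 0) > np.sum(d < 0) else (
        "x<y" if np.sum(d < 0) > np.sum(d > 0) else "none")
    return StatResult(method="wilcoxon_signed_rank",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(n), direction=direction)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Kendall tau-b correlation with tie correction, two-sided p.

    Exact null enumeration for n <= 8 untied samples, normal approximation
    otherwise. Constant inputs leave the correlation undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant input vector")
    untied = np.unique(x).size == x.size and np.unique(y).size == y.size
    method = "exact" if (x.size <= 8 and untied) else "asymptotic"
    res = stats.kendalltau(x, y, method=method, variant="b")
    tau = float(res.statistic)
    direction = "x>y" if tau > 0 else ("x<y" if tau < 0 else "none")
    return StatResult(method="kendall_tau_b", statistic=tau,
                      p_value=float(res.pvalue), n=int(x.size),
                      direction=direction)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann–Whitney rank-sum comparison of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    direction = "x>y" if np.median(x) > np.median(y) else (
        "x<y" if np.median(x) < np.median(y) else "none")
    return StatResult(method="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(x.size + y.size),
                      direction=direction)


def evaluate_patient(record: PatientRecord,
                     method: str = "CSP",
                     channel_sets: Sequence[str] = CHANNEL_SET_NAMES,
                     runs: int = 10,
                     folds: int = 10,
                     seed: int = 0,
                     drop_recording: bool = True) -> list[CVReport]:
    """CV-score one patient on each requested channel set.

    Materializes the patient's recording if needed, resolves the channel
    sets through the lesion side, and runs :func:`cross_validate` per set.
    ``drop_recording`` frees the (large) raw session afterwards so whole
    cohorts can be processed sequentially in modest memory.
    """
    from .preprocess import resolve_channel_sets

    recording = record.materialize()
    bundle = prepare_bundle(recording)
    sets = resolve_channel_sets(record.lesion_side, recording.channel_names)
    reports = []
    for name in channel_sets:
        reports.append(cross_validate(
            bundle, method, sets.get(name), runs=runs, folds=folds,
            seed=seed, patient_id=record.patient_id, channel_set=name))
    if drop_recording:
        record.recording = None
    return reports


# ---------------------------------------------------------------------------
# strata


@dataclass
class StratumComparison:
    """Paired ipsi-vs-contra accuracy comparison within one stratum."""

    n: int
    ipsilesional_mean: float | None
    contralesional_mean: float | None
    test: StatResult | None
    note: str = ""


@dataclass
class MethodStrata:
    """Stratified summary for one feature-extraction method."""

    method: str
    below_low_fraction: dict[str, float]
    low_stratum: StratumComparison
    high_stratum: StratumComparison
    fugl_meyer_test: StatResult | None
    fugl_meyer_note: str
    correlations: dict[str, StatResult | None]
    correlation_notes: dict[str, str]
    notes: list[str] = field(default_factory=list)


def _stratum_comparison(ipsi: np.ndarray, contra: np.ndarray,
                        label: str) -> StratumComparison:
    if ipsi.size == 0:
        return StratumComparison(n=0, ipsilesional_mean=None,
                                 contralesional_mean=None, test=None,
                                 note=f"{label} stratum empty; comparison skipped")
    try:
        test = wilcoxon_signed_rank(ipsi, contra)
        note = ""
    except ValueError as exc:
        test, note = None, f"{label} stratum: {exc}"
    return StratumComparison(n=int(ipsi.size),
                             ipsilesional_mean=float(ipsi.mean()),
                             contralesional_mean=float(contra.mean()),
                             test=test, note=note)


def stratify_and_compare(reports: Iterable[CVReport],
                         metadata: Iterable[PatientRecord],
                         low: float = 60.0,
                         high: float = 80.0) -> dict[str, MethodStrata]:
    """Chance-level / high-performer strata and their statistics, per method.

    For every feature method present in ``reports``: (a) the fraction of
    patients whose mean accuracy falls strictly below ``low`` for each
    channel set; (b) within the strata ipsilesional < ``low`` and
    ipsilesional > ``high``, a paired Wilcoxon of ipsilesional vs
    contralesional accuracy; (c) between those strata, a Mann–Whitney
    comparison of Fugl-Meyer scores, plus cohort-wide Kendall tau-b
    correlations of each channel set's accuracy with Fugl-Meyer score and
    months since stroke. Patients between the thresholds belong to neither
    stratum. Empty or too-small strata are reported as explicit notes,
    never silently dropped.
    """
    meta = {rec.patient_id: rec for rec in metadata}
    cells: dict[tuple[str, str, str], float] = {}
    for rep in reports:
        cells[(rep.method, rep.patient_id, rep.channel_set)] = rep.mean_accuracy
    methods = sorted({m for m, _, _ in cells})

    out: dict[str, MethodStrata] = {}
    for method in methods:
        patients = sorted({p for m, p, _ in cells if m == method})
        for pid in patients:
            if pid not in meta:
                raise KeyError(f"no PatientRecord for patient {pid!r}")
            for cs in ("ipsilesional", "contralesional"):
                if (method, pid, cs) not in cells:
                    raise ValueError(
                        f"patient {pid} lacks a {cs} report for {method}")
        notes: list[str] = []

        below: dict[str, float] = {}
        for cs in CHANNEL_SET_NAMES:
            accs = [cells[(method, p, cs)] for p in patients
                    if (method, p, cs) in cells]
            if accs:
                below[cs] = float(np.mean(np.asarray(accs) < low))

        ipsi = np.array([cells[(method, p, "ipsilesional")] for p in patients])
        contra = np.array([cells[(method, p, "contralesional")] for p in patients])
        fma = np.array([meta[p].fugl_meyer for p in patients], dtype=float)
        months = np.array([meta[p].months_since_stroke for p in patients])

        low_mask = ipsi < low
        high_mask = ipsi > high
        low_cmp = _stratum_comparison(ipsi[low_mask], contra[low_mask],
                                      f"ipsilesional<{low:g}%")
        high_cmp = _stratum_comparison(ipsi[high_mask], contra[high_mask],
                                       f"ipsilesional>{high:g}%")

        if low_mask.any() and high_mask.any():
            fma_test: StatResult | None = mann_whitney(fma[low_mask],
                                                       fma[high_mask])
            fma_note = ""
        else:
            fma_test = None
            fma_note = ("a Fugl-Meyer stratum is empty; rank-sum comparison "
                        "skipped")

        correlations: dict[str, StatResult | None] = {}
        corr_notes: dict[str, str] = {}
        for cs in CHANNEL_SET_NAMES:
            accs = np.array([cells[(method, p, cs)] for p in patients
                             if (method, p, cs) in cells])
            if accs.size != len(patients):
                corr_notes[cs] = f"{cs} reports incomplete; correlations skipped"
                continue
            for name, covariate in (("fugl_meyer", fma),
                                    ("months_since_stroke", months)):
                key = f"{cs}_vs_{name}"
                try:
                    correlations[key] = kendall_tau(accs, covariate)
                except ValueError as exc:
                    correlations[key] = None
                    corr_notes[key] = str(exc)

        out[method] = MethodStrata(
            method=method, below_low_fraction=below, low_stratum=low_cmp,
            high_stratum=high_cmp, fugl_meyer_test=fma_test,
            fugl_meyer_note=fma_note, correlations=correlations,
            correlation_notes=corr_notes, notes=notes)
    return out
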