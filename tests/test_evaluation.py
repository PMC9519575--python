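"""Tests of cross-validation, chance threshold, statistics and strata."""

import itertools

import numpy as np
import pytest

from strokebci import (CVReport, PatientRecord, SimConfig, chance_threshold,
                       cross_validate, generate_session, kendall_tau,
                       mann_whitney, prepare_bundle,
                       stratify_and_compare, wilcoxon_signed_rank)
from strokebci.evaluation import (_fold_accuracy_csp,
                                  _stratified_fold_assignment)
from strokebci.preprocess import bandpass_filter

IPSI_LEFT = ("FC3", "FCz", "T7", "C3", "Cz", "CP3", "CPz", "P3", "Pz")


class TestCrossValidate:
    def test_grid_shape_and_summary(self, small_bundle):
        rep = cross_validate(small_bundle, "CSP", IPSI_LEFT, runs=2, folds=10,
                             seed=4, patient_id="p1", channel_set="ipsilesional")
        assert rep.accuracies.shape == (2, 10)
        assert rep.mean_accuracy == pytest.approx(rep.accuracies.mean())
        assert np.all((rep.accuracies >= 0) & (rep.accuracies <= 100))

    def test_folds_partition_trials_exactly(self):
        labels = np.array([0, 1] * 30)
        rng = np.random.default_rng(0)
        assign = _stratified_fold_assignment(labels, 10, rng)
        assert assign.shape == labels.shape
        for f in range(10):
            fold_labels = labels[assign == f]
            assert (fold_labels == 0).sum() == 3
            assert (fold_labels == 1).sum() == 3

    def test_label_shuffled_session_is_at_chance(self, small_bundle, rng):
        from dataclasses import replace
        shuffled = replace(small_bundle.task,
                           labels=rng.permutation(small_bundle.task.labels))
        from strokebci import EpochsBundle
        bundle = EpochsBundle(task=shuffled, baseline=small_bundle.baseline)
        rep = cross_validate(bundle, "CSP", IPSI_LEFT, runs=3, folds=10, seed=8)
        # 99% binomial band around 50% for ~120 held-out decisions per run
        assert 30.0 < rep.mean_accuracy < 70.0

    def test_separable_session_is_nearly_perfect(self):
        cfg = SimConfig(seed=13, n_runs=2, trials_per_class_per_run=10,
                        erd_depth_left=0.8, erd_depth_right=0.8,
                        background_rms_uv=2.0, sensor_noise_sd=0.2)
        bundle = prepare_bundle(generate_session(cfg))
        rep = cross_validate(bundle, "CSP", IPSI_LEFT, runs=2, seed=5)
        assert rep.mean_accuracy > 95.0

    def test_same_seed_reproduces_grid(self, small_bundle):
        a = cross_validate(small_bundle, "BP", IPSI_LEFT, runs=2, seed=9)
        b = cross_validate(small_bundle, "BP", IPSI_LEFT, runs=2, seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_flipping_test_labels_mirrors_accuracy(self, small_bundle):
        """Held-out labels are used for scoring only: no leakage into fits."""
        from dataclasses import replace
        task_f = bandpass_filter(small_bundle.task.select_channels(IPSI_LEFT),
                                 8.0, 30.0)
        train = np.arange(0, 30)
        test = np.arange(30, 40)
        acc = _fold_accuracy_csp(task_f, train, test, n_pairs=2)
        flipped = replace(task_f, labels=task_f.labels.copy())
        flipped.labels[test] = 1 - flipped.labels[test]
        acc_flipped = _fold_accuracy_csp(flipped, train, test, n_pairs=2)
        assert acc + acc_flipped == pytest.approx(100.0)

    def test_too_few_trials_rejected(self, small_bundle):
        few = small_bundle.task.select_trials(range(6))
        from strokebci import EpochsBundle
        bundle = EpochsBundle(task=few,
                              baseline=small_bundle.baseline.select_trials(
                                  range(6)))
        with pytest.raises(ValueError, match="10"):
            cross_validate(bundle, "CSP", IPSI_LEFT, folds=10)

    def test_unknown_method_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="FBCSP"):
            cross_validate(small_bundle, "lda", IPSI_LEFT)


class TestChanceThreshold:
    def test_160_trials_at_99pc_is_59_375(self):
        assert chance_threshold(160, 0.99) == pytest.approx(59.375)

    def test_single_trial_needs_certainty(self):
        assert chance_threshold(1) == 100.0

    def test_non_increasing_in_trial_count(self):
        values = [chance_threshold(n) for n in (40, 80, 160, 320)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            chance_threshold(160, 1.5)


class TestWilcoxon:
    def test_identical_samples_are_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0],
                                   [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.degenerate and res.p_value == 1.0

    def test_six_positive_differences_match_sign_enumeration(self):
        """Exact p for n=6 all-positive distinct differences is 2/64."""
        x = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        res = wilcoxon_signed_rank(x, y)
        # oracle: enumerate all 2^6 sign assignments of the ranks
        ranks = np.arange(1, 7)
        w_obs = ranks.sum()  # all positive
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=6)]
        w_max = ranks.sum()
        p_oracle = np.mean([min(w, w_max - w) <= min(w_obs, w_max - w_obs)
                            for w in stats_all])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.p_value == pytest.approx(p_oracle)
        assert res.direction == "x>y"

    def test_shift_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        y = np.array([2.0, 2.0, 3.0, 2.5, 7.0, 3.1, 4.9])
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(x + 100.0, y + 100.0)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.standard_normal(60) + 0.5
        y = rng.standard_normal(60)
        res = wilcoxon_signed_rank(x, y)
        assert 0.0 <= res.p_value <= 1.0 and res.n == 60

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestKendall:
    def test_perfect_concordance_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert kendall_tau(x, [2.0, 4.0, 6.0, 8.0, 10.0]).statistic == \
            pytest.approx(1.0)
        assert kendall_tau(x, [10.0, 8.0, 6.0, 4.0, 2.0]).statistic == \
            pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tau_b_matches_pair_counting_oracle(self, seed):
        """tau-b vs O(n^2) concordant/discordant counting with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.integers(0, 4, n).astype(float)   # ties likely
        y = rng.integers(0, 4, n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            x[0], y[0] = x[0] + 10, y[0] + 10
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
        res = kendall_tau(x, y)
        assert res.statistic == pytest.approx((conc - disc) / denom)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def _report(pid, cs, acc, method="CSP"):
    grid = np.full((10, 10), acc)
    return CVReport.from_grid(grid, patient_id=pid, channel_set=cs,
                              method=method)


def _patient(pid, fma=30, months=12.0, side="left"):
    return PatientRecord(patient_id=pid, lesion_side=side, fugl_meyer=fma,
                         months_since_stroke=months)


class TestStrata:
    def test_below_threshold_fractions(self):
        reports, meta = [], []
        for i in range(8):
            pid = f"p{i}"
            reports += [_report(pid, "ipsilesional", 50.0),
                        _report(pid, "contralesional", 70.0)]
            meta.append(_patient(pid, fma=20 + i, months=6.0 + i))
        strata = stratify_and_compare(reports, meta)["CSP"]
        assert strata.below_low_fraction["ipsilesional"] == 1.0
        assert strata.below_low_fraction["contralesional"] == 0.0

    def test_low_stratum_compares_ipsi_vs_contra(self):
        reports, meta = [], []
        for i in range(10):
            pid = f"p{i}"
            ipsi = 52.0 + i * 0.5          # all below 60
            reports += [_report(pid, "ipsilesional", ipsi),
                        _report(pid, "contralesional", ipsi + 10.0 + 0.1 * i)]
            meta.append(_patient(pid, fma=10 + i, months=3.0 + i))
        strata = stratify_and_compare(reports, meta)["CSP"]
        low = strata.low_stratum
        assert low.n == 10
        assert low.contralesional_mean > low.ipsilesional_mean
        assert low.test is not None and low.test.direction == "x<y"
        assert strata.high_stratum.n == 0
        assert "empty" in strata.high_stratum.note
        assert strata.fugl_meyer_test is None

    def test_two_strata_fugl_meyer_comparison(self):
        reports, meta = [], []
        for i in range(6):  # impaired, chance-level ipsilesional
            pid = f"low{i}"
            reports += [_report(pid, "ipsilesional", 50.0 + i),
                        _report(pid, "contralesional", 68.0 + i)]
            meta.append(_patient(pid, fma=10 + i))
        for i in range(6):  # high performers
            pid = f"high{i}"
            reports += [_report(pid, "ipsilesional", 88.0 + i),
                        _report(pid, "contralesional", 80.0 + i)]
            meta.append(_patient(pid, fma=40 + i))
        strata = stratify_and_compare(reports, meta)["CSP"]
        assert strata.fugl_meyer_test is not None
        assert strata.fugl_meyer_test.direction == "x<y"   # low stratum more impaired
        assert strata.fugl_meyer_test.p_value < 0.05

    def test_boundary_values_belong_to_no_stratum(self):
        reports, meta = [], []
        for i, acc in enumerate([60.0, 70.0, 80.0]):
            pid = f"p{i}"
            reports += [_report(pid, "ipsilesional", acc),
                        _report(pid, "contralesional", acc)]
            meta.append(_patient(pid, fma=20 + i, months=4.0 + i))
        strata = stratify_and_compare(reports, meta, low=60.0, high=80.0)["CSP"]
        assert strata.low_stratum.n == 0
        assert strata.high_stratum.n == 0

    def test_missing_contralesional_report_is_an_error(self):
        reports = [_report("p0", "ipsilesional", 70.0)]
        with pytest.raises(ValueError, match="contralesional"):
            stratify_and_compare(reports, [_patient("p0")])

    def test_mann_whitney_directionality(self):
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.direction == "x<y"
        assert res.p_value < 0.2
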