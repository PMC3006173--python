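"""Metrics, cross-validation protocol, corrected t-test, sweeps, subsets."""

import numpy as np
import pytest

import lfpdecode as ld
from lfpdecode.ecoc import DecoderConfig
from lfpdecode.errors import ValidationError
from lfpdecode.evaluation import (
    corrected_ttest,
    cross_validate_covs,
    delay_period_test,
)


class TestDecodingPower:
    @pytest.mark.parametrize(
        "pred,actual,expect",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([0, 0, 0], [1, 2, 3], 0.0),
            ([0, 1, 2, 3, 9, 9, 9, 9], [0, 1, 2, 4, 5, 6, 7, 8], 0.375),
        ],
    )
    def test_values(self, pred, actual, expect):
        assert ld.decoding_power(np.array(pred), np.array(actual)) == expect

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ld.decoding_power(np.array([]), np.array([]))


class TestCircularCorrelation:
    def test_identical_sequences_give_one(self, rng):
        a = rng.uniform(0, 2 * np.pi, 100)
        assert ld.circular_correlation(a, a) == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self, rng):
        a = rng.uniform(0, 2 * np.pi, 100)
        assert ld.circular_correlation(-a, a) == pytest.approx(-1.0)

    def test_independent_angles_near_zero(self):
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            a = r.uniform(0, 2 * np.pi, 1000)
            b = r.uniform(0, 2 * np.pi, 1000)
            assert abs(ld.circular_correlation(a, b)) < 0.1

    def test_rotation_invariance(self, rng):
        a = rng.uniform(0, 2 * np.pi, 60)
        b = rng.uniform(0, 2 * np.pi, 60)
        r0 = ld.circular_correlation(a, b)
        r1 = ld.circular_correlation(a + 1.234, b + 1.234)
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_constant_sequence_flagged_degenerate(self, rng):
        a = np.full(10, 0.7)
        b = rng.uniform(0, 2 * np.pi, 10)
        r = ld.circular_correlation(a, b)
        assert r == 0.0 and r.degenerate

    def test_matches_naive_double_loop(self, rng):
        a = rng.uniform(0, 2 * np.pi, 25)
        b = rng.uniform(0, 2 * np.pi, 25)
        num = den_a = den_b = 0.0
        for i in range(25):
            for j in range(i + 1, 25):
                num += np.sin(a[i] - a[j]) * np.sin(b[i] - b[j])
                den_a += np.sin(a[i] - a[j]) ** 2
                den_b += np.sin(b[i] - b[j]) ** 2
        expect = num / np.sqrt(den_a * den_b)
        assert ld.circular_correlation(a, b) == pytest.approx(expect, abs=1e-12)


def _planted_covs(rng, labels, C=8, sep=3.0):
    covs = []
    for k in labels:
        d = np.ones(C)
        d[k % C] = sep
        d[(k + 1) % C] = sep / 2
        a = rng.standard_normal((C, 160)) * np.sqrt(d)[:, None]
        covs.append(np.cov(a))
    return np.asarray(covs)


class TestCrossValidate:
    def test_confusion_consistent_with_dp(self, rng):
        labels = np.repeat(np.arange(8), 12)
        covs = _planted_covs(rng, labels)
        res = cross_validate_covs([covs], labels, [ld.SubBandSpec(1, 4)],
                                  (0.0, 1.0), folds=4, reps=2, seed=3)
        assert res.dp == pytest.approx(np.trace(res.confusion) / res.confusion.sum())
        # row sums = per-class test counts over folds x reps
        np.testing.assert_array_equal(res.confusion.sum(axis=1), 12 * 2)
        assert res.fold_dp.size == 8

    def test_same_seed_reproduces_scores(self, rng):
        labels = np.repeat(np.arange(8), 12)
        covs = _planted_covs(rng, labels)
        kw = dict(folds=4, reps=2, seed=9)
        a = cross_validate_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0, 1), **kw)
        b = cross_validate_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0, 1), **kw)
        np.testing.assert_array_equal(a.fold_dp, b.fold_dp)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_class_too_small_for_folds_rejected(self, rng):
        labels = np.repeat(np.arange(8), 3)
        covs = _planted_covs(rng, labels)
        with pytest.raises(ValidationError, match="fold"):
            cross_validate_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0, 1),
                                folds=10, reps=1, seed=0)


class TestCorrectedTTest:
    def test_equal_scores_give_t0_p1(self):
        s = np.array([0.5, 0.6, 0.7, 0.8])
        out = corrected_ttest(s, s, n_train=90, n_test=10)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_gives_inf_t(self):
        a = np.full(10, 0.8)
        out = corrected_ttest(a, 0.6, n_train=90, n_test=10)
        assert np.isinf(out["t"]) and out["p"] == 0.0

    def test_correction_widens_ci_by_known_factor(self, rng):
        # corrected CI / naive CI = sqrt(1 + J * n_test / n_train)
        scores = rng.normal(0.7, 0.05, 100)
        J, n_tr, n_te = 100, 90, 10
        out = corrected_ttest(scores, 0.0, n_train=n_tr, n_test=n_te)
        half = (out["ci95"][1] - out["ci95"][0]) / 2
        from scipy import stats
        naive = stats.t.ppf(0.975, J - 1) * scores.std(ddof=1) / np.sqrt(J)
        np.testing.assert_allclose(
            half / naive, np.sqrt(1 + J * n_te / n_tr), rtol=1e-10
        )

    def test_detects_real_difference(self, rng):
        a = rng.normal(0.8, 0.03, 100)
        b = rng.normal(0.4, 0.03, 100)
        out = corrected_ttest(a, b, n_train=90, n_test=10)
        assert out["p"] < 0.001 and out["t"] > 0


class TestRateOfChange:
    def _sweep(self, times, rho):
        return ld.WindowSweepResult(
            window_end_times=np.asarray(times, dtype=float),
            rho_series=np.asarray(rho, dtype=float),
            dp_series=np.zeros(len(rho)),
            rate_of_change=np.diff(rho) / (np.diff(times) / 100.0),
            ci_low=np.zeros(len(rho)),
            ci_high=np.zeros(len(rho)),
        )

    def test_direct_readout(self):
        sweep = self._sweep([0, 100, 200, 300], [0.0, 1.0, 1.4, 1.5])
        s = ld.rate_of_change_summary(sweep)
        assert s["peak_value"] == pytest.approx(1.0)
        assert s["peak_time"] == 100.0
        assert s["half_decay_time"] == 200.0

    def test_constant_series_undefined_marker(self):
        sweep = self._sweep([0, 100, 200], [0.5, 0.5, 0.5])
        assert ld.rate_of_change_summary(sweep)["half_decay_time"] is None

    def test_step_beats_ramp_peak_rate(self):
        t = np.arange(0, 1000, 100)
        step = np.where(t >= 500, 0.9, 0.0)
        ramp = 0.9 * t / t.max()
        s_step = ld.rate_of_change_summary(self._sweep(t, step))
        s_ramp = ld.rate_of_change_summary(self._sweep(t, ramp))
        assert s_step["peak_value"] > s_ramp["peak_value"]


class TestSweepAndSubsets:
    def test_sweep_window_outside_epoch_names_position(self, small_banded,
                                                       small_session):
        _, T, _ = small_session
        with pytest.raises(ValidationError, match="-9000"):
            ld.sliding_timecourse(small_banded, T.labels, 1000.0, -9000.0,
                                  100.0, -7000.0, reps=1)

    def test_subset_identity_at_full_channel_count(self, small_banded,
                                                   small_session):
        _, T, _ = small_session
        n_ch = small_banded[0].data.shape[1]
        cfg = DecoderConfig(csp_shrinkage=0.05)
        curves = ld.subset_curves(small_banded, T.labels,
                                  channel_counts=[n_ch], draws=1, seed=5,
                                  config=cfg, reps=1)
        row = curves["channels"].iloc[0]
        res = ld.cross_validate(small_banded, T.labels, (0.0, 1000.0),
                                cfg, folds=10, reps=1,
                                seed=int(row.cv_seed))
        assert row.rho_t == pytest.approx(res.rho_t, abs=1e-12)

    def test_count_exceeding_available_rejected(self, small_banded,
                                                small_session):
        _, T, _ = small_session
        with pytest.raises(ValidationError):
            ld.subset_curves(small_banded, T.labels, channel_counts=[999],
                             draws=1, seed=0)


class TestCrossSession:
    def test_channel_mismatch_rejected(self, rng):
        a = ld.TrialSet(data=rng.standard_normal((4, 4, 600)), fs=1000.0,
                        labels=np.arange(4) % 8)
        b = ld.TrialSet(data=rng.standard_normal((4, 4, 600)), fs=1000.0,
                        labels=np.arange(4) % 8,
                        channel_mask=np.array([True, True, True, False]))
        with pytest.raises(ValidationError, match="channel"):
            ld.cross_session_validate([a], [b], ld.informative_bands(),
                                      (0.0, 100.0))

    def test_stationary_transfer_and_drift_penalty(self):
        cfg = ld.SimConfig(seed=31, n_channels=16, n_trials_per_class=12,
                           drift=0.6)
        bands = ld.informative_bands()
        s0, _ = ld.simulate_session(cfg)
        s0b, _ = ld.simulate_session(ld.drift_session(
            ld.SimConfig(seed=31, n_channels=16, n_trials_per_class=12,
                         drift=0.0), 1))
        s1, _ = ld.simulate_session(ld.drift_session(cfg, 1))
        stationary = ld.cross_session_validate([s0], [s0b], bands, (0.0, 1000.0))
        drifted = ld.cross_session_validate([s0], [s1], bands, (0.0, 1000.0))
        assert stationary["dp"] > 0.5
        assert drifted["dp"] < stationary["dp"]

    def test_two_training_sessions_beat_one_on_drifting_data(self):
        bands = ld.informative_bands()
        one, two = [], []
        for seed in (41, 42, 43):
            cfg = ld.SimConfig(seed=seed, n_channels=12, n_trials_per_class=10,
                               drift=0.5)
            s = [ld.simulate_session(ld.drift_session(cfg, i))[0]
                 for i in range(3)]
            one.append(ld.cross_session_validate([s[1]], [s[2]], bands,
                                                 (0.0, 1000.0))["dp"])
            two.append(ld.cross_session_validate([s[0], s[1]], [s[2]], bands,
                                                 (0.0, 1000.0))["dp"])
        assert np.mean(two) >= np.mean(one)


class TestDelayPeriodTest:
    def test_interval_without_windows_rejected(self):
        sweep = ld.WindowSweepResult(
            window_end_times=np.array([0.0, 100.0]),
            rho_series=np.zeros(2), dp_series=np.zeros(2),
            rate_of_change=np.zeros(1), ci_low=np.zeros(2), ci_high=np.zeros(2),
            results=[],
        )
        with pytest.raises(ValidationError):
            delay_period_test(sweep, (5000.0, 6000.0))
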