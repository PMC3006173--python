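"""Contrast enumeration, code matrix, FLD, ECOC fusion and model store."""

import itertools

import numpy as np
import pytest

import lfpdecode as ld
from lfpdecode.ecoc import decode_margins, ecoc_fit_covs
from lfpdecode.errors import ConfigurationError, TrainingError, ValidationError


class TestEnumerateContrasts:
    def test_k8_counts(self):
        contrasts = ld.enumerate_contrasts(8)
        assert len(contrasts) == 40
        assert sum(c.kind == "pair" for c in contrasts) == 28
        assert sum(c.kind == "group" for c in contrasts) == 12

    def test_k8_group_sides_are_diametric(self):
        for c in ld.enumerate_contrasts(8):
            if c.kind == "group":
                assert c.negative_set == frozenset((k + 4) % 8
                                                   for k in c.positive_set)
                assert 2 <= len(c.positive_set) <= 4

    def test_k4_brute_force(self):
        # brute force: all pairs + deduplicated contiguous-vs-opposite groups
        contrasts = ld.enumerate_contrasts(4)
        pairs = {frozenset({frozenset({a}), frozenset({b})})
                 for a, b in itertools.combinations(range(4), 2)}
        groups = set()
        for start in range(4):
            pos = frozenset({start, (start + 1) % 4})
            neg = frozenset({(start + 2) % 4, (start + 3) % 4})
            groups.add(frozenset({pos, neg}))
        got = {frozenset({c.positive_set, c.negative_set}) for c in contrasts}
        assert got == pairs | groups
        assert len(contrasts) == 8

    def test_odd_k_rejected(self):
        with pytest.raises(ConfigurationError):
            ld.enumerate_contrasts(5)

    def test_order_deterministic(self):
        a = ld.enumerate_contrasts(8)
        b = ld.enumerate_contrasts(8)
        assert [(c.positive_set, c.negative_set) for c in a] == \
               [(c.positive_set, c.negative_set) for c in b]


class TestCodeMatrix:
    def test_shape_and_entries(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        assert M.shape == (8, 40)
        assert set(np.unique(M)) <= {-1, 0, 1}

    def test_pair_columns_have_one_of_each(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        for j, c in enumerate(contrasts):
            if c.kind == "pair":
                assert (M[:, j] == 1).sum() == 1
                assert (M[:, j] == -1).sum() == 1
                assert (M[:, j] == 0).sum() == 6

    def test_each_class_in_seven_pair_columns(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        pair_cols = [j for j, c in enumerate(contrasts) if c.kind == "pair"]
        for k in range(8):
            assert np.count_nonzero(M[k, pair_cols]) == 7

    def test_columns_balanced(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        np.testing.assert_array_equal((M == 1).sum(axis=0), (M == -1).sum(axis=0))

    def test_pairwise_submatrix_independent_of_groups(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        pairs_only = [c for c in contrasts if c.kind == "pair"]
        Mp = ld.build_code_matrix(pairs_only, 8)
        np.testing.assert_array_equal(M[:, :28], Mp)


class TestFLD:
    def test_symmetric_1d_threshold_at_zero(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.3, 500), rng.normal(-1.0, 0.3, 500)])
        y = np.concatenate([np.ones(500), -np.ones(500)])
        fld = ld.fld_fit(x[:, None], y)
        assert abs(fld.b / fld.w[0]) < 0.05

    def test_no_signal_accuracy_near_half(self, rng):
        X = rng.standard_normal((400, 3))
        y = np.concatenate([np.ones(200), -np.ones(200)])
        fld = ld.fld_fit(X, y)
        acc = np.mean(np.sign(X @ fld.w - fld.b) == y)
        assert abs(acc - 0.5) < 0.1

    def test_weights_match_closed_form(self, rng):
        sigma = np.array([[1.0, 0.6], [0.6, 2.0]])
        mu = np.array([0.8, -0.5])
        L = np.linalg.cholesky(sigma)
        n = 2000
        xp = rng.standard_normal((n, 2)) @ L.T + mu
        xn = rng.standard_normal((n, 2)) @ L.T - mu
        fld = ld.fld_fit(np.vstack([xp, xn]),
                         np.concatenate([np.ones(n), -np.ones(n)]))
        expect = np.linalg.solve(sigma, 2 * mu)
        cos = fld.w @ expect / np.linalg.norm(fld.w) / np.linalg.norm(expect)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_margin_signs(self, rng):
        xp = rng.normal(2.0, 0.5, (50, 2))
        xn = rng.normal(-2.0, 0.5, (50, 2))
        fld = ld.fld_fit(np.vstack([xp, xn]),
                         np.concatenate([np.ones(50), -np.ones(50)]))
        mu_p, mu_n = xp.mean(axis=0), xn.mean(axis=0)
        assert ld.fld_margin(fld, mu_p) > 0
        assert ld.fld_margin(fld, mu_n) < 0
        assert abs(ld.fld_margin(fld, (mu_p + mu_n) / 2)) < 1e-9

    def test_single_class_rejected(self, rng):
        with pytest.raises(TrainingError):
            ld.fld_fit(rng.standard_normal((10, 2)), np.ones(10))

    def test_margin_dimension_mismatch(self):
        fld = ld.FLD(w=np.array([1.0, 2.0]), b=0.0)
        with pytest.raises(ValidationError):
            ld.fld_margin(fld, np.zeros(3))


class TestEcocDecoding:
    def test_oracle_margins_decode_every_class(self):
        contrasts = ld.enumerate_contrasts(8)
        M = ld.build_code_matrix(contrasts, 8)
        for k in range(8):
            y = M[k].astype(float)  # oracle: +1/-1/0 exactly per code row
            assert decode_margins(y[None, :], M)[0] == k

    def test_all_zero_margins_tie_break_to_class_zero(self):
        M = ld.build_code_matrix(ld.enumerate_contrasts(8), 8)
        assert decode_margins(np.zeros((1, 40)), M)[0] == 0

    def test_argmin_matches_exhaustive_minimum(self, rng):
        M = ld.build_code_matrix(ld.enumerate_contrasts(8), 8)
        Y = rng.standard_normal((50, 40))
        got = decode_margins(Y, M)
        for i in range(50):
            scores = [-(M[k] @ Y[i]) for k in range(8)]
            assert got[i] == int(np.argmin(scores))


def _planted_covs(rng, labels, C=8, sep=3.0):
    """Per-trial covariances with class-dependent anisotropy."""
    K = 8
    covs = []
    for k in labels:
        d = np.ones(C)
        d[k % C] = sep
        d[(k + 1) % C] = sep / 2
        a = rng.standard_normal((C, 160)) * np.sqrt(d)[:, None]
        covs.append(np.cov(a))
    return np.asarray(covs)


class TestEcocFit:
    def test_feature_dimension_two_bands(self, small_banded, small_session):
        _, T, _ = small_session
        model = ld.ecoc_fit(small_banded, T.labels, (0.0, 1000.0))
        assert model.L == 40
        for fld in model.flds:
            assert fld.w.size == 12  # 6 per band x 2 bands

    def test_training_recovery_on_planted_structure(self, rng):
        labels = np.repeat(np.arange(8), 10)
        covs = _planted_covs(rng, labels)
        model = ecoc_fit_covs([covs], labels, [ld.SubBandSpec(1, 4, name="x")],
                              (0.0, 1.0))
        pred = ld.ecoc_predict_batch([covs], model)
        assert ld.decoding_power(pred, labels) > 0.9

    def test_too_few_trials_in_class_named(self, rng):
        labels = np.repeat(np.arange(8), 4)
        labels = labels[labels != 3]
        labels = np.append(labels, 3)
        covs = _planted_covs(rng, labels)
        with pytest.raises(TrainingError, match="3"):
            ecoc_fit_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0.0, 1.0))

    def test_determinism(self, rng):
        labels = np.repeat(np.arange(8), 6)
        covs = _planted_covs(rng, labels)
        a = ecoc_fit_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0.0, 1.0))
        b = ecoc_fit_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0.0, 1.0))
        for fa, fb in zip(a.flds, b.flds):
            np.testing.assert_array_equal(fa.w, fb.w)
        np.testing.assert_array_equal(
            ld.ecoc_predict_batch([covs], a), ld.ecoc_predict_batch([covs], b)
        )

    def test_rotation_equivariance(self, rng):
        # relabeling directions by +1 (a 45 deg rotation) rotates predictions
        labels = np.repeat(np.arange(8), 10)
        covs = _planted_covs(rng, labels)
        base = ecoc_fit_covs([covs], labels, [ld.SubBandSpec(1, 4)], (0.0, 1.0))
        rot = ecoc_fit_covs([covs], (labels + 1) % 8,
                            [ld.SubBandSpec(1, 4)], (0.0, 1.0))
        p0 = ld.ecoc_predict_batch([covs], base)
        p1 = ld.ecoc_predict_batch([covs], rot)
        assert np.mean(p1 == (p0 + 1) % 8) > 0.95

    def test_single_trial_predict_matches_batch(self, small_banded,
                                                small_session):
        _, T, _ = small_session
        model = ld.ecoc_fit(small_banded, T.labels, (0.0, 1000.0))
        sl = small_banded[0].window_slice(0.0, 1000.0)
        trial_bands = [b.data[5][:, sl] for b in small_banded]
        from lfpdecode.csp import trial_covariances
        covs = [trial_covariances(b.data[5:6], sl) for b in small_banded]
        assert ld.ecoc_predict(trial_bands, model) == \
            ld.ecoc_predict_batch(covs, model)[0]


class TestModelStore:
    def test_round_trip_preserves_predictions(self, tmp_path, small_banded,
                                              small_session):
        _, T, _ = small_session
        model = ld.ecoc_fit(small_banded, T.labels, (0.0, 1000.0))
        path = tmp_path / "model.h5"
        ld.save_model(model, path)
        loaded = ld.load_model(path)
        assert loaded.K == model.K and loaded.L == model.L
        np.testing.assert_array_equal(loaded.M, model.M)
        from lfpdecode.csp import trial_covariances
        sl = small_banded[0].window_slice(0.0, 1000.0)
        covs = [trial_covariances(b.data[:20], sl) for b in small_banded]
        np.testing.assert_array_equal(
            ld.ecoc_predict_batch(covs, model),
            ld.ecoc_predict_batch(covs, loaded),
        )
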