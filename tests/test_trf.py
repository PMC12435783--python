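"""TRF core: preprocessing, design matrices, ridge solves, CV, scoring."""

import numpy as np
import pytest

from speechtrf.trf import (
    AccuracyTable,
    EEGTrialSet,
    LagSpec,
    RidgeConfig,
    build_lagged_design,
    crossval_submodels,
    crossval_trf,
    predict_eeg,
    preprocess_eeg,
    ridge_fit,
    tune_lambda,
    valid_sample_correlation,
    valid_sample_mask,
)
from tests.conftest import loop_lagged_design, pearson_oracle, ridge_oracle


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_joint_zscore_moments(self, rng):
        raw = EEGTrialSet([rng.standard_normal((3, 2000)) for _ in range(2)], fs=100.0)
        out = preprocess_eeg(raw)
        pooled = np.concatenate([t.ravel() for t in out.trials])
        assert abs(pooled.mean()) < 1e-12
        assert abs(pooled.std() - 1.0) < 1e-12
        assert out.normalized

    def test_relative_channel_power_preserved(self, rng):
        a = rng.standard_normal(5000)
        raw = EEGTrialSet([np.vstack([3.0 * a, a])], fs=100.0)
        out = preprocess_eeg(raw)
        ratio = out.trials[0][0].std() / out.trials[0][1].std()
        assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_20hz_attenuated_by_15hz_lowpass(self):
        """Frequency-response oracle: stopband tone loses >99% variance."""
        fs = 500.0
        t = np.arange(int(fs * 10)) / fs
        sig = np.sin(2 * np.pi * 20 * t)[None, :]
        raw = EEGTrialSet([sig], fs=fs)
        taps_out = preprocess_eeg(raw, lowpass_hz=15.0)
        # compare variance before z-scoring: refilter manually via the ratio
        from scipy.signal import filtfilt, firwin

        taps = firwin(101, 15.0, fs=fs, window="hann")
        filtered = filtfilt(taps, 1.0, sig, axis=1)
        assert filtered.var() < 0.01 * sig.var()

    def test_nonfinite_rejected(self):
        bad = np.zeros((1, 100))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            EEGTrialSet([bad], fs=100.0)

    def test_fs_too_low(self):
        raw = EEGTrialSet([np.random.randn(1, 100)], fs=20.0)
        with pytest.raises(ValueError):
            preprocess_eeg(raw, lowpass_hz=15.0)


# ---------------------------------------------------------------------------
# lagged design
# ---------------------------------------------------------------------------

class TestLaggedDesign:
    def test_single_impulse_diagonal(self):
        x = np.zeros(20)
        x[10] = 1.0
        lag = LagSpec(fs=1000.0, lag_min_ms=0, lag_max_ms=2)
        X, names = build_lagged_design({"f": x}, lag)
        assert X.shape == (20, 4)  # 3 lags + bias
        for li, row in enumerate((10, 11, 12)):
            assert X[row, li] == 1.0
        assert X[:, :3].sum() == 3.0
        assert np.all(X[:, -1] == 1.0)

    def test_paper_window_gives_251_lags(self):
        lag = LagSpec(fs=500.0, lag_min_ms=0, lag_max_ms=500)
        assert lag.n_lags == 251
        X, _ = build_lagged_design({"f": np.zeros(300)}, lag)
        assert X.shape[1] == 252

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(50)
        lag = LagSpec(fs=1000.0, lag_min_ms=0, lag_max_ms=7)
        X, _ = build_lagged_design({"f": x}, lag)
        np.testing.assert_array_equal(X, loop_lagged_design({"f": x}, lag.lag_samples))

    def test_two_features_match_loop_oracle(self, rng):
        feats = {"a": rng.standard_normal(40), "b": rng.standard_normal(40)}
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=50)
        X, _ = build_lagged_design(feats, lag)
        np.testing.assert_array_equal(X, loop_lagged_design(feats, lag.lag_samples))

    def test_lag_window_longer_than_trial(self):
        lag = LagSpec(fs=500.0)
        with pytest.raises(ValueError, match="longer than trial"):
            build_lagged_design({"f": np.zeros(100)}, lag)


def test_ridge_config_grid_validation():
    with pytest.raises(ValueError):
        RidgeConfig(lambda_grid=(1.0, 0.5))
    with pytest.raises(ValueError):
        RidgeConfig(lambda_grid=(0.0, 1.0))
    assert len(RidgeConfig().lambda_grid) == 13


# ---------------------------------------------------------------------------
# ridge fit / predict
# ---------------------------------------------------------------------------

class TestRidgeFit:
    def test_noiseless_kernel_recovery(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=190)
        kernel = np.exp(-0.5 * ((np.arange(20) - 6) / 3.0) ** 2)
        x = (rng.random(2000) < 0.02).astype(float)
        y = np.convolve(x, kernel)[:2000]
        X, _ = build_lagged_design({"f": x}, lag)
        model = ridge_fit(X, y[None, :], 1e-6, lag, ["f"])
        assert np.abs(model.weights[0, :, 0] - kernel).max() < 1e-6

    def test_matches_direct_solve_oracle(self, rng):
        for _ in range(10):
            X = rng.standard_normal((60, 9))
            X[:, -1] = 1.0
            Y = rng.standard_normal((60, 2))
            lam = float(rng.uniform(0.1, 10))
            lag = LagSpec(fs=1000.0, lag_min_ms=0, lag_max_ms=3)
            model = ridge_fit(X, Y.T, lam, lag, ["a", "b"])
            W = ridge_oracle(X, Y, lam)
            got = np.vstack([model.weights.reshape(-1, 2), model.bias[None, :]])
            np.testing.assert_allclose(got, W, atol=1e-8)

    def test_large_lambda_shrinks(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        x = rng.standard_normal(400)
        y = rng.standard_normal((1, 400))
        X, _ = build_lagged_design({"f": x}, lag)
        small = ridge_fit(X, y, 1e-6, lag, ["f"])
        big = ridge_fit(X, y, 1e6, lag, ["f"])
        assert np.linalg.norm(big.weights) < 1e-3 * np.linalg.norm(small.weights)

    def test_lambda_zero_rejected(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        X, _ = build_lagged_design({"f": rng.standard_normal(200)}, lag)
        with pytest.raises(ValueError, match="grid"):
            ridge_fit(X, np.zeros((1, 200)), 0.0, lag, ["f"])

    def test_row_mismatch_rejected(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        X, _ = build_lagged_design({"f": rng.standard_normal(200)}, lag)
        with pytest.raises(ValueError, match="rows"):
            ridge_fit(X, np.zeros((1, 150)), 1.0, lag, ["f"])

    def test_equivalence_random_instances(self, rng):
        """Spec invariant: agreement to 1e-8 up to 5 features x 50 lags x 8 ch."""
        lag = LagSpec(fs=1000.0, lag_min_ms=0, lag_max_ms=49)
        feats = {f"f{i}": rng.standard_normal(600) for i in range(5)}
        Y = rng.standard_normal((600, 8))
        X, names = build_lagged_design(feats, lag)
        lam = 3.7
        model = ridge_fit(X, Y.T, lam, lag, names)
        W = ridge_oracle(X, Y, lam)
        got = np.vstack([model.weights.reshape(-1, 8), model.bias[None, :]])
        np.testing.assert_allclose(got, W, atol=1e-8)


class TestPredict:
    def _model(self, rng, n_feat=1, n_ch=2):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=90)
        from speechtrf.trf import TRFModel

        names = [f"f{i}" for i in range(n_feat)]
        w = rng.standard_normal((n_feat, lag.n_lags, n_ch))
        return TRFModel(w, rng.standard_normal(n_ch), 1.0, lag, names)

    def test_zero_features_predict_bias(self, rng):
        model = self._model(rng)
        pred = predict_eeg(model, {"f0": np.zeros(100)})
        np.testing.assert_allclose(pred, model.bias[:, None] * np.ones((2, 100)))

    def test_self_prediction_noiseless(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=90)
        x = (rng.random(500) < 0.05).astype(float)
        kernel = rng.standard_normal(lag.n_lags)
        y = np.convolve(x, kernel)[:500][None, :]
        X, _ = build_lagged_design({"f": x}, lag)
        model = ridge_fit(X, y, 1e-8, lag, ["f"])
        pred = predict_eeg(model, {"f": x})
        np.testing.assert_allclose(pred, y, atol=1e-6)

    def test_prediction_equals_convolution(self, rng):
        """Single-feature prediction is kernel * regressor + bias."""
        model = self._model(rng, n_feat=1, n_ch=1)
        x = (rng.random(300) < 0.05).astype(float)
        pred = predict_eeg(model, {"f0": x})
        expected = np.convolve(x, model.weights[0, :, 0])[:300] + model.bias[0]
        np.testing.assert_allclose(pred[0], expected, atol=1e-10)

    def test_missing_feature_rejected(self, rng):
        model = self._model(rng)
        with pytest.raises(ValueError, match="missing"):
            predict_eeg(model, {"other": np.zeros(100)})


# ---------------------------------------------------------------------------
# valid-sample machinery
# ---------------------------------------------------------------------------

class TestValidSampleMask:
    def test_single_onset_at_zero_gives_251(self):
        lag = LagSpec(fs=500.0)
        feat = np.zeros(1000)
        feat[0] = 1.0
        mask = valid_sample_mask({"word_onset": feat}, lag)
        assert mask.sum() == 251
        assert mask[:251].all() and not mask[251:].any()

    def test_dense_onsets_all_true_after_first(self):
        lag = LagSpec(fs=500.0)
        feat = np.zeros(2000)
        feat[100::50] = 1.0  # every 100 ms
        mask = valid_sample_mask({"word_onset": feat}, lag)
        assert not mask[:100].any()
        assert mask[100:].all()

    def test_matches_bruteforce_union(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=200)
        feat = (rng.random(3000) < 0.01).astype(float)
        mask = valid_sample_mask({"phoneme_onset": feat}, lag)
        expected = np.zeros(3000, dtype=bool)
        for s in np.flatnonzero(feat):
            expected[s : s + lag.n_lags] = True
        np.testing.assert_array_equal(mask, expected)

    def test_envelope_only_all_true(self):
        lag = LagSpec(fs=100.0)
        mask = valid_sample_mask({"envelope": np.random.rand(500)}, lag)
        assert mask.all()

    def test_union_over_multiple_onset_features(self):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=50)
        a = np.zeros(400)
        b = np.zeros(400)
        a[10] = 1.0
        b[300] = 1.0
        mask = valid_sample_mask({"word_onset": a, "phoneme_onset": b}, lag)
        assert mask[10:16].all() and mask[300:306].all()
        assert mask.sum() == 12


class TestValidSampleCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal((2, 100))
        mask = np.ones(100, dtype=bool)
        np.testing.assert_allclose(valid_sample_correlation(x, x, mask), 1.0)

    def test_perfect_anticorrelation(self, rng):
        x = rng.standard_normal((1, 100))
        mask = np.ones(100, dtype=bool)
        np.testing.assert_allclose(valid_sample_correlation(x, -x, mask), -1.0)

    def test_matches_pearson_oracle(self, rng):
        a = rng.standard_normal((3, 200))
        b = rng.standard_normal((3, 200))
        mask = np.ones(200, dtype=bool)
        r = valid_sample_correlation(a, b, mask)
        for ch in range(3):
            assert r[ch] == pytest.approx(pearson_oracle(a[ch], b[ch]), abs=1e-12)

    def test_constant_masked_segment_is_nan(self, rng):
        pred = np.zeros((1, 50))
        actual = rng.standard_normal((1, 50))
        mask = np.ones(50, dtype=bool)
        assert np.isnan(valid_sample_correlation(pred, actual, mask)[0])

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            valid_sample_correlation(np.zeros((1, 10)), np.zeros((1, 10)),
                                     np.array([True, True] + [False] * 8))

    def test_masking_monotonicity(self, rng):
        """Growing the mask toward all-true converges to plain Pearson r."""
        actual = rng.standard_normal((1, 1000))
        pred = actual + 0.5 * rng.standard_normal((1, 1000))
        r_full = pearson_oracle(pred[0], actual[0])
        order = rng.permutation(1000)
        dist = []
        for frac in (0.3, 0.5, 0.7, 0.9, 1.0):
            mask = np.zeros(1000, dtype=bool)
            mask[order[: int(1000 * frac)]] = True
            r = valid_sample_correlation(pred, actual, mask)[0]
            dist.append(abs(r - r_full))
        assert dist[-1] < 1e-12
        assert dist[0] > dist[-2] or dist[0] < 0.05  # shrinking trend


# ---------------------------------------------------------------------------
# cross-validation and tuning
# ---------------------------------------------------------------------------

def _impulse_trials(rng, n_trials=3, n=800, p=0.03):
    return [{"phoneme_onset": (rng.random(n) < p).astype(float)} for _ in range(n_trials)]


class TestCrossval:
    def test_identical_noiseless_trials_near_perfect(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=200)
        x = (rng.random(1000) < 0.04).astype(float)
        kernel = rng.standard_normal(lag.n_lags)
        y = np.convolve(x, kernel)[:1000]
        feats = [{"phoneme_onset": x}] * 6
        eeg = EEGTrialSet([y[None, :]] * 6, fs=100.0)
        model, acc = crossval_trf(feats, eeg, 1e-6, lag)
        assert np.all(acc.r > 0.999)
        assert acc.r.shape == (6, 1)  # each trial is test exactly once

    def test_fold_refits_match_bruteforce(self, rng):
        """Fold-averaged TRF equals the average of explicit per-fold solves."""
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=120)
        feats = _impulse_trials(rng, n_trials=3)
        eeg = EEGTrialSet([rng.standard_normal((2, 800)) for _ in range(3)], fs=100.0)
        lam = 2.0
        model, acc = crossval_trf(feats, eeg, lam, lag, per_feature_standardize=False)
        fold_W = []
        for ti in range(3):
            train = [j for j in range(3) if j != ti]
            X = np.vstack([
                build_lagged_design(feats[j], lag, ["phoneme_onset"])[0] for j in train
            ])
            Y = np.vstack([eeg.trials[j].T for j in train])
            fold_W.append(ridge_oracle(X, Y, lam))
        avg = np.mean(fold_W, axis=0)
        got = np.vstack([model.weights.reshape(-1, 2), model.bias[None, :]])
        np.testing.assert_allclose(got, avg, atol=1e-8)

    def test_standardization_does_not_change_recovered_units(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=150)
        x = (rng.random(2000) < 0.04).astype(float)
        kernel = rng.standard_normal(lag.n_lags)
        y = np.convolve(x, kernel)[:2000]
        feats = [{"f_onset": x}] * 3
        eeg = EEGTrialSet([y[None, :]] * 3, fs=100.0)
        m_std, _ = crossval_trf(feats, eeg, 1e-8, lag, per_feature_standardize=True)
        m_raw, _ = crossval_trf(feats, eeg, 1e-8, lag, per_feature_standardize=False)
        np.testing.assert_allclose(m_std.weights, m_raw.weights, atol=1e-6)
        np.testing.assert_allclose(m_std.weights[0, :, 0], kernel, atol=1e-6)

    def test_submodels_match_separate_fits(self, rng):
        """Column-sliced submodel equals an independent fit of that subset."""
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        feats = [
            {"word_onset": (rng.random(600) < 0.02).astype(float),
             "phoneme_onset": (rng.random(600) < 0.05).astype(float)}
            for _ in range(3)
        ]
        eeg = EEGTrialSet([rng.standard_normal((2, 600)) for _ in range(3)], fs=100.0)
        both = crossval_submodels(
            feats, eeg, 1.5, lag,
            {"word": ["word_onset"], "joint": ["word_onset", "phoneme_onset"]},
        )
        word_only = [{"word_onset": f["word_onset"]} for f in feats]
        solo, acc_solo = crossval_trf(word_only, eeg, 1.5, lag)
        np.testing.assert_allclose(both["word"].model.weights, solo.weights, atol=1e-10)
        np.testing.assert_allclose(both["word"].accuracy.r, acc_solo.r, atol=1e-12)

    def test_mismatched_features_rejected(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        feats = [{"a_onset": np.zeros(500)}, {"b_onset": np.zeros(500)}]
        eeg = EEGTrialSet([np.zeros((1, 500)) + np.arange(500)] * 2, fs=100.0)
        with pytest.raises(ValueError, match="mismatched"):
            crossval_trf(feats, eeg, 1.0, lag)

    def test_single_trial_rejected(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        eeg = EEGTrialSet([rng.standard_normal((1, 500))], fs=100.0)
        with pytest.raises(ValueError, match="at least 2"):
            crossval_trf(_impulse_trials(rng, 1, 500), eeg, 1.0, lag)


class TestTuneLambda:
    def test_matches_bruteforce_grid(self, rng):
        """Selected lambda equals the argmin of an exhaustive evaluation."""
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=120)
        feats = _impulse_trials(rng, 3, 700)
        kernel = rng.standard_normal(lag.n_lags)
        trials = [
            (np.convolve(f["phoneme_onset"], kernel)[:700]
             + 2.0 * rng.standard_normal(700))[None, :]
            for f in feats
        ]
        eeg = EEGTrialSet(trials, fs=100.0)
        grid = (0.1, 10.0, 1000.0, 1e5)
        lam_opt, mse = tune_lambda(feats, eeg, grid, lag, per_feature_standardize=False)

        oracle_mse = []
        for lam in grid:
            err, npts = 0.0, 0
            for ti in range(3):
                train = [j for j in range(3) if j != ti]
                X = np.vstack([
                    build_lagged_design(feats[j], lag, ["phoneme_onset"])[0]
                    for j in train
                ])
                Y = np.vstack([eeg.trials[j].T for j in train])
                W = ridge_oracle(X, Y, lam)
                Xt = build_lagged_design(feats[ti], lag, ["phoneme_onset"])[0]
                mask = valid_sample_mask(feats[ti], lag)
                diff = (Xt @ W).T[:, mask] - eeg.trials[ti][:, mask]
                err += (diff**2).sum()
                npts += diff.size
            oracle_mse.append(err / npts)
        np.testing.assert_allclose(mse, oracle_mse, rtol=1e-9)
        assert lam_opt == grid[int(np.argmin(oracle_mse))]

    def test_noiseless_selects_grid_minimum(self, rng):
        lag = LagSpec(fs=100.0, lag_min_ms=0, lag_max_ms=100)
        feats = _impulse_trials(rng, 3, 900)
        kernel = rng.standard_normal(lag.n_lags)
        trials = [np.convolve(f["phoneme_onset"], kernel)[:900][None, :] for f in feats]
        eeg = EEGTrialSet(trials, fs=100.0)
        grid = (1e-6, 1e-2, 1.0, 100.0)
        lam_opt, mse = tune_lambda(feats, eeg, grid, lag)
        assert lam_opt == 1e-6
        assert np.all(np.diff(mse) > 0)  # bias-only MSE grows with lambda

    def test_empty_grid_rejected(self, rng):
        eeg = EEGTrialSet([rng.standard_normal((1, 500))] * 2, fs=100.0)
        with pytest.raises(ValueError, match="empty"):
            tune_lambda(_impulse_trials(rng, 2, 500), eeg, [], LagSpec(fs=100.0, lag_max_ms=100))


def test_accuracy_table_bounds():
    with pytest.raises(ValueError, match="outside"):
        AccuracyTable(r=np.array([[1.5]]), valid_sample_fraction=np.array([1.0]))
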