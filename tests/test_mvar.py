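"""MVAR fitting, AIC order selection, spectral transfer, squared PDC and
surrogate-null binarization."""

import numpy as np
import pytest

from netparafac.mvar import (
    BANDS,
    Epochs,
    MVARModel,
    band_average,
    binarize_null,
    default_freq_grid,
    fit_mvar,
    pdc,
    select_order_aic,
    transfer_matrix,
)


def simulate_mvar(coeffs, T, rng, n_trials=1, scale=1.0):
    """Drive an MVAR model with unit white noise (burn-in discarded)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, K, _ = coeffs.shape
    burn = 200
    out = np.empty((K, T, n_trials))
    for n in range(n_trials):
        y = np.zeros((K, T + burn))
        for t in range(p, T + burn):
            acc = rng.standard_normal(K) * scale
            for q in range(p):
                acc += coeffs[q] @ y[:, t - q - 1]
            y[:, t] = acc
        out[:, :, n] = y[:, burn:]
    return out


BIVAR2 = np.array([[[0.5, 0.2], [0.0, 0.4]],
                   [[-0.3, 0.0], [0.1, -0.2]]])


class TestFitMVAR:
    def test_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(0)
        data = simulate_mvar(np.array([[[0.5]]]), T=5000, rng=rng)
        model = fit_mvar(Epochs(data=data, fs=100), order=1)
        assert model.coeffs[0, 0, 0] == pytest.approx(0.5, abs=0.05)

    def test_mvar2_recovery_within_tolerance(self):
        rng = np.random.default_rng(1)
        data = simulate_mvar(BIVAR2, T=5000, rng=rng)
        model = fit_mvar(Epochs(data=data, fs=100), order=2)
        np.testing.assert_allclose(model.coeffs, BIVAR2, atol=0.05)

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        ep = Epochs(data=rng.standard_normal((2, 4000, 1)), fs=100)
        model = fit_mvar(ep, order=1)
        # 3 x standard error of an AR coefficient at T samples
        assert np.all(np.abs(model.coeffs) < 3.0 / np.sqrt(4000))

    def test_matches_statsmodels_var(self):
        """Independent oracle: statsmodels VAR (no intercept) on one trial."""
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(3)
        data = simulate_mvar(BIVAR2, T=1500, rng=rng)
        model = fit_mvar(Epochs(data=data, fs=100), order=2)
        ref = VAR(data[:, :, 0].T).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(model.coeffs, ref.coefs, atol=1e-8)

    def test_multi_trial_pooling(self):
        rng = np.random.default_rng(4)
        data = simulate_mvar(BIVAR2, T=400, rng=rng, n_trials=12)
        model = fit_mvar(Epochs(data=data, fs=100), order=2)
        np.testing.assert_allclose(model.coeffs, BIVAR2, atol=0.06)

    def test_order_exceeding_samples_raises(self):
        ep = Epochs(data=np.random.default_rng(0).standard_normal((2, 10, 1)),
                    fs=10)
        with pytest.raises(ValueError):
            fit_mvar(ep, order=10)

    def test_collinear_channels_raise(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        ep = Epochs(data=np.stack([x, 2 * x])[:, :, None], fs=100)
        with pytest.raises(np.linalg.LinAlgError, match="channels"):
            fit_mvar(ep, order=1)


class TestOrderSelection:
    def test_known_order_majority(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            data = simulate_mvar(BIVAR2, T=5000, rng=rng)
            hits += select_order_aic(Epochs(data=data, fs=100), 5) == 2
        assert hits > 10

    def test_white_noise_prefers_order_one(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            ep = Epochs(data=rng.standard_normal((2, 2000, 1)), fs=100)
            hits += select_order_aic(ep, 5) == 1
        assert hits > 10

    def test_single_candidate(self):
        ep = Epochs(data=np.random.default_rng(0).standard_normal((2, 200, 1)),
                    fs=100)
        assert select_order_aic(ep, 1) == 1


class TestTransferAndPDC:
    def test_zero_coefficients_identity(self):
        model = MVARModel(order=1, coeffs=np.zeros((1, 3, 3)),
                          noise_cov=np.eye(3), fs=100)
        for f in (0.0, 10.0, 50.0):
            np.testing.assert_allclose(transfer_matrix(model, f), np.eye(3))

    def test_dc_value_scalar(self):
        model = MVARModel(order=1, coeffs=np.array([[[0.5]]]),
                          noise_cov=np.eye(1), fs=100)
        assert transfer_matrix(model, 0.0)[0, 0] == pytest.approx(0.5)

    def test_diagonal_model_stays_diagonal(self):
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = np.diag([0.5, -0.3, 0.2])
        coeffs[1] = np.diag([0.1, 0.2, -0.1])
        model = MVARModel(order=2, coeffs=coeffs, noise_cov=np.eye(3), fs=100)
        for f in (5.0, 20.0, 45.0):
            lam = transfer_matrix(model, f)
            off = lam[~np.eye(3, dtype=bool)]
            assert np.max(np.abs(off)) == 0.0

    def test_univariate_pdc_is_one(self):
        model = MVARModel(order=1, coeffs=np.array([[[0.4]]]),
                          noise_cov=np.eye(1), fs=100)
        spec = pdc(model, default_freq_grid(100))
        np.testing.assert_allclose(spec.values, 1.0)

    def test_absent_coupling_gives_zero_pdc(self):
        coeffs = np.array([[[0.5, 0.0], [0.3, 0.4]]])  # no 2 -> 1 influence
        model = MVARModel(order=1, coeffs=coeffs, noise_cov=np.eye(2), fs=100)
        spec = pdc(model, default_freq_grid(100))
        assert np.all(spec.values[0, 1, :] == 0)
        assert np.all(spec.values[1, 0, :] > 0)

    def test_column_normalization_random_stable_models(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            K = int(rng.integers(2, 5))
            coeffs = rng.standard_normal((2, K, K)) * 0.2
            model = MVARModel(order=2, coeffs=coeffs, noise_cov=np.eye(K),
                              fs=128)
            spec = pdc(model, default_freq_grid(128))
            np.testing.assert_allclose(spec.values.sum(axis=0), 1.0,
                                       atol=1e-8)
            assert np.all(spec.values >= 0) and np.all(spec.values <= 1)

    def test_pdc_invariant_to_common_channel_scaling(self):
        rng = np.random.default_rng(8)
        data = simulate_mvar(BIVAR2, T=2000, rng=rng)
        grid = default_freq_grid(100)
        base = pdc(fit_mvar(Epochs(data=data, fs=100), 2), grid)
        scaled = pdc(fit_mvar(Epochs(data=data * 37.5, fs=100), 2), grid)
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-6)


class TestBandAverage:
    def test_constant_spectrum(self):
        vals = np.tile(np.array([[0.2]]), (1, 1, 40))
        from netparafac.mvar import PDCSpectrum
        spec = PDCSpectrum(values=vals, freqs=np.arange(1.0, 41.0))
        assert band_average(spec, (8, 12)).values[0, 0] == pytest.approx(0.2)

    def test_theta_band_on_integer_grid(self):
        freqs = np.arange(1.0, 41.0)
        vals = np.broadcast_to(freqs, (1, 1, 40)).copy()
        from netparafac.mvar import PDCSpectrum
        spec = PDCSpectrum(values=vals, freqs=freqs)
        assert band_average(spec, BANDS["theta"]).values[0, 0] == pytest.approx(5.0)

    def test_empty_overlap_raises(self):
        from netparafac.mvar import PDCSpectrum
        spec = PDCSpectrum(values=np.ones((1, 1, 3)),
                           freqs=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="band"):
            band_average(spec, (10, 12))


class TestBinarizeNull:
    def test_coupled_pair_always_detected(self):
        grid = default_freq_grid(100)
        for s in range(5):
            rng = np.random.default_rng(300 + s)
            coeffs = np.array([[[0.5, 0.0], [0.8, 0.4]]])  # strong 1 -> 2
            data = simulate_mvar(coeffs, T=800, rng=rng)
            ep = Epochs(data=data, fs=100)
            bn = band_average(pdc(fit_mvar(ep, 1), grid), BANDS["alpha"])
            binary = binarize_null(bn, ep, order=1, alpha=0.05,
                                   n_surrogates=60, rng_seed=s)
            assert binary[1, 0] == 1      # cell (i, j) = influence j -> i
            assert np.all(np.diag(binary) == 0)

    def test_false_positive_rate_near_alpha(self):
        """Connection-wise null calibration on independent channels: the
        off-diagonal hit fraction should be close to alpha."""
        grid = default_freq_grid(100)
        hits = total = 0
        for s in range(25):
            rng = np.random.default_rng(400 + s)
            ep = Epochs(data=rng.standard_normal((3, 500, 1)), fs=100)
            bn = band_average(pdc(fit_mvar(ep, 2), grid), BANDS["alpha"])
            binary = binarize_null(bn, ep, order=2, alpha=0.05,
                                   n_surrogates=60, rng_seed=s)
            hits += int(binary.sum())
            total += 6
        rate = hits / total
        # 95% binomial band around alpha=0.05 for 150 Bernoulli draws
        assert 0.05 - 2.5 * np.sqrt(0.05 * 0.95 / total) <= rate \
            <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / total)

    def test_single_channel_rejected(self):
        rng = np.random.default_rng(0)
        ep = Epochs(data=rng.standard_normal((1, 300, 1)), fs=100)
        spec = pdc(fit_mvar(ep, 1), default_freq_grid(100))
        with pytest.raises(ValueError, match="2 channels"):
            binarize_null(spec, ep, order=1)

    def test_pluggable_threshold_function(self):
        rng = np.random.default_rng(1)
        ep = Epochs(data=rng.standard_normal((2, 300, 1)), fs=100)
        bn = band_average(pdc(fit_mvar(ep, 1), default_freq_grid(100)),
                          BANDS["alpha"])
        always_pass = lambda epochs, order, freqs, band: np.full((2, 2), -1.0)
        binary = binarize_null(bn, ep, order=1, threshold_fn=always_pass)
        assert binary[0, 1] == 1 and binary[1, 0] == 1
        assert np.all(np.diag(binary) == 0)
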