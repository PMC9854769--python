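import numpy as np
import pytest

from eegmusic import (AutocorrMatrix, SubspaceConfig, SyntheticSpec,
                      eigen_split, estimate_autocorrelation,
                      music_pseudospectrum, music_spectra_batch,
                      pisarenko_powers, simulate_trial, welch_psd)
from eegmusic.errors import ConfigError, DataError, NumericalError

FS = 200.0


def char_poly_eigvals(mat):
    """Independent eigenvalue oracle: Faddeev-LeVerrier characteristic
    polynomial coefficients, then polynomial root finding."""
    n = mat.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    m = np.eye(n)
    for k in range(1, n + 1):
        m = mat @ m
        c = -np.trace(m) / k
        coeffs[k] = c
        m += c * np.eye(n)
    roots = np.roots(coeffs)
    return np.sort(roots.real)[::-1]


class TestAutocorrelation:
    def test_zero_vector(self):
        r = estimate_autocorrelation(np.zeros(100), 8)
        np.testing.assert_array_equal(r.matrix, np.zeros((8, 8)))

    def test_white_noise_is_nearly_diagonal(self, rng):
        n = 100_000
        r = estimate_autocorrelation(rng.standard_normal(n), 4)
        assert r.lags[0] == pytest.approx(1.0, abs=0.02)
        assert np.all(np.abs(r.lags[1:]) < 3 / np.sqrt(n))

    def test_cosine_closed_form(self):
        # x = A cos(2 pi 10 n / 200): biased lags ~ (A^2/2) cos(0.1 pi k)
        n, a = 10_000, 2.0
        x = a * np.cos(2 * np.pi * 10 * np.arange(n) / FS)
        r = estimate_autocorrelation(x, 8)
        expected = (a ** 2 / 2) * np.cos(0.1 * np.pi * np.arange(8))
        np.testing.assert_allclose(r.lags, expected, atol=0.02 * a ** 2 / 2)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal(64)
        r = estimate_autocorrelation(x, 5)
        for k in range(5):
            brute = sum(x[i] * x[i + k] for i in range(len(x) - k)) / len(x)
            assert r.lags[k] == pytest.approx(brute, abs=1e-12)

    def test_toeplitz_psd_structure(self, rng):
        r = estimate_autocorrelation(rng.standard_normal(500), 10)
        mat = r.matrix
        np.testing.assert_array_equal(mat, mat.T)
        assert np.all(np.abs(r.lags) <= r.lags[0] + 1e-12)
        assert np.linalg.eigvalsh(mat).min() > -1e-10

    def test_short_input_rejected(self):
        with pytest.raises(DataError, match="4L"):
            estimate_autocorrelation(np.zeros(30), 8)


class TestEigenSplit:
    def test_identity_matrix_threshold_mode(self):
        cfg = SubspaceConfig(L=4, p=0, p_mode="noise_threshold", threshold=2.0)
        split = eigen_split(np.eye(4), cfg)
        assert split.d == 0
        assert split.noise_variance == pytest.approx(1.0)

    def test_rank_one_update(self):
        # R = a a^T + 0.1 I, a = ones(4): lambda = (4.1, 0.1, 0.1, 0.1)
        a = np.ones((4, 1))
        r = a @ a.T + 0.1 * np.eye(4)
        cfg = SubspaceConfig(L=4, p=1, p_mode="complex_dims")
        split = eigen_split(r, cfg)
        np.testing.assert_allclose(split.eigenvalues, [4.1, 0.1, 0.1, 0.1],
                                   atol=1e-12)
        assert split.noise_variance == pytest.approx(0.1)

    def test_matches_characteristic_polynomial_oracle(self, rng):
        # distinct-spectrum random PSD matrices; repeated eigenvalues would
        # degrade the polynomial-root oracle itself, not the eigensolver
        for _ in range(20):
            b = rng.standard_normal((5, 5))
            r = b @ b.T
            cfg = SubspaceConfig(L=5, p=1, p_mode="complex_dims")
            split = eigen_split(r, cfg)
            np.testing.assert_allclose(char_poly_eigvals(r), split.eigenvalues,
                                       atol=1e-8)

    def test_eigenvector_residuals_and_orthonormality(self, rng):
        b = rng.standard_normal((6, 6))
        r = b @ b.T
        cfg = SubspaceConfig(L=6, p=2, p_mode="complex_dims")
        split = eigen_split(r, cfg)
        for lam, v in zip(split.eigenvalues, split.eigenvectors.T):
            np.testing.assert_allclose(r @ v, lam * v, atol=1e-8)
        np.testing.assert_allclose(split.eigenvectors.T @ split.eigenvectors,
                                   np.eye(6), atol=1e-10)
        assert np.all(np.diff(split.eigenvalues) <= 1e-12)

    def test_three_band_literal_p_accepted(self, rng):
        # p=3 complex dims on an alpha/beta/gamma channel: valid configuration
        x = sum(np.cos(2 * np.pi * f * np.arange(2000) / FS + ph)
                for f, ph in zip((10, 20, 35), rng.uniform(0, 6, 3)))
        cfg = SubspaceConfig(L=20, p=3, p_mode="complex_dims")
        split = eigen_split(estimate_autocorrelation(x, 20), cfg)
        assert split.d == 3 and split.noise_vectors.shape == (20, 17)

    def test_empty_noise_subspace_rejected(self):
        cfg = SubspaceConfig(L=4, p=2, p_mode="real_sinusoids")  # d = 4 = L
        with pytest.raises(ConfigError, match="noise subspace"):
            eigen_split(np.eye(4), cfg)

    def test_asymmetric_matrix_rejected(self):
        cfg = SubspaceConfig(L=3, p=1, p_mode="complex_dims")
        with pytest.raises(DataError, match="symmetric"):
            eigen_split(np.arange(9.0).reshape(3, 3), cfg)


def _two_tone(rng, n=2000, f=(10.0, 20.0), snr_db=10.0):
    t = np.arange(n) / FS
    x = sum(np.cos(2 * np.pi * fi * t + rng.uniform(0, 2 * np.pi)) for fi in f)
    noise_var = (len(f) / 2) / 10 ** (snr_db / 10)
    return x + rng.standard_normal(n) * np.sqrt(noise_var)


class TestMusic:
    def test_two_tones_located(self, rng):
        x = _two_tone(rng)
        cfg = SubspaceConfig(L=20, p=2, p_mode="real_sinusoids")
        split = eigen_split(estimate_autocorrelation(x, 20), cfg)
        grid = np.linspace(1.0, 99.0, 1961)  # 0.05 Hz steps
        ps = music_pseudospectrum(split, FS, grid)
        top2 = np.sort(ps.top_frequencies(2))
        assert abs(top2[0] - 10.0) < 0.5
        assert abs(top2[1] - 20.0) < 0.5

    def test_scale_invariance(self, rng):
        x = _two_tone(rng)
        cfg = SubspaceConfig(L=16, p=2, p_mode="real_sinusoids")
        grid = np.linspace(5, 45, 200)
        p1 = music_pseudospectrum(
            eigen_split(estimate_autocorrelation(x, 16), cfg), FS, grid).values
        p5 = music_pseudospectrum(
            eigen_split(estimate_autocorrelation(5 * x, 16), cfg), FS, grid).values
        np.testing.assert_allclose(p1 / p1.max(), p5 / p5.max(), rtol=1e-8)

    def test_band_peaks_on_synthetic_eeg(self):
        # one pseudospectrum peak inside each of the alpha/beta/gamma bands
        spec = SyntheticSpec(n_channels=1, duration=10.0, seed=9,
                             noise_scale=1.0, powerline_amplitude=0.0,
                             blink_rate=0.0)
        x = simulate_trial(spec, "neutral").data[0]
        cfg = SubspaceConfig(L=20, p=3, p_mode="real_sinusoids")
        split = eigen_split(estimate_autocorrelation(x, 20), cfg)
        ps = music_pseudospectrum(split, FS)
        top3 = ps.top_frequencies(3)
        for lo, hi in ((8, 13), (13, 30), (30, 40)):
            assert any(lo <= f <= hi for f in top3), (lo, hi, top3)

    def test_eq7_literal_form_same_peaks(self, rng):
        x = _two_tone(rng)
        cfg = SubspaceConfig(L=20, p=2, p_mode="real_sinusoids")
        split = eigen_split(estimate_autocorrelation(x, 20), cfg)
        grid = np.linspace(5, 45, 801)
        sq = music_pseudospectrum(split, FS, grid, squared=True)
        lit = music_pseudospectrum(split, FS, grid, squared=False)
        assert sq.peaks[0][0] == lit.peaks[0][0]
        assert sq.peaks[0][1] != lit.peaks[0][1]

    def test_noise_orthogonality_grows_with_snr(self, rng):
        # |s(w_true)^H v_noise| shrinks as SNR rises -> peak height grows
        heights = []
        for snr in (0.0, 10.0, 30.0):
            x = _two_tone(np.random.default_rng(5), snr_db=snr)
            cfg = SubspaceConfig(L=20, p=2, p_mode="real_sinusoids")
            split = eigen_split(estimate_autocorrelation(x, 20), cfg)
            grid = np.linspace(9.5, 10.5, 101)
            heights.append(music_pseudospectrum(split, FS, grid).values.max())
        assert heights[0] < heights[1] < heights[2]

    def test_batch_matches_sequential(self, rng):
        wins = rng.standard_normal((6, 512))
        cfg = SubspaceConfig(L=12, p=2, p_mode="real_sinusoids")
        grid = np.linspace(8, 40, 50)
        batch = music_spectra_batch(wins, FS, cfg, grid)
        for i in range(6):
            split = eigen_split(estimate_autocorrelation(wins[i], 12), cfg)
            seq = music_pseudospectrum(split, FS, grid).values
            np.testing.assert_allclose(batch[i], seq, rtol=1e-8)

    def test_grid_must_be_increasing_and_in_band(self, rng):
        x = _two_tone(rng)
        cfg = SubspaceConfig(L=12, p=2, p_mode="real_sinusoids")
        split = eigen_split(estimate_autocorrelation(x, 12), cfg)
        with pytest.raises(ConfigError):
            music_pseudospectrum(split, FS, np.array([10.0, 5.0, 20.0]))
        with pytest.raises(ConfigError):
            music_pseudospectrum(split, FS, np.array([10.0, 120.0]))


def exact_lags(amps, freqs_hz, n_lags, fs=FS):
    """Closed-form autocorrelation of a sum of random-phase sinusoids."""
    k = np.arange(n_lags)
    return sum((a ** 2 / 2) * np.cos(2 * np.pi * f * k / fs)
               for a, f in zip(amps, freqs_hz))


class TestPisarenko:
    def test_one_by_one_solve(self):
        # cos(w) = 0.8, g(1) = 1.6 -> P = 2.0
        omega = np.arccos(0.8)
        sol = pisarenko_powers([omega], np.array([2.5, 1.6]))
        assert sol.powers[0] == pytest.approx(2.0)

    def test_single_sinusoid_power(self):
        lags = exact_lags([2.0], [10.0], 4)
        sol = pisarenko_powers([2 * np.pi * 10 / FS], lags)
        assert sol.powers[0] == pytest.approx(2.0, abs=1e-6)

    def test_two_sinusoids_recovered(self):
        lags = exact_lags([np.sqrt(2.0), np.sqrt(0.5)], [10.0, 25.0], 5)
        omegas = 2 * np.pi * np.array([10.0, 25.0]) / FS
        sol = pisarenko_powers(omegas, lags)
        np.testing.assert_allclose(sol.powers, [1.0, 0.25], atol=1e-6)
        # oracle: brute-force Gaussian elimination on the same system
        k = np.arange(1, 3)
        a = np.cos(np.outer(k, omegas))
        brute = np.linalg.inv(a) @ lags[1:3]
        np.testing.assert_allclose(sol.powers, brute, atol=1e-10)

    def test_four_tones_machine_precision(self):
        freqs = [10.0, 22.0, 35.0, 48.0]
        amps = [2.0, 1.5, 1.0, 0.5]
        lags = exact_lags(amps, freqs, 6)
        omegas = 2 * np.pi * np.asarray(freqs) / FS
        sol = pisarenko_powers(omegas, lags)
        np.testing.assert_allclose(sol.powers, np.square(amps) / 2, atol=1e-9)
        assert sol.residual < 1e-9

    def test_duplicate_frequencies_rejected(self):
        with pytest.raises(DataError, match="distinct"):
            pisarenko_powers([0.5, 0.5], np.arange(4.0))

    def test_near_degenerate_system_flagged(self):
        omegas = [0.5, 0.5 + 1e-13]
        with pytest.raises(NumericalError, match="cond"):
            pisarenko_powers(omegas, np.arange(4.0))


class TestWelch:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(100_000)
        freqs, psd = welch_psd(x, FS, segment_length=1024)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(1.0, abs=0.05)

    def test_tone_peak_at_nearest_bin(self):
        x = np.sin(2 * np.pi * 10 * np.arange(8192) / FS)
        freqs, psd = welch_psd(x, FS, segment_length=1024)
        assert abs(freqs[np.argmax(psd)] - 10.0) <= freqs[1] - freqs[0]

    def test_zero_signal(self):
        _, psd = welch_psd(np.zeros(4096), FS, segment_length=512)
        np.testing.assert_array_equal(psd, 0.0)

    def test_bad_overlap_rejected(self):
        with pytest.raises(ConfigError):
            welch_psd(np.zeros(4096), FS, 512, overlap_fraction=1.0)

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(DataError):
            welch_psd(np.zeros(100), FS, segment_length=512)


class TestResolutionAdvantage:
    def test_music_beats_welch_bin_width(self):
        # RMSE of MUSIC two-tone peak frequencies over seeded replicates
        # stays below the Welch bin width at the same record length
        n, seg = 2000, 1000
        bin_width = FS / seg  # 0.2 Hz
        errs = []
        cfg = SubspaceConfig(L=20, p=2, p_mode="real_sinusoids")
        grid = np.linspace(5.0, 45.0, 801)
        for seed in range(50):
            x = _two_tone(np.random.default_rng(seed), n=n)
            split = eigen_split(estimate_autocorrelation(x, 20), cfg)
            top2 = np.sort(music_pseudospectrum(split, FS, grid).top_frequencies(2))
            errs.append((top2[0] - 10.0) ** 2 + (top2[1] - 20.0) ** 2)
        rmse = np.sqrt(np.mean(errs) / 2)
        assert rmse < bin_width
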