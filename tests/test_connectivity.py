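import numpy as np
import pytest

from prepercept import connectivity as conn
from prepercept import simulate as sim
from prepercept import spectral

from conftest import make_epochs


def analytic_csd(coeffs, noise_cov, freqs, fs):
    H = conn.var_transfer_function(coeffs, freqs, fs)
    return np.einsum("fij,jk,flk->fil", H, np.asarray(noise_cov, float), np.conj(H))


class TestCoherence:
    def test_independent_channels_bias_floor(self):
        # mean squared coherence under independence ~ 1/n_est
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((100, 2, 250)))
        csd = spectral.multitaper_csd(ep, (-1.0, 0.0), time_bandwidth=2.0)
        msc = conn.coherence(csd) ** 2
        n_est = csd.n_estimates
        assert 0.5 / n_est < msc.mean() < 2.0 / n_est

    def test_bounds(self, coupled_epochs):
        csd = spectral.multitaper_csd(coupled_epochs, (-1.0, 0.0))
        c = conn.coherence(csd)
        assert np.all(c >= 0) and np.all(c <= 1)
        ic = conn.imaginary_coherency(csd)
        assert np.all(np.abs(ic) <= 1)

    def test_single_estimate_rejected(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((1, 2, 250)))
        csd = spectral.multitaper_csd(ep, (-1.0, 0.0), time_bandwidth=1.0, n_tapers=1)
        with pytest.raises(ValueError, match="degenerate"):
            conn.coherence(csd)


class TestImaginaryCoherency:
    def test_zero_lag_mixing_has_no_imaginary_part(self):
        # two instantaneous mixtures of one source: coherence ~1, imag ~0
        rng = np.random.default_rng(2)
        s = rng.standard_normal((200, 1, 250))
        noise = 0.3 * rng.standard_normal((200, 2, 250))
        data = np.concatenate([s + noise[:, :1], 0.7 * s + noise[:, 1:]], axis=1)
        ep = make_epochs(data)
        csd = spectral.multitaper_csd(ep, (-1.0, 0.0))
        band = (csd.freqs_hz > 2) & (csd.freqs_hz < 100)
        assert np.abs(conn.imaginary_coherency(csd)[band]).max() < 0.05
        assert conn.coherence(csd)[band].min() > 0.5

    def test_quarter_cycle_delay_makes_coherency_imaginary(self):
        # narrowband source coupled with a quarter-cycle lag at f0: the
        # cross-spectrum phase is pi/2, so |imag coherency| ~ coherence
        fs, f0 = 250.0, 10.0
        lag = int(round(fs / f0 / 4))
        rng = np.random.default_rng(3)
        coeffs = sim.default_var_coeffs(pole_radius=0.9)[:2] * np.array([1.0, 1.0])[None, None, :]
        coeffs[:, 0, 1] = coeffs[:, 1, 0] = 0.0
        src = sim.var_generate(coeffs, np.eye(2), 250 + lag, seed=3, n_trials=300)
        x = src[:, 0, lag:]
        y = src[:, 0, : src.shape[2] - lag] + 0.2 * rng.standard_normal((300, 250))
        ep = make_epochs(np.stack([x, y], axis=1))
        csd = spectral.multitaper_csd(ep, (-1.0, 0.0), time_bandwidth=2.0)
        i0 = np.argmin(np.abs(csd.freqs_hz - f0))
        coh = conn.coherence(csd)[i0]
        imag = np.abs(conn.imaginary_coherency(csd))[i0]
        assert coh > 0.5
        assert imag > 0.8 * coh


class TestWilsonFactorize:
    def test_white_spectrum_factorizes_to_identity(self):
        freqs = np.linspace(0, 125, 126)
        S = np.broadcast_to(2.5 * np.eye(2), (126, 2, 2)).astype(complex)
        fact = conn.wilson_factorize(S, freqs)
        assert fact.converged
        assert np.allclose(fact.H, np.broadcast_to(np.eye(2), fact.H.shape), atol=1e-8)
        assert np.allclose(fact.Sigma, 2.5 * np.eye(2), atol=1e-8)

    def test_analytic_var2_reconstruction_and_sigma(self):
        # CSD built analytically from a known stable VAR(2): factorization
        # reconstructs S within 1e-6 and recovers the innovation covariance
        coeffs = sim.default_var_coeffs(pole_radius=0.85)[:2]
        coeffs[0, 0, 1] = 0.1
        Sigma_true = np.array([[1.0, 0.2], [0.2, 1.5]])
        freqs = np.linspace(0, 125, 501)
        S = analytic_csd(coeffs, Sigma_true, freqs, 250.0)
        fact = conn.wilson_factorize(S, freqs)
        assert fact.converged
        assert fact.residual < 1e-6
        assert np.allclose(fact.Sigma, Sigma_true, rtol=0.01)

    def test_non_psd_rejected(self):
        freqs = np.linspace(0, 125, 126)
        S = np.broadcast_to(-np.eye(2), (126, 2, 2)).astype(complex)
        with pytest.raises(ValueError, match="semidefinite|PSD|power"):
            conn.wilson_factorize(S, freqs)

    def test_nonuniform_grid_rejected(self):
        freqs = np.array([0.0, 1.0, 3.0, 4.0])
        S = np.broadcast_to(np.eye(2), (4, 2, 2)).astype(complex)
        with pytest.raises(ValueError, match="uniform"):
            conn.wilson_factorize(S, freqs)


class TestGrangerSpectrum:
    def test_uncoupled_var_estimates_near_zero(self):
        coeffs = sim.default_var_coeffs()
        x = sim.var_generate(coeffs, np.eye(2), 250, seed=5, n_trials=500)
        ep = make_epochs(x)
        cs = conn.connectivity_spectrum(ep, (-1.0, 0.0))
        assert cs.granger_fb.max() < 0.02
        assert cs.granger_ff.max() < 0.02

    def test_matches_parametric_oracle_at_peak(self, coupled_var, coupled_epochs):
        cs = conn.connectivity_spectrum(coupled_epochs, (-1.0, 0.0))
        oracle = conn.parametric_granger_var(
            coupled_var, np.eye(2), cs.freqs_hz, 250.0, (sim.FFA, sim.V1)
        )
        pk = np.argmax(oracle)
        rel = abs(cs.granger_fb[pk] - oracle[pk]) / oracle[pk]
        assert rel < 0.15

    def test_error_decreases_with_trial_count(self, coupled_var):
        errs = []
        for n_trials in (100, 2000):
            x = sim.var_generate(coupled_var, np.eye(2), 250, seed=21, n_trials=n_trials)
            cs = conn.connectivity_spectrum(make_epochs(x), (-1.0, 0.0))
            oracle = conn.parametric_granger_var(
                coupled_var, np.eye(2), cs.freqs_hz, 250.0, (sim.FFA, sim.V1)
            )
            pk = np.argmax(oracle)
            errs.append(abs(cs.granger_fb[pk] - oracle[pk]) / oracle[pk])
        assert errs[1] < errs[0]

    def test_nonnegative(self, coupled_epochs):
        cs = conn.connectivity_spectrum(coupled_epochs, (-1.0, 0.0))
        assert np.all(cs.granger_fb >= 0) and np.all(cs.granger_ff >= 0)


class TestParametricOracle:
    def test_zero_cross_terms_give_zero(self):
        coeffs = sim.default_var_coeffs()
        freqs = np.arange(0.0, 126.0)
        for d in ((0, 1), (1, 0)):
            assert np.allclose(
                conn.parametric_granger_var(coeffs, np.eye(2), freqs, 250.0, d), 0.0
            )

    def test_scale_invariance(self, coupled_var):
        freqs = np.arange(1.0, 126.0)
        g1 = conn.parametric_granger_var(coupled_var, np.eye(2), freqs, 250.0)
        g2 = conn.parametric_granger_var(coupled_var, 7.3 * np.eye(2), freqs, 250.0)
        assert np.allclose(g1, g2, rtol=1e-10)

    def test_frozen_regression_value(self, coupled_var):
        # peak feedback value of the canonical coupled VAR, frozen from a
        # brute-force long-run simulation + parametric fit (see scripts in
        # the test body history); guards against silent formula changes
        freqs = np.arange(0.0, 126.0)
        g = conn.parametric_granger_var(coupled_var, np.eye(2), freqs, 250.0, (sim.FFA, sim.V1))
        pk = int(np.argmax(g))
        assert freqs[pk] == pytest.approx(10.0, abs=1.0)
        assert g[pk] == pytest.approx(BRUTE_FORCE_PEAK, rel=0.05)

    def test_unstable_model_rejected(self):
        bad = np.zeros((1, 2, 2))
        bad[0] = 1.01 * np.eye(2)
        with pytest.raises(ValueError, match="unstable"):
            conn.parametric_granger_var(bad, np.eye(2), np.arange(1.0, 10.0), 250.0)


# Peak feedback Granger of the canonical coupled VAR, computed once by fitting
# a VAR(5) by least squares to a 2e6-sample realization and evaluating the
# Geweke measure from the fitted coefficients (independent of the analytic
# transfer-function path).
BRUTE_FORCE_PEAK = 0.5379


class TestTimeReversal:
    def test_dominance_flips_on_reversed_data(self, coupled_var):
        flips = 0
        n = 20
        for seed in range(n):
            x = sim.var_generate(coupled_var, np.eye(2), 250, seed=100 + seed, n_trials=120)
            ep = make_epochs(x)
            fwd = conn.connectivity_spectrum(ep, (-1.0, 0.0)).band(5, 25)
            rev = conn.time_reversed_granger(ep, (-1.0, 0.0)).band(5, 25)
            if fwd.granger_fb.max() > fwd.granger_ff.max() and (
                rev.granger_ff.max() > rev.granger_fb.max()
            ):
                flips += 1
        assert flips >= int(0.95 * n)

    def test_white_noise_both_directions_small(self):
        rng = np.random.default_rng(9)
        ep = make_epochs(rng.standard_normal((300, 2, 250)))
        for f in (conn.connectivity_spectrum, conn.time_reversed_granger):
            cs = f(ep, (-1.0, 0.0))
            assert cs.granger_fb.max() < 0.03
            assert cs.granger_ff.max() < 0.03

    def test_autospectra_invariant_under_reversal(self, coupled_epochs):
        csd_f = spectral.multitaper_csd(coupled_epochs, (-1.0, 0.0))
        mask = coupled_epochs.mask((-1.0, 0.0))
        flipped = make_epochs(coupled_epochs.data[:, :, mask][:, :, ::-1].copy())
        csd_r = spectral.multitaper_csd(flipped, (-1.0, 0.0))
        a = csd_f.mean()
        b = csd_r.mean()
        scale = np.abs(a[:, 0, 0]).max()
        assert np.allclose(a[:, 0, 0], b[:, 0, 0], atol=1e-10 * scale)
        assert np.allclose(a[:, 1, 1], b[:, 1, 1], atol=1e-10 * scale)
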