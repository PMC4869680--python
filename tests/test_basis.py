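"""Gamma response function, derivative, fitting, locking, input reconstruction."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from hpr.basis import (
    CANONICAL_PARAMS,
    BasisFunction,
    GammaParams,
    derivative_rf,
    fit_rf,
    gamma_rf,
    load_fixture,
    lock_to_us,
    make_basis_set,
    reconstruct_input,
)
from hpr.exceptions import IllPosedError, InvalidParamsError


def curve_properties(samples, fs):
    """(mode, peak, FWHM) of a sampled unimodal curve."""
    i = int(np.argmax(samples))
    peak = samples[i]
    above = np.flatnonzero(samples >= peak / 2)
    return i / fs, peak, (above[-1] - above[0]) / fs


class TestGammaRf:
    @pytest.mark.parametrize("name", sorted(CANONICAL_PARAMS))
    def test_argmax_at_closed_form_mode(self, name):
        p = CANONICAL_PARAMS[name]
        fs = 100.0
        bf = gamma_rf(p, fs=fs, duration=11.0)
        assert bf.times[np.argmax(bf.samples)] == pytest.approx(p.mode, abs=1.0 / fs)

    def test_peak_normalized_to_one(self, canonical):
        assert np.max(np.abs(canonical.samples)) == pytest.approx(1.0)
        assert canonical.norm > 0

    def test_density_integrates_to_amplitude(self):
        p = GammaParams(k=40.0, theta=0.15, x0=-1.0, A=3.0)
        bf = gamma_rf(p, fs=100.0, duration=11.0, normalize=False)
        assert np.trapezoid(bf.samples, bf.times) == pytest.approx(p.A, rel=1e-3)

    def test_large_k_approaches_gaussian(self):
        # gamma skewness 2/sqrt(k) -> 0; compare shape against the normal
        # with the same mode and SD
        p = GammaParams(k=4000.0, theta=1.4 / np.sqrt(4000), x0=5.0 - 3999 * 1.4 / np.sqrt(4000))
        bf = gamma_rf(p, fs=10.0, duration=11.0)
        sd = np.sqrt(p.k) * p.theta
        gauss = np.exp(-0.5 * ((bf.times - p.mode) / sd) ** 2)
        assert np.max(np.abs(bf.samples - gauss)) < 0.02

    def test_mode_outside_window_rejected(self):
        with pytest.raises(InvalidParamsError):
            gamma_rf(GammaParams(k=200.0, theta=0.1, x0=0.0), fs=10.0, duration=11.0)

    def test_degenerate_parameterizations_share_one_shape(self):
        """Wildly different (k, theta, x0) rows produce near-identical
        curves; shapes, not parameters, are comparable."""
        a = gamma_rf(CANONICAL_PARAMS["dataset1"], fs=10.0)
        b = gamma_rf(CANONICAL_PARAMS["dataset1_optimized"], fs=10.0)
        assert np.max(np.abs(a.samples - b.samples)) < 0.10  # 10% of peak


class TestDerivativeRf:
    def test_zero_crossing_at_canonical_mode(self, canonical):
        d = derivative_rf(canonical)
        p = canonical.params
        i = int(round(p.mode * canonical.fs))
        signs = np.sign(d.samples)
        crossings = np.flatnonzero(np.diff(signs[signs != 0].astype(int)) != 0)
        idx_nonzero = np.flatnonzero(signs != 0)
        cross_time = idx_nonzero[crossings[0] + 1] / canonical.fs
        assert abs(cross_time - p.mode) <= 1.0 / canonical.fs + 1e-9

    def test_first_order_shift_reconstruction(self, canonical):
        """canonical(t - dt) ~ canonical(t) - dt * canonical'(t)."""
        p = canonical.params
        fs = canonical.fs
        d = derivative_rf(canonical)
        dt = 0.1
        shifted = gamma_rf(GammaParams(p.k, p.theta, p.x0 + dt), fs=fs, normalize=False).samples
        approx = canonical.samples * canonical.norm - dt * d.samples * d.norm
        resid = np.linalg.norm(shifted - approx)
        assert resid < 0.05 * np.linalg.norm(shifted)

    def test_integrates_to_zero(self, canonical):
        d = derivative_rf(canonical)
        un_normalized = d.samples * d.norm
        # support is inside the window, so the integral telescopes to ~0
        assert abs(np.trapezoid(un_normalized, d.times)) < 1e-3 * np.max(np.abs(un_normalized))


class TestBasisSets:
    def test_model_composition(self):
        assert make_basis_set("G1").kinds == ("canonical",)
        assert make_basis_set("G2").kinds == ("canonical", "derivative")
        assert make_basis_set("G3").kinds == ("canonical", "derivative", "early")
        assert make_basis_set("S1").kinds == ("cs_minus_baseline", "canonical")

    def test_fixture_components_loadable_and_normalized(self):
        for kind in ("early", "cs_minus_baseline", "brief_stimulus"):
            bf = load_fixture(kind)
            assert bf.samples.size == 110
            assert np.max(np.abs(bf.samples)) == pytest.approx(1.0, abs=1e-6)


class TestLockToUs:
    def test_reference_soa_is_identity(self):
        bset = make_basis_set("G2")
        locked = lock_to_us(bset, trial_soa=3.5)
        assert locked.lock == "us" and locked.us_shift == 0.0
        for a, b in zip(bset.functions, locked.functions):
            assert np.allclose(a.samples, b.samples)

    def test_half_second_shift_on_grid(self):
        bset = make_basis_set("G2", fs=10.0)
        locked = lock_to_us(bset, trial_soa=4.0)
        for orig, shifted in zip(bset.functions, locked.functions):
            assert np.allclose(shifted.samples[5:], orig.samples[:-5], atol=1e-12)
            assert np.allclose(shifted.samples[:5], 0.0)


class TestFitRf:
    def test_noiseless_self_consistency(self):
        truth = GammaParams(k=40.0, theta=0.20, x0=-3.2, A=30.0)
        fs = 10.0
        y = gamma_rf(truth, fs=fs, normalize=False).samples
        fit = fit_rf(y, fs=fs)
        fitted = fit.params.A * gamma_dist.pdf(
            np.arange(110) / fs, fit.params.k, loc=fit.params.x0, scale=fit.params.theta
        )
        m_t, p_t, w_t = curve_properties(y, fs)
        m_f, p_f, w_f = curve_properties(fitted, fs)
        assert fit.rss <= fit.grid_rss
        assert abs(m_f - m_t) <= 1e-3 + 1.0 / fs * 0  # same grid cell
        assert p_f == pytest.approx(p_t, rel=1e-3)
        assert w_f == pytest.approx(w_t, rel=1e-3)

    def test_mode_recovery_under_noise(self):
        """Median peak-latency error over 100 noisy replicates within 0.2 s."""
        truth = GammaParams(k=48.5, theta=0.182, x0=-3.86, A=25.0)
        fs = 10.0
        clean = gamma_rf(truth, fs=fs, normalize=False).samples
        sigma = 0.1 * np.max(np.abs(clean))
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(100):
            fit = fit_rf(clean + rng.normal(0, sigma, clean.size), fs=fs)
            errs.append(abs(fit.params.mode - truth.mode))
        assert np.median(errs) <= 0.2

    def test_all_zero_waveform_degenerate(self):
        fit = fit_rf(np.zeros(110), fs=10.0)
        assert fit.degenerate and fit.params.A == 0.0


class TestReconstructInput:
    def test_self_consistency_known_gaussian(self):
        prior = load_fixture("brief_stimulus")
        fs = prior.fs
        x = prior.times
        mu, sigma, gain = 3.8, 0.8, 5.0
        g = gain * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        observed = np.convolve(g, prior.samples)[: x.size] / fs
        est = reconstruct_input(
            BasisFunction(samples=observed, kind="canonical", fs=fs), prior
        )
        assert est.mu == pytest.approx(mu, rel=1e-3)
        assert est.sigma == pytest.approx(sigma, rel=1e-3)
        assert est.gain == pytest.approx(gain, rel=1e-3)

    def test_delta_prior_returns_the_gaussian_itself(self):
        fs = 10.0
        x = np.arange(110) / fs
        delta = np.zeros(110)
        delta[0] = fs  # unit-area discrete delta
        prior = BasisFunction(samples=delta, kind="canonical", fs=fs)
        g = 3.0 * np.exp(-0.5 * ((x - 4.2) / 0.9) ** 2)
        est = reconstruct_input(BasisFunction(samples=g, kind="canonical", fs=fs), prior)
        assert est.mu == pytest.approx(4.2, abs=1e-3)
        assert est.sigma == pytest.approx(0.9, abs=1e-3)

    def test_mu_nonnegative_constraint(self):
        prior = load_fixture("brief_stimulus")
        # observed response starting immediately: optimum would sit at mu <= 0
        observed = BasisFunction(samples=prior.samples.copy(), kind="canonical", fs=prior.fs)
        est = reconstruct_input(observed, prior)
        assert est.mu >= 0.0

    def test_zero_prior_ill_posed(self):
        fs = 10.0
        zero = BasisFunction(samples=np.zeros(110), kind="canonical", fs=fs)
        obs = BasisFunction(samples=np.ones(110), kind="canonical", fs=fs)
        with pytest.raises(IllPosedError):
            reconstruct_input(obs, zero)
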