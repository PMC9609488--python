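import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from fibergen.distributions import (
    GammaParams,
    HistogramDensity,
    SamplingDomain,
    TruncatedLognormalParams,
    VMFParams,
    VPKernel,
    VPParams,
    gamma_params_from_moments,
    lognormal_params_from_moments,
    sample_gamma_rejection,
    sample_rejection,
    sample_uniform_sphere,
    sample_vmf,
    sample_vp,
    vp_pdf_2d,
)


class TestGammaMoments:
    @pytest.mark.parametrize(
        "mean,std,k,theta",
        [(2.0, 1.0, 4.0, 0.5), (1.0, 1.0, 1.0, 1.0), (10.0, 2.0, 25.0, 0.4)],
    )
    def test_moment_matching(self, mean, std, k, theta):
        p = gamma_params_from_moments(mean, std)
        assert p.k_shape == pytest.approx(k)
        assert p.theta_scale == pytest.approx(theta)

    @given(mean=st.floats(0.1, 50), std=st.floats(0.05, 10))
    @settings(max_examples=50, deadline=None)
    def test_implied_moments_roundtrip(self, mean, std):
        p = gamma_params_from_moments(mean, std)
        assert p.mean == pytest.approx(mean, rel=1e-12)
        assert p.std == pytest.approx(std, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gamma_params_from_moments(-1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_params_from_moments(1.0, 0.0)

    def test_monte_carlo_moment_recovery(self, rng):
        p = gamma_params_from_moments(2.0, 1.0)
        n = 100_000
        x = sample_gamma_rejection(p, n, rng)
        se_mean = p.std / math.sqrt(n)
        assert abs(x.mean() - 2.0) < 3 * se_mean
        # std of the sample std ~ std/sqrt(2n) for near-normal; gamma k=4 is
        # skewed so allow a generous factor
        assert abs(x.std(ddof=1) - 1.0) < 6 * 1.0 / math.sqrt(2 * n)


class TestLognormalMoments:
    def test_degenerate_distribution(self):
        p = lognormal_params_from_moments(1.7, 0.0)
        assert p.m_ln == pytest.approx(math.log(1.7))
        assert p.s_ln == 0.0

    def test_against_independent_evaluation(self):
        # m = ln(mu^2 / sqrt(sigma^2 + mu^2)), s = sqrt(ln(1 + sigma^2/mu^2))
        # evaluated independently for mu=2, sigma=1
        p = lognormal_params_from_moments(2.0, 1.0)
        assert p.m_ln == pytest.approx(0.5815754049, abs=1e-9)
        assert p.s_ln == pytest.approx(0.4723807271, abs=1e-9)

    def test_untruncated_moments_match(self):
        p = lognormal_params_from_moments(2.0, 0.5)
        mean = math.exp(p.m_ln + p.s_ln**2 / 2)
        var = (math.exp(p.s_ln**2) - 1) * mean**2
        assert mean == pytest.approx(2.0, rel=1e-12)
        assert math.sqrt(var) == pytest.approx(0.5, rel=1e-12)

    def test_samples_respect_truncation(self, rng):
        p = lognormal_params_from_moments(1.3, 0.4)
        domain = SamplingDomain(1.0, 1.3 + 6 * 0.4)
        x = sample_rejection(p.pdf, domain, 5000, rng)
        assert np.all(x >= 1.0)

    def test_mean_below_one_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(0.9, 0.1)


class TestRejectionSampling:
    def test_uniform_density_mean(self, rng):
        n = 100_000
        x = sample_rejection(lambda v: np.ones_like(v), SamplingDomain(0, 1), n, rng)
        assert abs(x.mean() - 0.5) < 3 * (1 / math.sqrt(12 * n))

    def test_single_bin_histogram_is_point_mass(self, rng):
        hist = HistogramDensity([0.5, 1.5, 2.5], [0.0, 1.0, 0.0])
        x = sample_rejection(hist, hist.domain, 2000, rng)
        # nonzero density only on (0.5, 2.5) triangle peaked at 1.5
        assert np.all((x > 0.5) & (x < 2.5))

    def test_gamma_target_mean(self, rng):
        p = GammaParams(4.0, 0.5)
        x = sample_gamma_rejection(p, 50_000, rng)
        assert abs(x.mean() - 2.0) < 3 * p.std / math.sqrt(50_000)

    def test_agrees_with_direct_gamma_sampler(self, rng):
        p = GammaParams(4.0, 0.5)
        ours = sample_gamma_rejection(p, 100_000, rng)
        direct = stats.gamma(a=4.0, scale=0.5).rvs(size=100_000, random_state=7)
        ks = stats.ks_2samp(ours, direct)
        assert ks.pvalue > 0.001

    def test_zero_mass_target_raises(self, rng):
        with pytest.raises(ValueError):
            sample_rejection(lambda v: np.zeros_like(v), SamplingDomain(0, 1), 10, rng)

    def test_unbounded_target_raises(self, rng):
        with np.errstate(divide="ignore"), pytest.raises(ValueError):
            sample_rejection(lambda v: 1.0 / np.asarray(v), SamplingDomain(0, 1), 10, rng)

    def test_seeded_determinism(self):
        a = sample_rejection(lambda v: np.ones_like(v), SamplingDomain(0, 1), 100,
                             np.random.default_rng(3))
        b = sample_rejection(lambda v: np.ones_like(v), SamplingDomain(0, 1), 100,
                             np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestVPSampling:
    def test_isotropic_limit(self, rng):
        v = sample_vp(VPParams((VPKernel([0, 0, 1], 0.0),)), 100_000, rng)
        assert np.linalg.norm(v.mean(axis=0)) < 0.02

    def test_second_moment_matches_quadrature(self, rng):
        k = 6.0
        v = sample_vp(VPParams((VPKernel([0, 0, 1], k),)), 100_000, rng)
        m2 = np.mean(v[:, 2] ** 2)
        expected = quad(lambda u: u**2 * (2 * k + 1) / 2 * u ** (2 * k), -1, 1)[0]
        assert m2 == pytest.approx(expected, abs=0.005)

    def test_eigenvector_aligns_with_mean_axis(self, rng):
        axis = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        v = sample_vp(VPParams((VPKernel(axis, 6.0),)), 100_000, rng)
        tensor = v.T @ v / v.shape[0]
        w, vec = np.linalg.eigh(tensor)
        principal = vec[:, -1]
        angle = math.degrees(math.acos(min(abs(float(principal @ axis)), 1.0)))
        assert angle < 2.0

    def test_antipodal_symmetry(self, rng):
        v = sample_vp(VPParams((VPKernel([0, 0, 1], 4.0),)), 50_000, rng)
        # distribution of z and -z components indistinguishable
        ks = stats.ks_2samp(v[:, 2], -v[:, 2])
        assert ks.pvalue > 0.001

    def test_unit_norm_and_determinism(self):
        params = VPParams((VPKernel([0, 1, 0], 2.0), VPKernel([1, 0, 0], 5.0)))
        a = sample_vp(params, 1000, np.random.default_rng(9))
        b = sample_vp(params, 1000, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)


class TestVMFSampling:
    def test_uniform_limit(self, rng):
        v = sample_vmf(VMFParams([0, 0, 1], 0.0), 100_000, rng)
        assert np.linalg.norm(v.mean(axis=0)) < 0.02

    def test_high_concentration_cone(self, rng):
        v = sample_vmf(VMFParams([0, 0, 1], 300.0), 10_000, rng)
        angles = np.degrees(np.arccos(np.clip(v[:, 2], -1, 1)))
        assert np.max(angles) < 15.0

    def test_mean_cosine_matches_closed_form(self, rng):
        kappa = 5.0
        n = 100_000
        v = sample_vmf(VMFParams([0, 0, 1], kappa), n, rng)
        expected = 1.0 / math.tanh(kappa) - 1.0 / kappa
        sd = math.sqrt(max(1 - expected**2, 1e-6))  # loose bound on the spread
        assert abs(v[:, 2].mean() - expected) < 4 * sd / math.sqrt(n)

    def test_rotation_to_arbitrary_mean(self, rng):
        mean = np.array([1.0, -2.0, 0.5])
        v = sample_vmf(VMFParams(mean, 50.0), 20_000, rng)
        mdir = mean / np.linalg.norm(mean)
        assert float(v.mean(axis=0) @ mdir) > 0.95

    def test_determinism(self):
        a = sample_vmf(VMFParams([0, 0, 1], 2.0), 500, np.random.default_rng(4))
        b = sample_vmf(VMFParams([0, 0, 1], 2.0), 500, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)


class TestVpPdf2D:
    def test_isotropic_constant(self):
        theta = np.linspace(0, math.pi, 50, endpoint=False)
        np.testing.assert_allclose(vp_pdf_2d(theta, [(0.3, 0.0)]), 1 / math.pi)

    @pytest.mark.parametrize("k2d", [1.0, 5.0, 15.0])
    def test_normalization(self, k2d):
        val, _ = quad(lambda t: float(vp_pdf_2d(t, [(1.0, k2d)])), 0, math.pi)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mixture_normalization(self):
        kernels = [(0.5, 2.0), (2.0, 7.0), (2.8, 0.5)]
        val, _ = quad(lambda t: float(vp_pdf_2d(t, kernels)), 0, math.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_kernel_angle(self):
        theta = np.linspace(0, math.pi, 721, endpoint=False)
        dens = vp_pdf_2d(theta, [(1.0, 5.0)])
        assert theta[np.argmax(dens)] == pytest.approx(1.0, abs=0.01)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            vp_pdf_2d(0.5, [(0.0, -1.0)])


class TestDomainAndTypes:
    def test_domain_from_moments_six_sigma(self):
        d = SamplingDomain.from_moments(10.0, 1.0)
        assert d.lower == pytest.approx(4.0)
        assert d.upper == pytest.approx(16.0)

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            SamplingDomain(1.0, 1.0)

    def test_kernel_normalizes_axis(self):
        k = VPKernel([0.0, 0.0, 2.0], 1.0)
        np.testing.assert_allclose(k.mean_axis, [0, 0, 1])

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            VPKernel([0, 0, 1], -1.0)
        with pytest.raises(ValueError):
            VMFParams([0, 0, 1], -0.1)
        with pytest.raises(ValueError):
            TruncatedLognormalParams(0.0, -1.0)
        with pytest.raises(ValueError):
            VPParams(())
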