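"""Multipath-time moments, dispersion densities and the pencil scatter field."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

import fiberlight as fl
from fiberlight.grids import depth_axis, extents_for, log_tau_axis
from fiberlight.pencil import (SIGMA_MU_RATIO_LUTOMIRSKI, SIGMA_MU_RATIO_VDH,
                               moments, pencil_scatter_field,
                               scatter_integrand, spatial_angular_h,
                               time_dispersion_G)

TISSUES = [fl.TissueOptics(),
           fl.TissueOptics(n=1.4, mu_a=1e-4, mu_s=0.01, g=0.9)]


def _optics(tissue):
    return fl.derive_optics(tissue, fl.FiberSpec())


class TestMoments:
    @pytest.mark.parametrize("tissue", TISSUES)
    def test_constant_sigma_mu_ratios(self, tissue):
        z = np.array([1.0, 50.0, 700.0])
        opt = _optics(tissue)
        p = moments(z, "table1_Lutomirski", tissue, opt)
        np.testing.assert_allclose(p.sigma_tau / p.mu_tau,
                                   math.sqrt(2 / 3), rtol=1e-12)
        p = moments(z, "table1_vandeHulst", tissue, opt)
        np.testing.assert_allclose(p.sigma_tau / p.mu_tau,
                                   math.sqrt(1.4), rtol=1e-12)
        assert SIGMA_MU_RATIO_LUTOMIRSKI == pytest.approx(0.816497, abs=1e-6)
        assert SIGMA_MU_RATIO_VDH == pytest.approx(1.183216, abs=1e-6)

    def test_exact_first_moment_at_700um(self):
        # x = μs z v ≈ 2.06758 → μτ c / z = 1 − (1 − e^−x)/x ≈ 0.57755
        tissue = fl.TissueOptics()
        opt = _optics(tissue)
        p = moments(np.array([700.0]), "eq4", tissue, opt)
        assert float(p.mu_tau[0]) * opt.c / 700 == pytest.approx(0.57755,
                                                                 abs=2e-5)

    @pytest.mark.parametrize("tissue", TISSUES)
    def test_exact_moment_meets_quadratic_approximation_at_small_depth(
            self, tissue):
        opt = _optics(tissue)
        z = np.array([1e-3 / (tissue.mu_s * opt.v)])  # μs z v = 1e-3
        mu_exact = moments(z, "eq4", tissue, opt).mu_tau[0]
        mu_approx = moments(z, "table1_Lutomirski", tissue, opt).mu_tau[0]
        assert abs(mu_exact / mu_approx - 1) < 1e-3

    def test_moments_positive_and_vanishing_at_origin(self):
        tissue = fl.TissueOptics()
        opt = _optics(tissue)
        z = np.geomspace(1e-6, 700, 50)
        for mode in ("eq4", "table1_Lutomirski", "table1_vandeHulst"):
            p = moments(z, mode, tissue, opt)
            assert np.all(p.mu_tau > 0) and np.all(p.sigma_tau > 0)
            assert p.mu_tau[0] < 1e-12  # → 0 as z → 0

    def test_precise_sigma_requires_cos2_mean(self):
        tissue = fl.TissueOptics()
        with pytest.raises(fl.ConfigError, match="cos2_mean"):
            moments(np.array([100.0]), "eq4_precise_sigma", tissue,
                    _optics(tissue))

    def test_precise_sigma_with_cos2_mean_is_positive(self):
        tissue = fl.TissueOptics(cos2_mean=0.76)
        p = moments(np.array([10.0, 700.0]), "eq4_precise_sigma", tissue,
                    _optics(tissue))
        assert np.all(p.sigma_tau > 0)

    def test_nonpositive_depth_rejected(self):
        tissue = fl.TissueOptics()
        with pytest.raises(fl.ConfigError):
            moments(np.array([0.0]), "eq4", tissue, _optics(tissue))


class TestTimeDispersionG:
    def test_unit_shape_reduces_to_exponential(self):
        tau = np.linspace(0.1, 500, 64)
        mu = 80.0
        np.testing.assert_allclose(time_dispersion_G(tau, mu, mu),
                                   np.exp(-tau / mu) / mu, rtol=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(50.0, 40.0), (200.0, 163.3),
                                          (1000.0, 10.0)])
    def test_normalization_mean_variance(self, mu, sigma):
        # integrate over a window wide enough for any shape; an infinite
        # upper limit can miss a very narrow spike entirely
        hi = mu + 40 * sigma
        pts = [max(mu - 5 * sigma, 0.0), mu, mu + 5 * sigma]
        kw = dict(limit=400, points=pts)
        norm, _ = integrate.quad(lambda t: time_dispersion_G(t, mu, sigma),
                                 0, hi, **kw)
        assert norm == pytest.approx(1.0, abs=1e-9)
        mean, _ = integrate.quad(lambda t: t * time_dispersion_G(t, mu, sigma),
                                 0, hi, **kw)
        assert mean == pytest.approx(mu, rel=1e-9)
        var, _ = integrate.quad(
            lambda t: (t - mu) ** 2 * time_dispersion_G(t, mu, sigma),
            0, hi, **kw)
        assert var == pytest.approx(sigma**2, rel=1e-8)

    def test_matches_scipy_gamma_pdf(self):
        tau = np.geomspace(1, 1000, 32)
        mu, sigma = 120.0, 98.0
        k = (mu / sigma) ** 2
        np.testing.assert_allclose(
            time_dispersion_G(tau, mu, sigma),
            stats.gamma.pdf(tau, a=k, scale=sigma**2 / mu), rtol=1e-10)

    def test_large_shape_does_not_overflow(self):
        # shape k = 1e6: log-space evaluation must stay finite
        val = time_dispersion_G(np.array([100.0]), 100.0, 0.1)
        assert np.isfinite(val).all() and val[0] > 0

    def test_nonpositive_moments_rejected(self):
        with pytest.raises(ValueError):
            time_dispersion_G(np.array([1.0]), 0.0, 1.0)


class TestSpatialAngularH:
    def test_on_axis_value_and_decay_point(self):
        tau, z, c = 200.0, 300.0, 0.22
        on_axis = 3 / (4 * math.pi * tau * c * z)
        assert spatial_angular_h(tau, 0.0, z, c) == pytest.approx(on_axis)
        rho_e = math.sqrt(4 * tau * c * z / 3)
        assert spatial_angular_h(tau, rho_e, z, c) == pytest.approx(
            on_axis / math.e)

    def test_transverse_normalization(self):
        tau, z, c = 57.0, 410.0, 0.2204
        norm, _ = integrate.quad(
            lambda r: 2 * np.pi * r * spatial_angular_h(tau, r, z, c),
            0, np.inf, limit=200)
        assert norm == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("a", [0.1, 2.0, 17.0])
    def test_depends_on_tau_z_product_only(self, a):
        tau, rho, z, c = 120.0, 40.0, 500.0, 0.22
        assert spatial_angular_h(a * tau, rho, z / a, c) == pytest.approx(
            spatial_angular_h(tau, rho, z, c), rel=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            spatial_angular_h(-1.0, 0.0, 10.0, 0.22)
        with pytest.raises(ValueError):
            spatial_angular_h(1.0, 0.0, 0.0, 0.22)


class TestScatterIntegrand:
    def test_factorization_at_known_values(self):
        # μs z = ln 2 → scattered fraction 1/2;  μa = 0 → absorption 1
        tissue = fl.TissueOptics(mu_a=0.0, mu_s=0.01)
        opt = _optics(tissue)
        z = math.log(2) / tissue.mu_s
        mu, sigma = 100.0, 80.0
        tau = np.array([150.0])
        val = scatter_integrand(tau, 0.0, z, tissue, opt, mu, sigma)
        expected = 0.5 * time_dispersion_G(tau, mu, sigma) \
            * spatial_angular_h(tau, 0.0, z, opt.c)
        np.testing.assert_allclose(val, expected, rtol=1e-12)

    def test_strictly_decreasing_in_rho(self):
        tissue = fl.TissueOptics()
        opt = _optics(tissue)
        rho = np.linspace(0, 300, 40)
        vals = scatter_integrand(np.array([200.0]), rho, 350.0, tissue, opt,
                                 150.0, 120.0)
        assert np.all(np.diff(vals) < 0)


class TestPencilScatterField:
    def test_field_nonnegative_finite_and_decreasing_in_rho(self, small_config):
        cfg = small_config
        ext = extents_for(cfg)
        z = depth_axis(cfg.z_start, ext.pencil_z_max, cfg.grid.dz)
        f = pencil_scatter_field(cfg.tissue, cfg.derived(), cfg.sampling,
                                 ext.pencil_rho_max, z)
        assert np.all(np.isfinite(f.values)) and np.all(f.values >= 0)
        # strictly decreasing along ρ wherever the column is significant
        sig = f.values[:, 0] > 1e-12 * f.values.max()
        assert np.all(np.diff(f.values[sig], axis=1) < 0)

    def test_default_tau_sampling_matches_dense_reference(self, tau_report):
        assert tau_report.max_rel_dev < 0.02

    def test_tau_upper_bound_insensitivity(self, small_config):
        """Doubling tau_max barely changes the field: the gamma tail beyond
        10⁴ fs carries negligible mass at these depths.  (The lower bound is
        a genuine model cutoff — at depths where μτ(z) ≪ tau_min the
        residual scattered intensity is set by tau_min itself — so no
        analogous insensitivity holds there.)"""
        cfg = small_config
        ext = extents_for(cfg)
        z = depth_axis(cfg.z_start, ext.pencil_z_max, cfg.grid.dz)
        base = pencil_scatter_field(cfg.tissue, cfg.derived(), cfg.sampling,
                                    ext.pencil_rho_max, z)
        alt = pencil_scatter_field(cfg.tissue, cfg.derived(), cfg.sampling,
                                   ext.pencil_rho_max, z,
                                   tau_axis=log_tau_axis(
                                       5, 20000, cfg.sampling.n_tau_smpls))
        mask = base.values > 1e-12 * base.values.max()
        dev = np.abs(alt.values[mask] - base.values[mask]) / base.values[mask]
        assert dev.max() < 0.005
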