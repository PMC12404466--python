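"""Independent brute-force references for validating the numerics.

Every check here reaches its expected value by a route that shares no code
with the implementation it validates: dense quadratures for the
multipath-time and angular Riemann sums, full-disk enumeration against the
mirrored half-disk shortcut, and closed-form / scipy-based identities for
the density functions and the analytic cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .config import Config, DerivedOptics, TissueOptics
from .cone import angular_convolve_scatter, direct_cone_intensity
from .field import Field2D
from .fiber import DiskOffsets, disk_convolve_scattered, disk_offsets
from .grids import depth_axis, extents_for, log_tau_axis, uniform_radial_axis
from .pencil import (SIGMA_MU_RATIO_LUTOMIRSKI, SIGMA_MU_RATIO_VDH, moments,
                     pencil_scatter_field, spatial_angular_h,
                     time_dispersion_G)

#: nodes below this fraction of the field maximum are excluded from
#: relative-deviation reports (numerically vacuous far-tail values)
SIGNIFICANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class OracleReport:
    """Relative deviations of an implementation against a dense reference."""

    max_rel_dev: float
    n_checked: int
    floor: float
    deviations: np.ndarray | None = None


def _compare(test: np.ndarray, reference: np.ndarray,
             floor: float = SIGNIFICANCE_FLOOR) -> OracleReport:
    mask = reference >= floor * reference.max()
    dev = np.abs(test[mask] - reference[mask]) / reference[mask]
    return OracleReport(max_rel_dev=float(dev.max()), n_checked=int(mask.sum()),
                        floor=floor, deviations=dev)


def dense_tau_oracle(config: Config, n_dense: int) -> OracleReport:
    """Pencil field with the configured τ sampling vs an ``n_dense``-node
    reference quadrature on the same log axis."""
    if n_dense < 10 * config.sampling.n_tau_smpls:
        raise ValueError("dense reference must use >= 10x the default τ nodes")
    tissue, optics, sampling = config.tissue, config.derived(), config.sampling
    ext = extents_for(config)
    z = depth_axis(config.z_start, ext.pencil_z_max, config.grid.dz)
    test = pencil_scatter_field(tissue, optics, sampling, ext.pencil_rho_max, z)
    tau_dense = log_tau_axis(sampling.tau_min, sampling.tau_max, n_dense)
    ref = pencil_scatter_field(tissue, optics, sampling, ext.pencil_rho_max, z,
                               tau_axis=tau_dense)
    return _compare(test.values, ref.values)


def dense_angular_oracle(config: Config, factor: int) -> OracleReport:
    """Angular convolution at the configured resolution vs ``factor``× finer
    sampling of both angles, on the same cone grid."""
    if factor < 2:
        raise ValueError("refinement factor must be >= 2")
    tissue, optics, sampling = config.tissue, config.derived(), config.sampling
    ext = extents_for(config)
    pz = depth_axis(config.z_start, ext.pencil_z_max, config.grid.dz)
    pencil = pencil_scatter_field(tissue, optics, sampling, ext.pencil_rho_max, pz)
    cone_rho = uniform_radial_axis(ext.cone_rho_max, config.grid.dxy)
    cone_z = depth_axis(config.z_start, config.grid.zmax, config.grid.dz)
    test = angular_convolve_scatter(pencil, optics, sampling.nsteps_theta,
                                    sampling.nsteps_phi, cone_rho, cone_z)
    ref = angular_convolve_scatter(pencil, optics,
                                   factor * sampling.nsteps_theta,
                                   factor * sampling.nsteps_phi,
                                   cone_rho, cone_z)
    return _compare(test.values, ref.values)


def full_disk_offsets(radius: float, step: float) -> DiskOffsets:
    """Full-plane disk lattice (both half-planes enumerated, nothing
    doubled) — the reference for the mirrored half-disk shortcut."""
    if radius < 0 or step <= 0:
        raise ValueError("need radius >= 0 and step > 0")
    half = step / 2.0
    if radius < math.hypot(half, half):
        return DiskOffsets(points=np.zeros((1, 2)), weight=step * step,
                           doubled=np.zeros(1, dtype=bool))
    n = int(np.floor(radius / step)) + 1
    coords = (np.arange(-n, n) + 0.5) * step
    X, Y = np.meshgrid(coords, coords)
    inside = X**2 + Y**2 <= radius * radius
    pts = np.column_stack([X[inside], Y[inside]])
    return DiskOffsets(points=pts, weight=step * step,
                       doubled=np.zeros(len(pts), dtype=bool))


def half_disk_symmetry_report(cone_scattered: Field2D, rho_out: np.ndarray,
                              z_out: np.ndarray, fiber, step: float) -> OracleReport:
    """Mirrored half-disk convolution vs full-disk enumeration."""
    test = disk_convolve_scattered(cone_scattered, rho_out, z_out, fiber, step)
    ref = disk_convolve_scattered(cone_scattered, rho_out, z_out, fiber, step,
                                  offsets=full_disk_offsets(fiber.radius, step))
    return _compare(test.values, ref.values, floor=0.0)


# ---------------------------------------------------------------------------
# analytic identities

def cap_power_integral(r: float, tissue: TissueOptics,
                       optics: DerivedOptics) -> float:
    """Direct-cone intensity integrated over the spherical cap at distance r
    (numerical quadrature); equals exp(−(μa+μs)·r) if power is conserved."""
    def integrand(theta: float) -> float:
        return float(direct_cone_intensity(r * math.sin(theta),
                                           r * math.cos(theta),
                                           tissue, optics)) * math.sin(theta)
    val, _ = integrate.quad(integrand, 0.0, optics.theta_div, epsabs=1e-12)
    return 2.0 * math.pi * r * r * val


def analytic_identity_suite(tissue: TissueOptics,
                            optics: DerivedOptics) -> dict[str, dict]:
    """Run all closed-form identity checks; returns per-identity results.

    Each entry carries the measured deviation, the tolerance it is held to,
    and a pass flag.  Checks: gamma-density normalization/mean/variance and
    agreement with scipy's gamma pdf; transverse normalization of the
    spread kernel; the small-depth limit where the exact first moment meets
    its quadratic approximation; the two constant στ/μτ ratios; and power
    conservation of the analytic direct cone over its spherical cap.
    """
    results: dict[str, dict] = {}

    def record(name: str, deviation: float, tol: float) -> None:
        results[name] = {"deviation": float(deviation), "tol": tol,
                         "passed": bool(deviation < tol)}

    # multipath-time density: moments at a representative depth
    prof = moments(np.array([300.0]), "eq4", tissue, optics)
    mu, sig = float(prof.mu_tau[0]), float(prof.sigma_tau[0])
    norm, _ = integrate.quad(lambda t: time_dispersion_G(t, mu, sig),
                             0, np.inf, limit=200)
    record("G_normalization", abs(norm - 1.0), 1e-3)
    mean, _ = integrate.quad(lambda t: t * time_dispersion_G(t, mu, sig),
                             0, np.inf, limit=200)
    record("G_mean", abs(mean / mu - 1.0), 1e-6)
    second, _ = integrate.quad(lambda t: t * t * time_dispersion_G(t, mu, sig),
                               0, np.inf, limit=200)
    record("G_variance", abs((second - mean**2) / sig**2 - 1.0), 1e-6)
    tgrid = np.linspace(0.5 * mu, 3 * mu, 64)
    scipy_pdf = stats.gamma.pdf(tgrid, a=(mu / sig) ** 2,
                                scale=sig**2 / mu)
    record("G_matches_scipy_gamma",
           np.max(np.abs(time_dispersion_G(tgrid, mu, sig) - scipy_pdf))
           / scipy_pdf.max(), 1e-12)

    # transverse kernel normalization at an arbitrary (τ, z)
    tau0, z0 = 200.0, 400.0
    hnorm, _ = integrate.quad(
        lambda r: 2 * np.pi * r * spatial_angular_h(tau0, r, z0, optics.c),
        0, np.inf, limit=200)
    record("h_normalization", abs(hnorm - 1.0), 1e-6)

    # exact first moment meets the quadratic approximation at small depth
    z_small = np.array([1e-3 / (tissue.mu_s * optics.v)])
    mu_exact = moments(z_small, "eq4", tissue, optics).mu_tau
    mu_approx = moments(z_small, "table1_Lutomirski", tissue, optics).mu_tau
    record("small_depth_limit", abs(float(mu_exact[0] / mu_approx[0]) - 1.0), 1e-3)

    # constant moment ratios
    zz = np.array([10.0, 100.0, 700.0])
    p_lut = moments(zz, "table1_Lutomirski", tissue, optics)
    record("sigma_mu_ratio_lutomirski",
           np.max(np.abs(p_lut.sigma_tau / p_lut.mu_tau
                         - SIGMA_MU_RATIO_LUTOMIRSKI)), 1e-12)
    p_vdh = moments(zz, "table1_vandeHulst", tissue, optics)
    record("sigma_mu_ratio_vandehulst",
           np.max(np.abs(p_vdh.sigma_tau / p_vdh.mu_tau
                         - SIGMA_MU_RATIO_VDH)), 1e-12)

    # direct cone conserves power through every spherical cap
    mu_t = tissue.mu_a + tissue.mu_s
    dev = max(abs(cap_power_integral(r, tissue, optics)
                  / math.exp(-mu_t * r) - 1.0)
              for r in (50.0, 300.0, 700.0))
    record("cap_power_conservation", dev, 1e-9)

    return results
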