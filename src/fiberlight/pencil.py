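"""Scattered-photon field of an infinitesimal pencil beam.

An idealized pencil beam launches photons from a point along +z through a
homogeneous scattering medium.  The ballistic (direct) part survives with
probability exp(−(μa+μs)z) and stays on-axis; it is never gridded here — it
enters the pipeline only through the analytic cone expression.  The
scattered part is described by a beam-spread function: at depth z, a photon
observed at radial offset ρ carries a multipath time τ (its travel-time
excess over the ballistic path), distributed as a gamma density G(τ; z)
whose first and second moments μτ(z), στ(z) follow from small-angle
scattering theory.  Given τ, the transverse spread is the Gaussian kernel

    h(τ, ρ, z) = 3 / (4π τ c z) · exp(−3ρ² / (4 τ c z)),

normalized over the transverse plane.  The time-resolved intensity is

    i(τ, ρ, z) = (1 − e^(−μs z)) · e^(−μa (z + cτ)) · G(τ, z) · h(τ, ρ, z)

and the stationary field is its integral over τ, evaluated here by a
composite Simpson rule on logarithmically spaced time samples.

Four parametrizations of (μτ, στ) are selectable; see :func:`moments`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.special import gammaln

from .config import ConfigError, DerivedOptics, ScatterSamplingSpec, TissueOptics
from .field import Field2D
from .grids import log_tau_axis, shifted_log_radial_axis

#: constant στ/μτ ratio from the small-angle moment approximations of
#: Lutomirski et al. with ⟨θ⁴⟩ = 0:  (√(1/24)) / (1/4) = √(2/3)
SIGMA_MU_RATIO_LUTOMIRSKI = np.sqrt(2.0 / 3.0)
#: constant στ/μτ ratio from the van de Hulst & Kattawar approximations:
#: 12·√(7/720) = √1.4
SIGMA_MU_RATIO_VDH = np.sqrt(1.4)


@dataclass(frozen=True)
class MomentsProfile:
    """First and second moments of multipath time per depth sample."""

    z: np.ndarray
    mu_tau: np.ndarray
    sigma_tau: np.ndarray
    mode: str


def _mu_tau_precise(z: np.ndarray, tissue: TissueOptics,
                    optics: DerivedOptics) -> np.ndarray:
    """Exact small-angle first moment:  μτ c / z = 1 − (1 − e^(−x))/x with
    x = μs z v.  Series fallback below x = 1e−6 avoids cancellation."""
    x = tissue.mu_s * z * optics.v
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = -np.expm1(-x) / x
    small = x < 1e-6
    out = np.where(small, x / 2.0 - x * x / 6.0, 1.0 - frac)
    return (z / optics.c) * out


def _sigma_tau_precise(z: np.ndarray, tissue: TissueOptics,
                       optics: DerivedOptics) -> np.ndarray:
    """Exact small-angle second central moment; needs w = (3/2)(1−⟨cos²θ⟩)."""
    if optics.w is None:
        raise ConfigError(
            "mu_tau mode 'eq4_precise_sigma' requires the parameter "
            "'cos2_mean' (the mean squared cosine of the scattering angle)")
    v, w = optics.v, optics.w
    if abs(w - v) < 1e-12:
        raise ConfigError("degenerate moments: w == v; the exact second-moment "
                          "expression is singular for this tissue")
    s = tissue.mu_s * z
    A = np.expm1(-s * v) + s * v
    B = np.expm1(-s * w) + s * w
    num = (2.0 / 3.0) * ((w * w - 3.0 * w * v) * A + 2.0 * v * v * B)
    den = s * s * w * v * v * (w - v)
    frac = -np.expm1(-s * v) / (s * v)
    var = (z / optics.c) ** 2 * (num / den - frac * frac)
    if np.any(var <= 0):
        raise ConfigError(
            "non-positive multipath-time variance from 'eq4_precise_sigma'; "
            "check cos2_mean against the anisotropy factor")
    return np.sqrt(var)


def moments(z: np.ndarray, mode: str, tissue: TissueOptics,
            optics: DerivedOptics) -> MomentsProfile:
    """Multipath-time moments μτ(z), στ(z) under the chosen parametrization.

    Modes
    -----
    ``eq4`` (default)
        μτ from the exact small-angle expression; στ = μτ·√(2/3), the
        constant ratio implied by the Lutomirski approximations.  Best match
        to experimental transmission profiles.
    ``table1_Lutomirski``
        μτ = (z/c)·(1/4)·μs z·⟨θ²⟩ and στ = μτ·√(2/3) (the ⟨θ⁴⟩ term of the
        second-moment approximation is dropped under the small-angle
        assumption).  Closest to the original closed-source model.
    ``table1_vandeHulst``
        μτ = (z/c)·(1/12)·μs z·⟨θ²⟩ and στ = μτ·√1.4.
    ``eq4_precise_sigma``
        μτ exact and στ from the exact second-moment expression; requires
        the user-supplied ⟨cos²θ⟩ (no defensible default exists).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ConfigError("moment profiles are defined for depths z > 0 only")
    t2 = optics.theta2_mean
    if mode == "eq4":
        mu = _mu_tau_precise(z, tissue, optics)
        sigma = mu * SIGMA_MU_RATIO_LUTOMIRSKI
    elif mode == "table1_Lutomirski":
        mu = (z / optics.c) * 0.25 * tissue.mu_s * z * t2
        sigma = mu * SIGMA_MU_RATIO_LUTOMIRSKI
    elif mode == "table1_vandeHulst":
        mu = (z / optics.c) * (1.0 / 12.0) * tissue.mu_s * z * t2
        sigma = mu * SIGMA_MU_RATIO_VDH
    elif mode == "eq4_precise_sigma":
        mu = _mu_tau_precise(z, tissue, optics)
        sigma = _sigma_tau_precise(z, tissue, optics)
    else:
        raise ConfigError(f"unknown mu_tau mode {mode!r}")
    return MomentsProfile(z=z, mu_tau=mu, sigma_tau=sigma, mode=mode)


def time_dispersion_G(tau: np.ndarray, mu_tau: float,
                      sigma_tau: float) -> np.ndarray:
    """Gamma density of multipath time with mean μτ and st.dev. στ (1/fs).

    Shape k = μτ²/στ², rate λ = μτ/στ²; evaluated through its logarithm so
    large shape parameters cannot overflow.
    """
    mu_tau = np.asarray(mu_tau, float)
    sigma_tau = np.asarray(sigma_tau, float)
    if np.any(mu_tau <= 0) or np.any(sigma_tau <= 0):
        raise ValueError("G requires positive moments mu_tau, sigma_tau")
    tau = np.asarray(tau, dtype=float)
    k = (mu_tau / sigma_tau) ** 2
    rate = mu_tau / sigma_tau**2
    with np.errstate(divide="ignore"):
        logG = (k * np.log(rate) + (k - 1.0) * np.log(tau)
                - rate * tau - gammaln(k))
    return np.exp(logG)


def spatial_angular_h(tau: np.ndarray, rho: np.ndarray, z: np.ndarray,
                      c: float) -> np.ndarray:
    """Transverse Gaussian spread kernel (1/μm²), normalized so that
    ∫ h · 2πρ dρ = 1 at every (τ, z)."""
    tau = np.asarray(tau, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(tau <= 0) or np.any(z <= 0):
        raise ValueError("h requires tau > 0 and z > 0")
    s = tau * c * z
    return 3.0 / (4.0 * np.pi * s) * np.exp(-3.0 * np.asarray(rho, float) ** 2
                                            / (4.0 * s))


def scatter_integrand(tau: np.ndarray, rho: np.ndarray, z: float,
                      tissue: TissueOptics, optics: DerivedOptics,
                      mu_tau: float, sigma_tau: float) -> np.ndarray:
    """Time-resolved scattered intensity of the pencil beam at depth z.

    Product of the scattered fraction 1 − e^(−μs z), the absorption survival
    e^(−μa (z + cτ)) along the lengthened path, the multipath-time density G
    and the transverse kernel h.
    """
    frac_scattered = -np.expm1(-tissue.mu_s * z)
    absorption = np.exp(-tissue.mu_a * (z + optics.c * tau))
    G = time_dispersion_G(tau, mu_tau, sigma_tau)
    h = spatial_angular_h(tau, rho, z, optics.c)
    return frac_scattered * absorption * G * h


def pencil_scatter_field(tissue: TissueOptics, optics: DerivedOptics,
                         sampling: ScatterSamplingSpec,
                         rho_max: float, z_axis: np.ndarray,
                         tau_axis: np.ndarray | None = None) -> Field2D:
    """Integrate the time-resolved pencil field over multipath time.

    The radial axis is the shifted-log axis on [0, rho_max]; the τ integral
    runs over ``tau_axis`` (default: the log axis from ``sampling``) with a
    composite Simpson rule, which handles the unequal log spacing and
    resolves the sharply peaked integrand at shallow depths, where the
    multipath-time density is narrow relative to the node spacing.
    """
    rho = shifted_log_radial_axis(sampling.rho_exp_min, sampling.n_rho_smpls,
                                  rho_max)
    if tau_axis is None:
        tau_axis = log_tau_axis(sampling.tau_min, sampling.tau_max,
                                sampling.n_tau_smpls)
    z_axis = np.asarray(z_axis, dtype=float)
    prof = moments(z_axis, sampling.mu_tau_mode, tissue, optics)

    tau = tau_axis[:, None]                      # (ntau, 1) against z
    G = time_dispersion_G(tau, prof.mu_tau[None, :], prof.sigma_tau[None, :])
    absorption = np.exp(-tissue.mu_a * (z_axis[None, :] + optics.c * tau))
    frac = -np.expm1(-tissue.mu_s * z_axis)       # (nz,)
    # (ntau, nz, nrho) transverse kernel
    h = spatial_angular_h(tau[:, :, None], rho[None, None, :],
                          z_axis[None, :, None], optics.c)
    integrand = (frac[None, :, None] * (absorption * G)[:, :, None]) * h
    values = simpson(integrand, x=tau_axis, axis=0)
    # Simpson weights are strictly positive on a log-spaced axis (adjacent
    # step ratios < 2), so the integral of a non-negative integrand can dip
    # below zero only through roundoff; clamp that.
    np.maximum(values, 0.0, out=values)
    return Field2D(rho_axis=rho, z_axis=z_axis, values=values)
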