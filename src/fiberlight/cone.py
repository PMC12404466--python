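"""Light cone of a point emitter built from pencil beams.

A point on the fiber face emits uniformly into a cone of half-angle
θdiv = arcsin(NA/n).  The cone field is the superposition of pencil beams
tilted over that cone.  For the direct (ballistic) component the angular
convolution has a closed form: inside the cone the intensity at distance r
is the attenuated emission spread over the spherical cap,

    I_direct(ρ, z) = exp(−(μa+μs) r) / (2π (1 − cos θdiv) r²),  r² = ρ² + z².

For the scattered component the convolution over (θ′, φ′) is a midpoint
Riemann sum: each tilted pencil beam is looked up in the precomputed pencil
field at rotated coordinates, weighted by sin θ′ Δθ′ Δφ′ / (2π).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import DerivedOptics, TissueOptics
from .field import Field2D, InterpStats


def direct_cone_intensity(rho, z, tissue: TissueOptics, optics: DerivedOptics,
                          bounded: bool = True) -> np.ndarray:
    """Analytic direct-light intensity of a point emitter (1/μm²).

    Zero outside the geometric cone (``atan2(ρ, z) > θdiv``) when
    ``bounded`` — ballistic photons cannot leave the emission cone; pass
    ``bounded=False`` for the raw unbounded expression.  The apex (0, 0) is
    singular and rejected.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    r2 = rho**2 + z**2
    if np.any(r2 == 0):
        raise ValueError("direct cone intensity is singular at (rho, z) = (0, 0)")
    r = np.sqrt(r2)
    norm = 2.0 * np.pi * (1.0 - np.cos(optics.theta_div))
    out = np.exp(-(tissue.mu_a + tissue.mu_s) * r) / (norm * r2)
    if bounded:
        inside = np.arctan2(rho, z) <= optics.theta_div
        out = np.where(inside, out, 0.0)
    return out


def tilt_coordinates(rho, z, theta_p, phi_p) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the point (ρ, 0, z) in the frame of a pencil beam
    tilted along (sin θ′ cos φ′, sin θ′ sin φ′, cos θ′).

    Returns ``(rho_pencil, z_pencil)`` with ``z_pencil`` the projection onto
    the tilted axis and ``rho_pencil`` the distance from it; the rotation
    preserves ``ρ² + z²``.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    st, ct = np.sin(theta_p), np.cos(theta_p)
    z_pencil = rho * st * np.cos(phi_p) + z * ct
    r2 = rho**2 + z**2
    rho_pencil = np.sqrt(np.maximum(r2 - z_pencil**2, 0.0))
    return rho_pencil, z_pencil


def angular_weights(theta_div: float, nsteps_theta: int,
                    nsteps_phi: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Midpoint angular samples and the per-sample quadrature weight factor.

    Returns ``(theta, phi, dw)`` where the weight of sample (θ, φ) is
    ``sin θ · dw`` with ``dw = Δθ Δφ / (2π)``.  The midpoint rule avoids the
    zero-weight θ′ = 0 sample and double counting at φ′ = 2π; the total
    weight Σ sin θ Δθ Δφ / (2π) converges to 1 − cos θdiv.
    """
    dtheta = theta_div / nsteps_theta
    dphi = 2.0 * np.pi / nsteps_phi
    theta = (np.arange(nsteps_theta) + 0.5) * dtheta
    phi = (np.arange(nsteps_phi) + 0.5) * dphi
    return theta, phi, dtheta * dphi / (2.0 * np.pi)


def angular_convolve_scatter(pencil: Field2D, optics: DerivedOptics,
                             nsteps_theta: int, nsteps_phi: int,
                             cone_rho_axis: np.ndarray,
                             cone_z_axis: np.ndarray,
                             strict: bool = True,
                             stats: InterpStats | None = None) -> Field2D:
    """Riemann-sum angular convolution of the scattered pencil field.

    For every cone-grid node the pencil field is evaluated (bilinearly, on
    its native log-radial grid) at the tilt coordinates of each midpoint
    angular sample and accumulated with weight sin θ′ Δθ′ Δφ′ / (2π).
    Points behind a tilted source plane (z_pencil < 0) contribute nothing.
    In strict mode any query beyond the pencil domain is a hard error —
    extents produced by :func:`fiberlight.grids.expanded_extents` guarantee
    there are none.
    """
    cone_rho_axis = np.asarray(cone_rho_axis, dtype=float)
    cone_z_axis = np.asarray(cone_z_axis, dtype=float)
    RHO, Z = np.meshgrid(cone_rho_axis, cone_z_axis)   # (nz, nrho)
    R2 = RHO**2 + Z**2
    theta, phi, dw = angular_weights(optics.theta_div, nsteps_theta, nsteps_phi)

    acc = np.zeros_like(RHO)
    for th, sth, cth in zip(theta, np.sin(theta), np.cos(theta)):
        # vectorize over phi: (nphi, nz, nrho)
        z_p = RHO[None] * (sth * np.cos(phi))[:, None, None] + Z[None] * cth
        rho_p = np.sqrt(np.maximum(R2[None] - z_p**2, 0.0))
        ahead = z_p > 0
        vals = pencil.interp(np.where(ahead, rho_p, 0.0),
                             np.where(ahead, z_p, pencil.z_axis[0]),
                             strict=strict, stats=stats)
        acc += (sth * dw) * np.where(ahead, vals, 0.0).sum(axis=0)
    return Field2D(rho_axis=cone_rho_axis, z_axis=cone_z_axis, values=acc)


@dataclass
class ConeField:
    """Light cone of a point emitter: analytic direct evaluator plus the
    gridded scattered component."""

    direct: Callable[[np.ndarray, np.ndarray], np.ndarray]
    scattered: Field2D
    theta_div: float
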