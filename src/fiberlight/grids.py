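"""Sample axes and the extent-expansion rules for the precompute volumes.

The scattered pencil beam is steep near its axis and near the source, so its
radial and multipath-time axes are logarithmically spaced; all output axes
are uniform.  Before the spatial convolutions, the pencil-beam and cone
volumes are expanded beyond the requested output volume so that every
interpolation query issued downstream — tilted-beam lookups during the
angular convolution, shifted lookups during the disk convolution — falls
inside the precomputed domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import Config, DerivedOptics, FiberSpec, GridSpec, LegacyTruncation

log = logging.getLogger(__name__)


def shifted_log_radial_axis(rho_exp_min: float, n: int, rho_max: float) -> np.ndarray:
    """Natural-log-spaced radial axis shifted to start at exactly 0.

    ``n`` samples are log-spaced on ``[rho_exp_min, rho_max + rho_exp_min]``
    and the start value is subtracted from the whole interval, so the axis
    runs from exactly 0 to exactly ``rho_max``.
    """
    if not rho_exp_min > 0:
        raise ValueError("rho_exp_min must be > 0")
    if n < 2:
        raise ValueError("need at least 2 radial samples")
    ax = np.exp(np.linspace(math.log(rho_exp_min),
                            math.log(rho_max + rho_exp_min), n)) - rho_exp_min
    ax[0] = 0.0
    ax[-1] = rho_max
    return ax


def log_tau_axis(tau_min: float, tau_max: float, n: int) -> np.ndarray:
    """Natural-log-spaced multipath-time axis with exact endpoints."""
    if not 0 < tau_min < tau_max:
        raise ValueError("need 0 < tau_min < tau_max")
    if n < 2:
        raise ValueError("need at least 2 time samples")
    ax = np.exp(np.linspace(math.log(tau_min), math.log(tau_max), n))
    ax[0] = tau_min
    ax[-1] = tau_max
    return ax


def uniform_radial_axis(rho_max: float, step: float) -> np.ndarray:
    """Uniform radial axis from 0 to ``rho_max`` inclusive."""
    n = round(rho_max / step) + 1
    return np.linspace(0.0, rho_max, n)


def depth_axis(z_start: float, zmax: float, step: float) -> np.ndarray:
    """Uniform depth axis from ``z_start`` to ``zmax`` inclusive.

    The number of samples is chosen so the effective step is as close as
    possible to ``step``; the axis never contains z = 0, where the direct
    cone is singular on-axis.
    """
    if not 0 < z_start <= zmax:
        raise ValueError("need 0 < z_start <= zmax")
    n = max(round((zmax - z_start) / step), 1) + 1
    return np.linspace(z_start, zmax, n)


@dataclass(frozen=True)
class Extents:
    """Precompute extents (μm) for the pencil-beam and cone fields.

    ``legacy`` is True when any extent was overridden downward to reproduce
    the truncation artifact of earlier software.
    """

    cone_rho_max: float
    pencil_rho_max: float
    pencil_z_max: float
    legacy: bool = False


def expanded_extents(grid: GridSpec, fiber: FiberSpec, optics: DerivedOptics,
                     legacy: LegacyTruncation | None = None) -> Extents:
    """Extents large enough that no downstream interpolation leaves its domain.

    The cone field is sampled by the disk convolution at radii up to
    ``xymax + fiber radius``, so its radial extent is at least that.  The
    pencil field is sampled by the angular convolution at tilted coordinates
    originating anywhere on the cone grid; the worst-case projections give

    * radial: ``cone_rho_max · cos θdiv + zmax · sin θdiv``
    * depth:  ``sqrt(cone_rho_max² + zmax²)``

    For a point emitter (radius 0) these reduce to the familiar expansion of
    the output volume itself.  A :class:`LegacyTruncation` clips any of the
    three extents downward, reintroducing — deliberately — the edge/corner
    underestimation of truncated convolution volumes.
    """
    cone_rho_max = grid.xymax + fiber.radius
    pencil_rho_max = (cone_rho_max * math.cos(optics.theta_div)
                      + grid.zmax * math.sin(optics.theta_div))
    pencil_z_max = math.hypot(cone_rho_max, grid.zmax)
    is_legacy = False
    if legacy is not None and legacy.active():
        is_legacy = True
        if legacy.cone_rho_max is not None:
            cone_rho_max = min(cone_rho_max, legacy.cone_rho_max)
        if legacy.pencil_rho_max is not None:
            pencil_rho_max = min(pencil_rho_max, legacy.pencil_rho_max)
        if legacy.pencil_z_max is not None:
            pencil_z_max = min(pencil_z_max, legacy.pencil_z_max)
        log.warning(
            "legacy truncation active: cone_rho_max=%.1f pencil_rho_max=%.1f "
            "pencil_z_max=%.1f — out-of-domain queries will be zero-filled",
            cone_rho_max, pencil_rho_max, pencil_z_max)
    return Extents(cone_rho_max=cone_rho_max, pencil_rho_max=pencil_rho_max,
                   pencil_z_max=pencil_z_max, legacy=is_legacy)


def extents_for(config: Config) -> Extents:
    return expanded_extents(config.grid, config.fiber, config.derived(),
                            config.disk.legacy_truncation)
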