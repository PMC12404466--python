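"""Fiber field assembly: disk convolution of point-emitter cones.

The fiber's flat circular emission surface is covered by a Cartesian lattice
of point emitters; the output field is the Riemann sum of their cone fields.
The direct cone is evaluated analytically at every shifted position (no
interpolation error), the scattered cone by bilinear interpolation of the
gridded cone field, each at its own lattice step.  The lattice is offset by
half a step from both axes, so the half-plane y′ > 0 doubled is an exact
mirror cover of the disk.  Direct and scattered parts are convolved
separately and summed afterwards.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import Config, DerivedOptics, FiberSpec, TissueOptics
from .cone import ConeField, angular_convolve_scatter, direct_cone_intensity
from .field import Field2D, InterpStats
from .grids import Extents, depth_axis, extents_for, uniform_radial_axis
from .pencil import pencil_scatter_field

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiskOffsets:
    """Lattice of emitter offsets covering the fiber face.

    ``points`` is an (n, 2) array of (x′, y′) offsets in μm, ``weight`` the
    area element (step², μm²), ``doubled`` marks offsets counted twice
    (mirror cover of the y′ < 0 half).  ``area`` is the total effective
    area, which converges to π·radius² as the step shrinks.
    """

    points: np.ndarray
    weight: float
    doubled: np.ndarray

    @property
    def area(self) -> float:
        return float(self.weight * np.sum(np.where(self.doubled, 2.0, 1.0)))


def disk_offsets(radius: float, step: float) -> DiskOffsets:
    """Half-plane lattice covering a disk of the given radius.

    Cell centers sit at ((i+½)·step, (j+½)·step), j ≥ 0, and a center is
    kept iff it lies inside the disk (plain Riemann sum, no partial-cell
    weighting).  A disk smaller than the lattice pitch — including
    radius 0, a point emitter — degenerates to the single offset (0, 0),
    not doubled.
    """
    if radius < 0 or step <= 0:
        raise ValueError("need radius >= 0 and step > 0")
    half = step / 2.0
    if radius < np.hypot(half, half):
        return DiskOffsets(points=np.zeros((1, 2)), weight=step * step,
                           doubled=np.zeros(1, dtype=bool))
    n = int(np.floor(radius / step)) + 1
    coords = (np.arange(-n, n) + 0.5) * step
    X, Y = np.meshgrid(coords, coords[coords > 0])
    inside = X**2 + Y**2 <= radius * radius
    pts = np.column_stack([X[inside], Y[inside]])
    return DiskOffsets(points=pts, weight=step * step,
                       doubled=np.ones(len(pts), dtype=bool))


def _offset_radii(rho_out: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """(n_off, n_rho) distances from each offset to the output points
    (ρᵢ, 0); the output map is evaluated on the +x axis, valid for all
    azimuths by symmetry."""
    dx = rho_out[None, :] - offsets[:, 0][:, None]
    return np.sqrt(dx**2 + offsets[:, 1][:, None] ** 2)


def disk_convolve_direct(rho_out: np.ndarray, z_out: np.ndarray,
                         fiber: FiberSpec, tissue: TissueOptics,
                         optics: DerivedOptics, step: float,
                         offsets: DiskOffsets | None = None,
                         chunk: int = 128) -> Field2D:
    """Disk convolution of the analytic direct cone onto the output grid."""
    rho_out = np.asarray(rho_out, dtype=float)
    z_out = np.asarray(z_out, dtype=float)
    if offsets is None:
        offsets = disk_offsets(fiber.radius, step)
    radii = _offset_radii(rho_out, offsets.points)
    mult = np.where(offsets.doubled, 2.0, 1.0) * offsets.weight
    acc = np.zeros((z_out.size, rho_out.size))
    for lo in range(0, len(offsets.points), chunk):
        sl = slice(lo, lo + chunk)
        # (n_chunk, nz, nrho)
        vals = direct_cone_intensity(radii[sl][:, None, :],
                                     z_out[None, :, None], tissue, optics)
        acc += np.einsum("k,kij->ij", mult[sl], vals)
    return Field2D(rho_axis=rho_out, z_axis=z_out, values=acc)


def disk_convolve_scattered(cone_scattered: Field2D, rho_out: np.ndarray,
                            z_out: np.ndarray, fiber: FiberSpec, step: float,
                            offsets: DiskOffsets | None = None,
                            strict: bool = True,
                            stats: InterpStats | None = None,
                            chunk: int = 256) -> Field2D:
    """Disk convolution of the gridded scattered cone onto the output grid.

    Values come from bilinear interpolation of the cone field; in strict
    mode any query beyond its radial extent raises.  The cone field must
    extend radially to at least xymax + fiber radius for the convolution to
    stay in-domain.
    """
    rho_out = np.asarray(rho_out, dtype=float)
    z_out = np.asarray(z_out, dtype=float)
    if offsets is None:
        offsets = disk_offsets(fiber.radius, step)
    radii = _offset_radii(rho_out, offsets.points)
    mult = np.where(offsets.doubled, 2.0, 1.0) * offsets.weight
    acc = np.zeros((z_out.size, rho_out.size))
    for lo in range(0, len(offsets.points), chunk):
        sl = slice(lo, lo + chunk)
        vals = cone_scattered.interp(radii[sl][:, None, :],
                                     z_out[None, :, None],
                                     strict=strict, stats=stats)
        acc += np.einsum("k,kij->ij", mult[sl], vals)
    return Field2D(rho_axis=rho_out, z_axis=z_out, values=acc)


@dataclass
class FiberLightField:
    """Final output: direct, scattered and total intensity on the output
    grid, plus run metadata (configuration echo, extents, counters)."""

    direct: Field2D
    scattered: Field2D
    total: Field2D
    metadata: dict = field(default_factory=dict)

    @property
    def rho_axis(self) -> np.ndarray:
        return self.total.rho_axis

    @property
    def z_axis(self) -> np.ndarray:
        return self.total.z_axis


def build_cone(config: Config, extents: Extents | None = None,
               stats: InterpStats | None = None) -> ConeField:
    """Pencil field plus angular convolution: the cone of one point emitter."""
    tissue, optics, sampling = config.tissue, config.derived(), config.sampling
    if extents is None:
        extents = extents_for(config)
    strict = config.strict

    t0 = time.perf_counter()
    pencil_z = depth_axis(config.z_start, extents.pencil_z_max, config.grid.dz)
    pencil = pencil_scatter_field(tissue, optics, sampling,
                                  extents.pencil_rho_max, pencil_z)
    log.info("pencil scatter field: %d rho x %d z samples (%.2f s)",
             pencil.rho_axis.size, pencil.z_axis.size, time.perf_counter() - t0)

    t0 = time.perf_counter()
    cone_rho = uniform_radial_axis(extents.cone_rho_max, config.grid.dxy)
    cone_z = depth_axis(config.z_start, config.grid.zmax, config.grid.dz)
    scattered = angular_convolve_scatter(
        pencil, optics, sampling.nsteps_theta, sampling.nsteps_phi,
        cone_rho, cone_z, strict=strict, stats=stats)
    log.info("angular convolution: %d x %d cone grid, %d x %d angular steps "
             "(%.2f s)", cone_rho.size, cone_z.size, sampling.nsteps_theta,
             sampling.nsteps_phi, time.perf_counter() - t0)

    def direct(rho, z):
        return direct_cone_intensity(rho, z, tissue, optics)

    return ConeField(direct=direct, scattered=scattered,
                     theta_div=optics.theta_div)


def simulate_fiber(config: Config) -> FiberLightField:
    """Run the full pipeline: moments → pencil scatter field → angular
    convolution → per-component disk convolutions → combined output.

    Deterministic — an identical configuration yields a bit-identical field.
    """
    stats = InterpStats()
    extents = extents_for(config)
    cone = build_cone(config, extents, stats=stats)

    rho_out = uniform_radial_axis(config.grid.xymax, config.grid.dxy)
    z_out = depth_axis(config.z_start, config.grid.zmax, config.grid.dz)
    strict = config.strict

    t0 = time.perf_counter()
    direct = disk_convolve_direct(rho_out, z_out, config.fiber, config.tissue,
                                  config.derived(), config.disk.dxy_direct_disk)
    log.info("direct disk convolution: step %.1f um (%.2f s)",
             config.disk.dxy_direct_disk, time.perf_counter() - t0)

    t0 = time.perf_counter()
    scattered = disk_convolve_scattered(
        cone.scattered, rho_out, z_out, config.fiber,
        config.disk.dxy_scattered_disk, strict=strict, stats=stats)
    log.info("scattered disk convolution: step %.1f um (%.2f s)",
             config.disk.dxy_scattered_disk, time.perf_counter() - t0)

    total = Field2D(rho_axis=rho_out, z_axis=z_out,
                    values=direct.values + scattered.values)
    disk_area = disk_offsets(config.fiber.radius,
                             config.disk.dxy_direct_disk).area
    metadata = {
        "config": config.echo(),
        "version": __version__,
        "strict": strict,
        "extents": {"cone_rho_max": extents.cone_rho_max,
                    "pencil_rho_max": extents.pencil_rho_max,
                    "pencil_z_max": extents.pencil_z_max,
                    "legacy": extents.legacy},
        "disk_area_um2": disk_area,
        "interp_queries": stats.n_queries,
        "interp_out_of_domain": stats.n_out_of_domain,
    }
    return FiberLightField(direct=direct, scattered=scattered, total=total,
                           metadata=metadata)


def radial_profile(fld: Field2D, z: float, normalize: bool = False) -> np.ndarray:
    """Radial intensity profile at the given depth.

    Exact grid depths return the stored row verbatim; other depths are
    linearly interpolated between the neighbouring rows.  With
    ``normalize`` the profile is divided by its on-axis (ρ = 0) value, so
    profile[0] is exactly 1.
    """
    z_axis = fld.z_axis
    if not (z_axis[0] <= z <= z_axis[-1]):
        raise ValueError(f"depth z={z} outside the grid "
                         f"[{z_axis[0]}, {z_axis[-1]}]")
    hits = np.nonzero(z_axis == z)[0]
    if hits.size:
        row = fld.values[hits[0]].copy()
    else:
        i = int(np.searchsorted(z_axis, z)) - 1
        t = (z - z_axis[i]) / (z_axis[i + 1] - z_axis[i])
        row = (1 - t) * fld.values[i] + t * fld.values[i + 1]
    if normalize:
        if row[0] == 0:
            raise ValueError(f"cannot normalize: on-axis value at z={z} is 0")
        row = row / row[0]
        row[0] = 1.0
    return row


def depth_profile(fld: Field2D, rho: float = 0.0) -> np.ndarray:
    """On-axis (or fixed-radius) intensity versus depth."""
    return fld.column(rho)
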