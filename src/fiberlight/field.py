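"""Gridded intensity fields and instrumented bilinear interpolation.

A :class:`Field2D` stores non-negative intensity samples on a (ρ, z) grid.
The radial axis may be non-uniform (the pencil field uses shifted-log
spacing); the depth axis is uniform.  Interpolation is bilinear directly on
the native axes — the near-axis resolution of the log grid is preserved, no
resampling — and every query is counted.  Queries beyond the stored extents
either raise (strict mode, the regression guard against truncated
convolution volumes) or are zero-filled and counted (legacy mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InterpolationDomainError(RuntimeError):
    """An interpolation query fell outside the precomputed field domain."""


@dataclass
class InterpStats:
    """Counters for interpolation queries; shared across pipeline stages."""

    n_queries: int = 0
    n_out_of_domain: int = 0

    def merge(self, other: "InterpStats") -> None:
        self.n_queries += other.n_queries
        self.n_out_of_domain += other.n_out_of_domain


@dataclass
class Field2D:
    """Intensity samples on a (ρ, z) grid.

    values[i, j] is the intensity at (z_axis[i], rho_axis[j]); units are
    per-source-power intensity (1/μm² scale).
    """

    rho_axis: np.ndarray
    z_axis: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.rho_axis = np.asarray(self.rho_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.z_axis.size, self.rho_axis.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.z_axis.size}, {self.rho_axis.size})")
        for name, ax in (("rho_axis", self.rho_axis), ("z_axis", self.z_axis)):
            if ax.ndim != 1 or not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be 1-D and strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if np.any(self.values < 0):
            raise ValueError("field values must be non-negative")

    def interp(self, rho: np.ndarray, z: np.ndarray, *,
               strict: bool = True,
               stats: InterpStats | None = None) -> np.ndarray:
        """Bilinear interpolation at query points (broadcast together).

        Queries below the first depth sample are ramped linearly to zero at
        z = 0 (the scattered field vanishes at the source plane); queries at
        negative z return 0.  Queries beyond ``rho_axis[-1]`` or
        ``z_axis[-1]`` raise :class:`InterpolationDomainError` when
        ``strict``, otherwise return 0; both outcomes are counted in
        ``stats``.
        """
        rho, z = np.broadcast_arrays(np.asarray(rho, float), np.asarray(z, float))
        out_of_domain = (rho > self.rho_axis[-1]) | (z > self.z_axis[-1])
        n_ood = int(np.count_nonzero(out_of_domain))
        if stats is not None:
            stats.n_queries += rho.size
            stats.n_out_of_domain += n_ood
        if n_ood and strict:
            bad_rho = rho[out_of_domain].flat[0]
            bad_z = z[out_of_domain].flat[0]
            raise InterpolationDomainError(
                f"{n_ood} interpolation quer{'y' if n_ood == 1 else 'ies'} "
                f"outside the precomputed domain "
                f"(first: rho={bad_rho:.2f}, z={bad_z:.2f}; domain "
                f"rho<={self.rho_axis[-1]:.2f}, z<={self.z_axis[-1]:.2f}). "
                f"Expand the precompute extents or enable legacy truncation.")

        rho_c = np.clip(rho, self.rho_axis[0], self.rho_axis[-1])
        z_c = np.clip(z, self.z_axis[0], self.z_axis[-1])

        j = np.clip(np.searchsorted(self.rho_axis, rho_c, side="right") - 1,
                    0, self.rho_axis.size - 2)
        i = np.clip(np.searchsorted(self.z_axis, z_c, side="right") - 1,
                    0, self.z_axis.size - 2)
        drho = self.rho_axis[j + 1] - self.rho_axis[j]
        dz = self.z_axis[i + 1] - self.z_axis[i]
        tr = (rho_c - self.rho_axis[j]) / drho
        tz = (z_c - self.z_axis[i]) / dz

        v = ((1 - tr) * (1 - tz) * self.values[i, j]
             + tr * (1 - tz) * self.values[i, j + 1]
             + (1 - tr) * tz * self.values[i + 1, j]
             + tr * tz * self.values[i + 1, j + 1])

        # below the first depth sample: ramp to zero at the source plane
        below = z < self.z_axis[0]
        if np.any(below):
            ramp = np.clip(z / self.z_axis[0], 0.0, 1.0)
            v = np.where(below, v * ramp, v)
        if n_ood:
            v = np.where(out_of_domain, 0.0, v)
        return v

    def column(self, rho: float = 0.0) -> np.ndarray:
        """Depth profile at fixed radius (nearest radial sample)."""
        j = int(np.argmin(np.abs(self.rho_axis - rho)))
        return self.values[:, j]
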