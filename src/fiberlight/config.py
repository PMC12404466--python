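"""Configuration, validation and derived optical quantities.

All lengths are micrometres, all times femtoseconds; intensities are per
unit source power.  A run is fully described by five parameter blocks:
tissue optics, fiber geometry, the output grid, the sampling controls for
the scattered pencil beam, and the disk-convolution step sizes.  Parameters
are read from a YAML file whose keys mirror the shipped ``defaults.yml``;
keys that are absent fall back to the defaults, unknown keys are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

SPEED_OF_LIGHT_VACUUM = 0.299792458  # μm / fs

#: recognised parametrizations of the multipath-time moments
MU_TAU_MODES = ("eq4", "table1_Lutomirski", "table1_vandeHulst", "eq4_precise_sigma")


class ConfigError(ValueError):
    """A configuration value violates an invariant, or a key is unknown."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for '{key}': {msg}")


@dataclass(frozen=True)
class TissueOptics:
    """Optical coefficients and scattering anisotropy of the (homogeneous) medium.

    Parameters
    ----------
    n : refractive index (dimensionless, ≥ 1)
    mu_a : absorption coefficient (1/μm)
    mu_s : scattering coefficient (1/μm)
    g : anisotropy factor ⟨cos θ⟩ of the single-scattering phase function
    cos2_mean : optional ⟨cos² θ⟩, needed only by the ``eq4_precise_sigma``
        moment parametrization
    """

    n: float = 1.36
    mu_a: float = 0.00006
    mu_s: float = 0.0211
    g: float = 0.86
    cos2_mean: float | None = None

    def __post_init__(self) -> None:
        _require(self.n >= 1, "ntissue", f"refractive index must be >= 1, got {self.n}")
        _require(self.mu_a >= 0, "mu_a", f"must be >= 0, got {self.mu_a}")
        _require(self.mu_s > 0, "mu_s", f"must be > 0, got {self.mu_s}")
        _require(-1 < self.g < 1, "g", f"anisotropy must lie in (-1, 1), got {self.g}")
        if self.cos2_mean is not None:
            _require(0 <= self.cos2_mean <= 1, "cos2_mean",
                     f"must lie in [0, 1], got {self.cos2_mean}")


@dataclass(frozen=True)
class FiberSpec:
    """Fiber numerical aperture and emission-surface radius (μm)."""

    NA: float = 0.37
    radius: float = 100.0

    def __post_init__(self) -> None:
        _require(self.NA > 0, "NA", f"must be > 0, got {self.NA}")
        _require(self.radius >= 0, "opt_radius", f"must be >= 0, got {self.radius}")


@dataclass(frozen=True)
class GridSpec:
    """Output-grid extents and steps (μm)."""

    xymax: float = 700.0
    dxy: float = 5.0
    zmax: float = 700.0
    dz: float = 5.0

    def __post_init__(self) -> None:
        for key in ("xymax", "dxy", "zmax", "dz"):
            _require(getattr(self, key) > 0, key, "must be > 0")
        _require(self.dxy <= self.xymax, "dxy", "step exceeds lateral extent")
        _require(self.dz <= self.zmax, "dz", "step exceeds depth extent")

    def plane_area_mm2(self) -> float:
        """Area of the simulated ρ–z plane in mm²."""
        return self.xymax * self.zmax * 1e-6

    def octant_volume_mm3(self) -> float:
        """Volume of the positive-octant box (xymax × xymax × zmax) the plane
        represents under rotational symmetry, in mm³."""
        return self.xymax * self.xymax * self.zmax * 1e-9


@dataclass(frozen=True)
class ScatterSamplingSpec:
    """Sampling controls for the scattered pencil-beam computation.

    ``rho_exp_min``/``n_rho_smpls`` parametrize the shifted-log radial axis,
    ``tau_*``/``n_tau_smpls`` the logarithmic multipath-time axis, ``mu_tau_mode``
    selects the moment parametrization, and the ``nsteps_*`` set the angular
    resolution of the cone convolution.
    """

    rho_exp_min: float = 1.0
    n_rho_smpls: int = 20
    tau_min: float = 5.0
    tau_max: float = 10000.0
    n_tau_smpls: int = 100
    mu_tau_mode: str = "eq4"
    nsteps_theta: int = 24
    nsteps_phi: int = 24

    def __post_init__(self) -> None:
        _require(self.rho_exp_min > 0, "rho_exp_min", "must be > 0")
        _require(self.n_rho_smpls >= 2, "n_rho_smpls", "need at least 2 samples")
        _require(0 < self.tau_min < self.tau_max, "tau_min",
                 "need 0 < tau_min < tau_max")
        _require(self.n_tau_smpls >= 2, "n_tau_smpls", "need at least 2 samples")
        _require(self.nsteps_theta >= 1, "nsteps_theta", "must be >= 1")
        _require(self.nsteps_phi >= 1, "nsteps_phi", "must be >= 1")
        _require(self.mu_tau_mode in MU_TAU_MODES, "mu_tau",
                 f"unknown mode {self.mu_tau_mode!r}; choose one of {MU_TAU_MODES}")


@dataclass(frozen=True)
class LegacyTruncation:
    """Optional override of the auto-expanded precompute extents (μm).

    Reproduces the boundary artifact of truncated spatial convolutions: with
    any of these limits active, interpolation queries outside the precomputed
    volume are zero-filled (and counted) instead of raising.
    """

    cone_rho_max: float | None = None
    pencil_rho_max: float | None = None
    pencil_z_max: float | None = None

    def active(self) -> bool:
        return any(v is not None for v in
                   (self.cone_rho_max, self.pencil_rho_max, self.pencil_z_max))


@dataclass(frozen=True)
class DiskConvSpec:
    """Step sizes (μm) of the disk convolutions; finer for the sharply peaked
    direct component, coarser for the smooth scattered component."""

    dxy_direct_disk: float = 3.0
    dxy_scattered_disk: float = 10.0
    legacy_truncation: LegacyTruncation | None = None

    def __post_init__(self) -> None:
        _require(self.dxy_direct_disk > 0, "dxy_direct_disk", "must be > 0")
        _require(self.dxy_scattered_disk > 0, "dxy_scattered_disk", "must be > 0")


@dataclass(frozen=True)
class DerivedOptics:
    """Quantities computed once per run from tissue and fiber parameters.

    c : in-medium speed of light (μm/fs), ``c0 / n``
    theta_div : divergence half-angle of the cone (rad), ``arcsin(NA / n)``
    v : ``1 − g``
    theta2_mean : mean squared scattering angle ``⟨θ²⟩ = 2(1 − g)``
        (small-angle relation)
    w : ``(3/2)(1 − ⟨cos²θ⟩)`` if ⟨cos²θ⟩ was supplied, else None
    """

    c: float
    theta_div: float
    v: float
    theta2_mean: float
    w: float | None = None


def derive_optics(tissue: TissueOptics, fiber: FiberSpec,
                  c0: float = SPEED_OF_LIGHT_VACUUM) -> DerivedOptics:
    """Compute the per-run derived optical quantities.

    Raises
    ------
    ConfigError
        If ``NA >= n`` (the in-tissue divergence angle would be undefined).
    """
    if fiber.NA >= tissue.n:
        raise ConfigError(
            f"invalid value for 'NA': must be < refractive index "
            f"({tissue.n}), got {fiber.NA}")
    w = None
    if tissue.cos2_mean is not None:
        w = 1.5 * (1.0 - tissue.cos2_mean)
    return DerivedOptics(
        c=c0 / tissue.n,
        theta_div=math.asin(fiber.NA / tissue.n),
        v=1.0 - tissue.g,
        theta2_mean=2.0 * (1.0 - tissue.g),
        w=w,
    )


# ---------------------------------------------------------------------------
# YAML front end

#: keys accepted in a parameter file, in the order they are echoed
_KNOWN_KEYS = (
    "c_0", "ntissue", "mu_a", "mu_s", "g", "cos2_mean",
    "NA", "opt_radius",
    "xymax", "dxy", "zmax", "dz", "z_start",
    "rho_exp_min", "n_rho_smpls", "tau_min", "tau_max", "n_tau_smpls",
    "mu_tau", "nsteps_theta", "nsteps_phi",
    "dxy_direct_disk", "dxy_scattered_disk", "legacy_truncation",
)

_LEGACY_KEYS = ("cone_rho_max", "pencil_rho_max", "pencil_z_max")


@dataclass(frozen=True)
class Config:
    """The complete, validated configuration of one simulation run."""

    c0: float
    tissue: TissueOptics
    fiber: FiberSpec
    grid: GridSpec
    sampling: ScatterSamplingSpec
    disk: DiskConvSpec
    z_start: float = 1.0

    @property
    def strict(self) -> bool:
        """True when no legacy truncation is active: interpolation outside the
        precomputed volume is then a hard error rather than a zero fill."""
        lt = self.disk.legacy_truncation
        return lt is None or not lt.active()

    def derived(self) -> DerivedOptics:
        return derive_optics(self.tissue, self.fiber, self.c0)

    def echo(self) -> dict:
        """Flat dict of effective parameters, for run metadata."""
        lt = self.disk.legacy_truncation
        return {
            "c_0": self.c0,
            "ntissue": self.tissue.n,
            "mu_a": self.tissue.mu_a,
            "mu_s": self.tissue.mu_s,
            "g": self.tissue.g,
            "cos2_mean": self.tissue.cos2_mean,
            "NA": self.fiber.NA,
            "opt_radius": self.fiber.radius,
            "xymax": self.grid.xymax,
            "dxy": self.grid.dxy,
            "zmax": self.grid.zmax,
            "dz": self.grid.dz,
            "z_start": self.z_start,
            "rho_exp_min": self.sampling.rho_exp_min,
            "n_rho_smpls": self.sampling.n_rho_smpls,
            "tau_min": self.sampling.tau_min,
            "tau_max": self.sampling.tau_max,
            "n_tau_smpls": self.sampling.n_tau_smpls,
            "mu_tau": self.sampling.mu_tau_mode,
            "nsteps_theta": self.sampling.nsteps_theta,
            "nsteps_phi": self.sampling.nsteps_phi,
            "dxy_direct_disk": self.disk.dxy_direct_disk,
            "dxy_scattered_disk": self.disk.dxy_scattered_disk,
            "legacy_truncation": None if lt is None else asdict(lt),
        }


def default_parameters() -> dict:
    """The shipped default parameter set, as a flat dict."""
    with resources.files("fiberlight").joinpath("defaults.yml").open() as fh:
        return yaml.safe_load(fh)


def _build_config(params: Mapping) -> Config:
    lt = params.get("legacy_truncation")
    if lt is not None:
        if not isinstance(lt, Mapping):
            raise ConfigError("invalid value for 'legacy_truncation': "
                              "expected a mapping of extent overrides")
        bad = set(lt) - set(_LEGACY_KEYS)
        if bad:
            raise ConfigError(
                f"unknown legacy_truncation key(s): {sorted(bad)}; "
                f"valid keys are {list(_LEGACY_KEYS)}")
        lt = LegacyTruncation(**{k: lt.get(k) for k in _LEGACY_KEYS})

    grid = GridSpec(xymax=params["xymax"], dxy=params["dxy"],
                    zmax=params["zmax"], dz=params["dz"])
    z_start = params.get("z_start")
    if z_start is None:
        # start the depth axis just off the source plane: the r = 0 point of
        # the direct cone is singular, and the scattered field vanishes there
        z_start = min(1.0, grid.dz)
    _require(0 < z_start <= grid.zmax, "z_start", "must lie in (0, zmax]")

    return Config(
        c0=float(params["c_0"]),
        tissue=TissueOptics(n=params["ntissue"], mu_a=params["mu_a"],
                            mu_s=params["mu_s"], g=params["g"],
                            cos2_mean=params.get("cos2_mean")),
        fiber=FiberSpec(NA=params["NA"], radius=params["opt_radius"]),
        grid=grid,
        sampling=ScatterSamplingSpec(
            rho_exp_min=params["rho_exp_min"], n_rho_smpls=params["n_rho_smpls"],
            tau_min=params["tau_min"], tau_max=params["tau_max"],
            n_tau_smpls=params["n_tau_smpls"], mu_tau_mode=params["mu_tau"],
            nsteps_theta=params["nsteps_theta"], nsteps_phi=params["nsteps_phi"]),
        disk=DiskConvSpec(dxy_direct_disk=params["dxy_direct_disk"],
                          dxy_scattered_disk=params["dxy_scattered_disk"],
                          legacy_truncation=lt),
        z_start=float(z_start),
    )


def config_from_dict(overrides: Mapping | None = None) -> Config:
    """Build a configuration from the defaults plus ``overrides``.

    Unknown keys raise :class:`ConfigError` — a misspelled parameter name
    must never silently fall back to its default.
    """
    params = default_parameters()
    if overrides:
        unknown = set(overrides) - set(_KNOWN_KEYS)
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        params.update(overrides)
    cfg = _build_config(params)
    cfg.derived()  # validates NA < n
    return cfg


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML parameter file.

    Missing keys are filled from the shipped defaults; an empty file yields
    the default configuration.
    """
    path = Path(path)
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, Mapping):
        raise ConfigError(f"parameter file {path} must contain a mapping")
    return config_from_dict(user)
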