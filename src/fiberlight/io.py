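"""Structured output: HDF5 container, CSV profile export, figures.

Schema of the HDF5 container::

    /direct /scattered /total   intensity on the output grid (z rows, ρ cols)
    /axes/rho /axes/z           axis vectors (μm)
    /manifest                   JSON-encoded run metadata

The round trip ``read_output(write_output(f))`` reproduces values
bit-exactly and axes exactly.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np

from .field import Field2D
from .fiber import FiberLightField, depth_profile, radial_profile


def write_output(result: FiberLightField, path: str | Path) -> None:
    """Write a simulation result to an HDF5 container."""
    path = Path(path)
    manifest = dict(result.metadata)
    manifest.setdefault("written_utc",
                        datetime.now(timezone.utc).isoformat(timespec="seconds"))
    with h5py.File(path, "w") as f:
        f.create_dataset("direct", data=result.direct.values)
        f.create_dataset("scattered", data=result.scattered.values)
        f.create_dataset("total", data=result.total.values)
        axes = f.create_group("axes")
        axes.create_dataset("rho", data=result.rho_axis)
        axes.create_dataset("z", data=result.z_axis)
        f.create_dataset("manifest", data=json.dumps(manifest))


def read_output(path: str | Path) -> FiberLightField:
    """Read a simulation result back from an HDF5 container."""
    with h5py.File(path, "r") as f:
        rho = f["axes/rho"][...]
        z = f["axes/z"][...]
        fields = {name: Field2D(rho_axis=rho, z_axis=z, values=f[name][...])
                  for name in ("direct", "scattered", "total")}
        manifest = json.loads(f["manifest"][()])
    return FiberLightField(metadata=manifest, **fields)


def write_profile_csv(rho_axis: np.ndarray, intensity: np.ndarray,
                      path: str | Path, header: str = "rho_um,intensity") -> None:
    """Export a 1-D radial profile as a two-column CSV table."""
    np.savetxt(path, np.column_stack([rho_axis, intensity]),
               delimiter=",", header=header, comments="")


def write_figures(result: FiberLightField, out_dir: str | Path,
                  depths: tuple[float, float] = (300.0, 600.0)) -> list[Path]:
    """Depth-profile and normalized radial-profile figures.

    Depths outside the grid are clamped to the deepest available sample.
    Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z_axis = result.z_axis
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(z_axis, depth_profile(result.total), label="total")
    ax.semilogy(z_axis, depth_profile(result.direct), "--", label="direct")
    ax.semilogy(z_axis, depth_profile(result.scattered), ":", label="scattered")
    ax.set_xlabel("depth z (μm)")
    ax.set_ylabel("on-axis intensity (a.u.)")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "depth_profile.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    for z in depths:
        zc = min(max(z, z_axis[0]), z_axis[-1])
        ax.plot(result.rho_axis, radial_profile(result.total, zc, normalize=True),
                label=f"z = {zc:.0f} μm")
    ax.set_xlabel("radial distance ρ (μm)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "radial_profiles.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
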