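"""Solvent-accessible surface area (SAS) and volume (SAV) of the solute cavity.

SASA is computed by the Shrake–Rupley point-counting scheme: each solute atom
is inflated by the probe radius, covered with a deterministic spherical point
lattice, and its area is 4π(r_i+probe)² times the fraction of points outside
every other inflated solute sphere. The point placement (a Fibonacci spiral
through :func:`biotite.structure.sasa`) is deterministic, so areas are exactly
reproducible with no seed.

SAV is the volume of the union of the probe-inflated spheres, estimated by
counting regular voxel centers inside the union — also deterministic for a
fixed voxel edge.

Only solute atoms enter either quantity: both describe the cavity the solute
carves into the solvent. Atom radii come from the topology's per-atom
``sasa_radius`` field (Bondi radii are the conventional choice); the probe
defaults to the 1.4 Å water probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .io_system import SystemTopology, Trajectory

__all__ = [
    "SasaResult",
    "SavResult",
    "shrake_rupley_sasa",
    "accessible_volume",
    "mean_sasa_over_trajectory",
]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_VOXEL = 0.25  # Å


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom: np.ndarray
    total: float
    probe_radius: float
    n_points: int


@dataclass(frozen=True)
class SavResult:
    """Solvent-accessible volume (Å³) by voxel counting."""

    volume: float
    probe_radius: float
    voxel: float


def _solute_coords_radii(topology: SystemTopology, coords) -> tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError(
            f"coordinates have shape {coords.shape}, expected ({topology.n_atoms}, 3)"
        )
    sel = topology.solute_indices
    if sel.size == 0:
        raise ValueError("topology has no solute atoms")
    return coords[sel], topology.sasa_radii[sel]


def shrake_rupley_sasa(topology: SystemTopology, coords,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake–Rupley SASA of the solute atoms in one frame."""
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    xyz, radii = _solute_coords_radii(topology, coords)
    arr = struc.AtomArray(len(xyz))
    arr.coord = xyz.astype(np.float32)
    arr.set_annotation("element", np.array(["X"] * len(xyz)))
    per_atom = struc.sasa(
        arr,
        probe_radius=float(probe_radius),
        point_number=int(n_points),
        vdw_radii=radii,
        ignore_ions=False,
    ).astype(float)
    return SasaResult(
        per_atom=per_atom,
        total=float(per_atom.sum()),
        probe_radius=float(probe_radius),
        n_points=int(n_points),
    )


def accessible_volume(topology: SystemTopology, coords,
                      probe_radius: float = DEFAULT_PROBE_RADIUS,
                      voxel: float = DEFAULT_VOXEL) -> SavResult:
    """Union-of-spheres volume of the probe-inflated solute, by voxel counting.

    Voxel centers on a regular grid spanning the bounding box are tested for
    membership in any inflated sphere; the volume is (count)·voxel³. The
    default 0.25 Å voxel keeps single-sphere volumes within ~1% of the
    analytic value at negligible cost for small-molecule solutes.
    """
    if not voxel > 0:
        raise ValueError("voxel edge must be positive")
    xyz, radii = _solute_coords_radii(topology, coords)
    r = radii + float(probe_radius)
    lo = (xyz - r[:, None]).min(axis=0)
    hi = (xyz + r[:, None]).max(axis=0)
    n = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    inside = np.zeros(n, dtype=bool)
    # mark voxels per atom over its own sub-box only, to bound memory
    for center, rad in zip(xyz, r):
        i_lo = np.maximum(((center - rad - lo) / voxel - 0.5).astype(int), 0)
        i_hi = np.minimum(((center + rad - lo) / voxel + 0.5).astype(int) + 1, n)
        axes = [
            lo[d] + (np.arange(i_lo[d], i_hi[d]) + 0.5) * voxel - center[d]
            for d in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        sub = inside[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]]
        sub |= d2 <= rad * rad
    return SavResult(
        volume=float(inside.sum()) * voxel ** 3,
        probe_radius=float(probe_radius),
        voxel=float(voxel),
    )


def mean_sasa_over_trajectory(topology: SystemTopology, trajectory: Trajectory,
                              mode: str = "sas", **params) -> float:
    """Arithmetic mean of the per-frame total SASA (mode ``"sas"``, Å²) or
    SAV (mode ``"sav"``, Å³) over all frames."""
    if trajectory.n_frames < 1:
        raise ValueError("trajectory is empty")
    totals = []
    for frame in trajectory.coordinates:
        if mode == "sas":
            totals.append(shrake_rupley_sasa(topology, frame, **params).total)
        elif mode == "sav":
            totals.append(accessible_volume(topology, frame, **params).volume)
        else:
            raise ValueError(f"unknown mode {mode!r} (expected 'sas' or 'sav')")
    return float(np.mean(totals))
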