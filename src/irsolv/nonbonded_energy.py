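"""Pairwise solute–solvent interaction energies.

The per-frame interaction energy is a direct double sum over all
(solute atom, solvent atom) pairs of a Coulomb term and a 12-6
Lennard-Jones term,

    E_ele = k_C * q_i * q_j / r_ij
    E_vdw = eps_ij * [ (R_ij / r_ij)^12 - 2 (R_ij / r_ij)^6 ]

with Lorentz–Berthelot-style combination R_ij = Rmin/2_i + Rmin/2_j and
eps_ij = sqrt(eps_i * eps_j), matching the AMBER force-field family. Since
solute and solvent are distinct molecules every inter-set pair contributes at
full strength; there is no exclusion or 1-4 scaling.

By default the sum runs over all pairs with no cutoff and no periodicity —
exact for isolated clusters. A cutoff and an orthorhombic minimum-image mode
are available for periodic frames; note that values computed this way differ
from Ewald/PME energies produced by MD engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_system import SystemTopology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyOptions",
    "EnergySeries",
    "SingularityError",
    "pair_energy",
    "frame_interaction_energy",
    "trajectory_energy_series",
]

#: Coulomb constant in kcal·Å/(mol·e²), AMBER convention.
COULOMB_CONSTANT = 332.0522173

#: Pairs closer than this (Å) raise :class:`SingularityError`.
OVERLAP_TOLERANCE = 1e-6


class SingularityError(ValueError):
    """Raised when two interacting atoms (near-)overlap."""


@dataclass(frozen=True)
class EnergyOptions:
    """Options for the pairwise sum.

    cutoff : float or None
        Radial cutoff in Å; pairs beyond it contribute zero. ``None`` (the
        default) sums all pairs.
    minimum_image : bool
        Apply orthorhombic minimum-image displacements; requires the topology
        to carry a box.
    coulomb_constant : float
        kcal·Å/(mol·e²); the AMBER value by default.
    """

    cutoff: float | None = None
    minimum_image: bool = False
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if self.cutoff is not None and not self.cutoff > 0:
            raise ValueError("cutoff must be positive or None")


@dataclass
class EnergySeries:
    """Per-frame solute–solvent energies in kcal/mol.

    ``e_total`` is always ``e_ele + e_vdw``; it is stored explicitly so file
    round-trips can verify it but recomputed here to keep the invariant exact.
    """

    e_ele: np.ndarray
    e_vdw: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_ele = np.asarray(self.e_ele, dtype=float)
        self.e_vdw = np.asarray(self.e_vdw, dtype=float)
        if self.e_ele.shape != self.e_vdw.shape or self.e_ele.ndim != 1:
            raise ValueError("e_ele and e_vdw must be 1-D arrays of equal length")
        if not (np.isfinite(self.e_ele).all() and np.isfinite(self.e_vdw).all()):
            raise ValueError("energy series contains non-finite entries")

    @property
    def e_total(self) -> np.ndarray:
        return self.e_ele + self.e_vdw

    @property
    def n_frames(self) -> int:
        return self.e_ele.shape[0]


def pair_energy(q_i: float, q_j: float, rmin_half_i: float, rmin_half_j: float,
                eps_i: float, eps_j: float, r: float,
                options: EnergyOptions | None = None) -> tuple[float, float]:
    """Coulomb and Lennard-Jones energy (kcal/mol) of one atom pair at distance r (Å)."""
    if options is None:
        options = EnergyOptions()
    if not r > 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    e_ele = options.coulomb_constant * q_i * q_j / r
    rmin = rmin_half_i + rmin_half_j
    eps = np.sqrt(eps_i * eps_j)
    s6 = (rmin / r) ** 6
    e_vdw = eps * (s6 * s6 - 2.0 * s6)
    return float(e_ele), float(e_vdw)


def frame_interaction_energy(topology: SystemTopology, frame_coords,
                             options: EnergyOptions | None = None
                             ) -> tuple[float, float]:
    """Total solute–solvent (e_ele, e_vdw) for one frame.

    Sums over every (solute, solvent) atom pair; solute–solute and
    solvent–solvent pairs never enter. Raises :class:`SingularityError`
    naming the closest pair if any interacting distance falls below
    ``OVERLAP_TOLERANCE``.
    """
    if options is None:
        options = EnergyOptions()
    coords = np.asarray(frame_coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError(
            f"frame has shape {coords.shape}, expected ({topology.n_atoms}, 3)"
        )
    u = topology.solute_indices
    v = topology.solvent_indices
    if v.size == 0:
        raise ValueError("topology has no solvent atoms; no interaction to compute")

    disp = coords[v][None, :, :] - coords[u][:, None, :]
    if options.minimum_image:
        if topology.box is None:
            raise ValueError("minimum_image requires a topology box")
        box = np.asarray(topology.box, dtype=float)
        disp -= box * np.round(disp / box)
    r = np.sqrt((disp ** 2).sum(axis=2))

    if (r < OVERLAP_TOLERANCE).any():
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise SingularityError(
            f"atoms {u[i]} (solute) and {v[j]} (solvent) overlap: "
            f"r = {r[i, j]:.3e} Å"
        )

    mask = np.ones_like(r, dtype=bool)
    if options.cutoff is not None:
        mask = r <= options.cutoff

    q = topology.charges
    qq = np.outer(q[u], q[v])
    e_ele = options.coulomb_constant * np.where(mask, qq / r, 0.0).sum()

    rmin = topology.lj_rmin_half
    eps = topology.lj_epsilon
    rmin_ij = rmin[u][:, None] + rmin[v][None, :]
    eps_ij = np.sqrt(np.outer(eps[u], eps[v]))
    s6 = (rmin_ij / r) ** 6
    e_vdw = np.where(mask, eps_ij * (s6 * s6 - 2.0 * s6), 0.0).sum()
    return float(e_ele), float(e_vdw)


def trajectory_energy_series(topology: SystemTopology, trajectory: Trajectory,
                             options: EnergyOptions | None = None) -> EnergySeries:
    """Per-frame interaction energies over a whole trajectory, in frame order."""
    if trajectory.n_frames < 1:
        raise ValueError("trajectory is empty")
    e_ele = np.empty(trajectory.n_frames)
    e_vdw = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.coordinates):
        try:
            e_ele[k], e_vdw[k] = frame_interaction_energy(topology, frame, options)
        except (SingularityError, ValueError) as exc:
            raise type(exc)(f"frame {k + 1}: {exc}") from exc
    return EnergySeries(e_ele=e_ele, e_vdw=e_vdw,
                        meta={"n_frames": trajectory.n_frames})
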