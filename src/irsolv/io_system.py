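"""Topology, trajectory and table I/O.

The system topology is a plain JSON document carrying everything the energy
and surface machinery needs per atom: partial charge (elementary charge
units), Lennard-Jones parameters in Rmin/2–epsilon form (Å, kcal/mol), a
SASA radius (Å) and a role label assigning the atom to the solute or the
solvent. Trajectories are multi-model PDB or repeated-block XYZ; coordinates
are always Å. Units are fixed package-wide (AMBER conventions): no unit
options anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "SystemTopology",
    "Trajectory",
    "TopologyError",
    "TrajectoryParseError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_energy_series_csv",
    "write_energy_series_csv",
]

ROLES = ("solute", "solvent")


class TopologyError(ValueError):
    """Raised when a topology document violates the schema or an invariant."""


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed against its topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a solvated system.

    Parameters
    ----------
    index : int
        0-based position in the topology; must be gap-free across the system.
    charge : float
        Partial charge in elementary-charge units.
    lj_rmin_half : float
        Rmin/2 Lennard-Jones radius, Å (AMBER convention).
    lj_epsilon : float
        Lennard-Jones well depth, kcal/mol (>= 0).
    sasa_radius : float
        Radius used for solvent-accessible surface/volume, Å (> 0).
    role : str
        ``"solute"`` or ``"solvent"``.
    mol_id : int
        Molecule grouping label.
    """

    index: int
    name: str
    element: str
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    sasa_radius: float
    role: str
    mol_id: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TopologyError(
                f"atom {self.index}: unknown role {self.role!r} (expected one of {ROLES})"
            )
        if self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.index}: lj_epsilon must be >= 0")
        if self.lj_rmin_half < 0:
            raise TopologyError(f"atom {self.index}: lj_rmin_half must be >= 0")
        if not self.sasa_radius > 0:
            raise TopologyError(f"atom {self.index}: sasa_radius must be > 0")


@dataclass
class SystemTopology:
    """Ordered atom records defining the energy model of one solvated system."""

    atoms: list[AtomRecord]
    box: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise TopologyError("topology contains no atoms")
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            for pos, idx in enumerate(indices):
                if idx != pos:
                    raise TopologyError(
                        f"atom indices must be 0..N-1 without gaps; "
                        f"position {pos} holds index {idx}"
                    )
        if self.box is not None:
            self.box = tuple(float(x) for x in self.box)
            if len(self.box) != 3 or any(x <= 0 for x in self.box):
                raise TopologyError("box lengths must be three positive floats")
        if not self.solute_indices.size:
            raise TopologyError("topology has no solute atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    @property
    def solute_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.role == "solute"], dtype=int)

    @property
    def solvent_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.role == "solvent"], dtype=int)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    @property
    def sasa_radii(self) -> np.ndarray:
        return np.array([a.sasa_radius for a in self.atoms])


@dataclass
class Trajectory:
    """Per-frame coordinates (Å) in topology atom order, shape (n_frames, N, 3)."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryParseError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise TrajectoryParseError("trajectory must contain at least one frame")
        if not np.isfinite(self.coordinates).all():
            raise TrajectoryParseError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# Topology JSON
# ---------------------------------------------------------------------------

_ATOM_FIELDS = (
    "index",
    "name",
    "element",
    "charge",
    "lj_rmin_half",
    "lj_epsilon",
    "sasa_radius",
    "role",
    "mol_id",
)


def read_topology(path) -> SystemTopology:
    """Read and validate a topology JSON document.

    Raises :class:`TopologyError` naming the offending atom index on any
    missing field, negative epsilon/radius, unknown role, or index gap.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "atoms" not in doc:
        raise TopologyError("topology document lacks an 'atoms' list")
    atoms = []
    for pos, raw in enumerate(doc["atoms"]):
        missing = [f for f in _ATOM_FIELDS if f not in raw]
        if missing:
            raise TopologyError(f"atom at position {pos}: missing fields {missing}")
        atoms.append(
            AtomRecord(
                index=int(raw["index"]),
                name=str(raw["name"]),
                element=str(raw["element"]),
                charge=float(raw["charge"]),
                lj_rmin_half=float(raw["lj_rmin_half"]),
                lj_epsilon=float(raw["lj_epsilon"]),
                sasa_radius=float(raw["sasa_radius"]),
                role=str(raw["role"]),
                mol_id=int(raw["mol_id"]),
            )
        )
    box = tuple(doc["box"]) if doc.get("box") is not None else None
    return SystemTopology(atoms=atoms, box=box, meta=doc.get("meta", {}))


def write_topology(topology: SystemTopology, path) -> None:
    doc = {
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS} for a in topology.atoms
        ],
        "box": list(topology.box) if topology.box is not None else None,
        "meta": topology.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Trajectories: multi-model PDB and repeated-block XYZ
# ---------------------------------------------------------------------------


def read_trajectory(path, topology: SystemTopology, format: str) -> Trajectory:
    """Read trajectory frames, validating each frame's atom count.

    ``format`` is ``"pdb"`` (MODEL/ENDMDL records; only the fixed coordinate
    columns of ATOM/HETATM lines are consulted — identities come from the
    topology) or ``"xyz"`` (repeated N-line blocks with a count header).
    """
    if format == "pdb":
        frames = _read_pdb_frames(path)
    elif format == "xyz":
        frames = _read_xyz_frames(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    n = topology.n_atoms
    for i, frame in enumerate(frames):
        if len(frame) != n:
            raise TrajectoryParseError(
                f"{path}: frame {i + 1} has {len(frame)} atoms, topology has {n}"
            )
    return Trajectory(np.array(frames, dtype=float))


def _read_pdb_frames(path) -> list[list[tuple[float, float, float]]]:
    frames: list[list] = []
    current: list | None = None
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model:
                        continue  # coordinates outside MODEL blocks are ignored
                    current = []
                try:
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise TrajectoryParseError(
                        f"{path}: bad coordinate columns in line {line.rstrip()!r}"
                    ) from exc
                current.append(xyz)
    if current:  # single-frame file without MODEL records
        frames.append(current)
    return frames


def _read_xyz_frames(path) -> list[list[tuple[float, float, float]]]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"{path}: expected atom-count header at line {pos + 1}, "
                f"got {lines[pos]!r}"
            ) from exc
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise TrajectoryParseError(
                f"{path}: frame {len(frames) + 1} truncated "
                f"({len(block)} of {count} atom lines)"
            )
        frame = []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"{path}: frame {len(frames) + 1}: malformed atom line {ln!r}"
                )
            frame.append((float(parts[1]), float(parts[2]), float(parts[3])))
        frames.append(frame)
        pos += 2 + count
    return frames


def write_trajectory(trajectory: Trajectory, topology: SystemTopology, path,
                     format: str) -> None:
    if trajectory.n_atoms != topology.n_atoms:
        raise TrajectoryParseError(
            f"trajectory has {trajectory.n_atoms} atoms, topology {topology.n_atoms}"
        )
    if format == "pdb":
        _write_pdb(trajectory, topology, path)
    elif format == "xyz":
        _write_xyz(trajectory, topology, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def _write_pdb(trajectory, topology, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory.coordinates, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for atom, (x, y, z) in zip(topology.atoms, frame):
                serial = atom.index + 1  # files keep native 1-based serials
                fh.write(
                    f"ATOM  {serial:5d} {atom.name:<4.4s} MOL {atom.mol_id % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{atom.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_xyz(trajectory, topology, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory.coordinates, start=1):
            fh.write(f"{topology.n_atoms}\nframe {m}\n")
            for atom, (x, y, z) in zip(topology.atoms, frame):
                fh.write(f"{atom.name:<4s} {x:.9f} {y:.9f} {z:.9f}\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trip safe for IEEE doubles


def read_dataset_csv(path):
    """Read a per-solute regression table into an :class:`~irsolv.irs_model.IRSDataset`.

    Required columns: ``solute_id, dG_int, sasa``. ``dG_exp`` is optional (its
    absence flags a prediction-only dataset), as are ``dH_int`` and
    ``minus_TdS_int`` for decomposition reports.
    """
    from .irs_model import IRSDataset

    df = pd.read_csv(path, float_precision="round_trip")
    required = ["solute_id", "dG_int", "sasa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dataset CSV missing columns {missing}")
    numeric = [c for c in df.columns if c != "solute_id"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r}, row(s) {bad}"
            ) from None
    return IRSDataset(df)


def write_dataset_csv(dataset, path) -> None:
    dataset.df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_energy_series_csv(path):
    """Read a per-frame energy table (columns ``frame,e_ele,e_vdw,e_total``)."""
    from .nonbonded_energy import EnergySeries

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("e_ele", "e_vdw", "e_total"):
        if col not in df.columns:
            raise ValueError(f"{path}: energy-series CSV missing column {col!r}")
    return EnergySeries(
        e_ele=df["e_ele"].to_numpy(float),
        e_vdw=df["e_vdw"].to_numpy(float),
        meta={"source": str(path)},
    )


def write_energy_series_csv(series, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "e_ele": series.e_ele,
            "e_vdw": series.e_vdw,
            "e_total": series.e_total,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
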