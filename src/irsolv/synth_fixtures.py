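"""Synthetic test systems: toy water shells, Gaussian energy series, and
regression datasets with known ground truth.

These generators exercise the energy, entropy, surface and regression
machinery on inputs whose statistics are known exactly. The water-shell
fixtures are *random packings*, not equilibrated molecular dynamics: waters
carry real TIP3P parameters and respect a minimum O–O contact distance, but
their arrangement has no Boltzmann weight. Interaction energies computed from
them are well-defined test quantities, not physical hydration energies.

All generators are pure functions of their spec: the same seed reproduces
bit-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_system import AtomRecord, SystemTopology, Trajectory
from .irs_model import IRSDataset, ModelSpec, signed_power
from .nonbonded_energy import EnergySeries

__all__ = [
    "FixtureSpec",
    "SyntheticDatasetSpec",
    "PackingError",
    "generate_water_shell",
    "generate_gaussian_series",
    "generate_regression_dataset",
]

# TIP3P rigid water: charges (e), Rmin/2 (Å), epsilon (kcal/mol).
# Hydrogen epsilon is a tiny positive value instead of 0 so that the geometric
# combination rule needs no special case; the resulting LJ energies are
# indistinguishable from zero at test tolerances.
TIP3P_O = {"charge": -0.834, "rmin_half": 1.7683, "epsilon": 0.1520, "sasa_radius": 1.52}
TIP3P_H = {"charge": +0.417, "rmin_half": 0.0, "epsilon": 1e-6, "sasa_radius": 1.20}
TIP3P_OH_BOND = 0.9572  # Å
TIP3P_HOH_ANGLE = np.deg2rad(104.52)

MIN_OO_DISTANCE = 2.6  # Å, enforced between water oxygens
MIN_SOLUTE_DISTANCE = 2.8  # Å, water O to any solute atom


class PackingError(RuntimeError):
    """Raised when the requested waters cannot be packed into the shell."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a toy solvated-shell fixture.

    jitter is the per-frame Gaussian coordinate noise (Å) applied to the base
    packing to mimic thermal fluctuation at toy scale.
    """

    seed: int = 0
    n_waters: int = 20
    shell_radius: float = 8.0
    solute: str = "point_charge"  # or "methane_like"
    jitter: float = 0.05
    n_frames: int = 10

    def __post_init__(self) -> None:
        if self.n_waters < 0:
            raise ValueError("n_waters must be >= 0")
        if not self.shell_radius > 0:
            raise ValueError("shell_radius must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def _solute_atoms(kind: str) -> list[dict]:
    if kind == "point_charge":
        return [
            dict(name="X", element="X", charge=1.0, lj_rmin_half=1.5,
                 lj_epsilon=0.1, sasa_radius=1.6, xyz=(0.0, 0.0, 0.0))
        ]
    if kind == "methane_like":
        # tetrahedral CH4 with GAFF-like c3/hc parameters
        d = 1.09 / np.sqrt(3.0)
        verts = [(d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
        atoms = [
            dict(name="C", element="C", charge=-0.24, lj_rmin_half=1.9080,
                 lj_epsilon=0.1094, sasa_radius=1.70, xyz=(0.0, 0.0, 0.0))
        ]
        for i, v in enumerate(verts, start=1):
            atoms.append(
                dict(name=f"H{i}", element="H", charge=0.06, lj_rmin_half=1.4870,
                     lj_epsilon=0.0157, sasa_radius=1.20, xyz=v)
            )
        return atoms
    raise ValueError(f"unknown solute kind {kind!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_template() -> np.ndarray:
    """TIP3P geometry centered on the oxygen: O, H1, H2."""
    half = TIP3P_HOH_ANGLE / 2.0
    h1 = TIP3P_OH_BOND * np.array([np.sin(half), np.cos(half), 0.0])
    h2 = TIP3P_OH_BOND * np.array([-np.sin(half), np.cos(half), 0.0])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def generate_water_shell(spec: FixtureSpec) -> tuple[SystemTopology, Trajectory]:
    """Pack rigid TIP3P waters around a solute and jitter them into frames.

    Water oxygens are placed uniformly in the shell sphere, rejected until
    they keep >= 2.6 Å from every other oxygen and >= 2.8 Å from the solute;
    each water gets a random rigid orientation. Frames are the base packing
    plus i.i.d. Gaussian jitter. Deterministic for a fixed seed.

    Raises :class:`PackingError` when the shell cannot host the requested
    number of waters at the minimum contact distance.
    """
    rng = np.random.default_rng(spec.seed)
    solute = _solute_atoms(spec.solute)
    solute_xyz = np.array([a["xyz"] for a in solute])

    o_positions: list[np.ndarray] = []
    max_attempts = 2000 * max(spec.n_waters, 1)
    attempts = 0
    while len(o_positions) < spec.n_waters:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {spec.n_waters} waters in a {spec.shell_radius} Å "
                f"shell at {MIN_OO_DISTANCE} Å minimum O-O distance; "
                "increase shell_radius or reduce n_waters"
            )
        attempts += 1
        # uniform point in the ball of radius shell_radius
        p = rng.normal(size=3)
        p *= spec.shell_radius * rng.uniform() ** (1 / 3) / np.linalg.norm(p)
        if np.linalg.norm(solute_xyz - p, axis=1).min() < MIN_SOLUTE_DISTANCE:
            continue
        if o_positions and min(
            np.linalg.norm(np.array(o_positions) - p, axis=1)
        ) < MIN_OO_DISTANCE:
            continue
        o_positions.append(p)

    atoms: list[AtomRecord] = []
    base: list[np.ndarray] = []
    for i, a in enumerate(solute):
        atoms.append(
            AtomRecord(index=i, name=a["name"], element=a["element"],
                       charge=a["charge"], lj_rmin_half=a["lj_rmin_half"],
                       lj_epsilon=a["lj_epsilon"], sasa_radius=a["sasa_radius"],
                       role="solute", mol_id=0)
        )
        base.append(np.asarray(a["xyz"], dtype=float))

    template = _water_template()
    names = ("O", "H1", "H2")
    elements = ("O", "H", "H")
    params = (TIP3P_O, TIP3P_H, TIP3P_H)
    idx = len(solute)
    for w, o_pos in enumerate(o_positions, start=1):
        rot = _random_rotation(rng)
        for site in range(3):
            p = params[site]
            atoms.append(
                AtomRecord(index=idx, name=names[site], element=elements[site],
                           charge=p["charge"], lj_rmin_half=p["rmin_half"],
                           lj_epsilon=p["epsilon"], sasa_radius=p["sasa_radius"],
                           role="solvent", mol_id=w)
            )
            base.append(o_pos + template[site] @ rot.T)
            idx += 1

    topology = SystemTopology(
        atoms=atoms,
        meta={"generator": "irsolv.synth_fixtures.generate_water_shell",
              "seed": spec.seed, "solute": spec.solute},
    )
    base_arr = np.array(base)
    frames = base_arr[None, :, :] + rng.normal(
        0.0, spec.jitter, size=(spec.n_frames, len(base), 3)
    )
    return topology, Trajectory(frames)


def generate_gaussian_series(mean: float, sigma: float, n: int,
                             seed: int = 0) -> EnergySeries:
    """i.i.d. normal energy series (kcal/mol); e_ele carries the draws, e_vdw = 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sigma, size=n)
    return EnergySeries(e_ele=draws, e_vdw=np.zeros(n),
                        meta={"mean": mean, "sigma": sigma, "seed": seed})


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Ground-truth regression dataset parameters.

    Default dG_int ~ N(-8, 6) kcal/mol spans the magnitude range of neutral
    small-molecule hydration interaction energies; sasa ~ N(300, 80) Å²
    matches small-organic solvent-accessible areas. Noise is added to dG_exp
    only.
    """

    n_rows: int = 280
    coefficients: tuple[float, ...] = (0.45, 0.012)
    gamma: float = 0.008
    b: float = 1.5
    dg_int_mean: float = -8.0
    dg_int_sd: float = 6.0
    sasa_mean: float = 300.0
    sasa_sd: float = 80.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dg_int_sd < 0 or self.sasa_sd < 0 or self.noise_sigma < 0:
            raise ValueError("standard deviations must be >= 0")


def generate_regression_dataset(spec: SyntheticDatasetSpec,
                                model_spec: ModelSpec | None = None
                                ) -> tuple[IRSDataset, dict]:
    """Draw (dG_int, sasa) and synthesize dG_exp from known coefficients.

    dG_exp = dG_int + sum_k c_k·dG_int^{p_k} + gamma·sasa + b + N(0, noise).
    Returns the dataset plus a truth record holding the exact generating
    coefficients for parameter-recovery tests.
    """
    if model_spec is None:
        model_spec = ModelSpec()
    if len(spec.coefficients) != len(model_spec.powers):
        raise ValueError(
            f"{len(spec.coefficients)} coefficients for "
            f"{len(model_spec.powers)} powers"
        )
    if spec.n_rows <= model_spec.n_parameters:
        raise ValueError("n_rows must exceed the parameter count")
    rng = np.random.default_rng(spec.seed)
    dg_int = rng.normal(spec.dg_int_mean, spec.dg_int_sd, size=spec.n_rows)
    sasa = np.clip(
        rng.normal(spec.sasa_mean, spec.sasa_sd, size=spec.n_rows), 1.0, None
    )
    f_poly = sum(
        c * signed_power(dg_int, p, model_spec.power_convention)
        for c, p in zip(spec.coefficients, model_spec.powers)
    )
    noise = rng.normal(0.0, spec.noise_sigma, size=spec.n_rows)
    dg_exp = dg_int + f_poly + spec.gamma * sasa + spec.b + noise
    ids = [f"synth-{i:04d}" for i in range(spec.n_rows)]
    dataset = IRSDataset.from_arrays(ids, dg_int, sasa, dG_exp=dg_exp)
    truth = {
        "coefficients": list(spec.coefficients),
        "gamma": spec.gamma,
        "b": spec.b,
        "powers": list(model_spec.powers),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return dataset, truth
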