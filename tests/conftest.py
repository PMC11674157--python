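import numpy as np
import pytest

from irsolv.io_system import AtomRecord, SystemTopology, Trajectory
from irsolv.synth_fixtures import FixtureSpec, generate_water_shell


def make_atom(index, role="solute", charge=0.0, rmin_half=1.5, epsilon=0.1,
              sasa_radius=1.6, name="X", element="X", mol_id=0):
    return AtomRecord(index=index, name=name, element=element, charge=charge,
                      lj_rmin_half=rmin_half, lj_epsilon=epsilon,
                      sasa_radius=sasa_radius, role=role, mol_id=mol_id)


@pytest.fixture
def point_pair_topology():
    """+1 solute point charge and -1 solvent point charge, LJ disabled."""
    return SystemTopology(
        atoms=[
            make_atom(0, "solute", charge=1.0, epsilon=0.0),
            make_atom(1, "solvent", charge=-1.0, epsilon=0.0, mol_id=1),
        ]
    )


@pytest.fixture(scope="session")
def small_shell():
    """20-water shell around a point-charge solute, 5 jittered frames."""
    spec = FixtureSpec(seed=11, n_waters=20, shell_radius=8.0, n_frames=5)
    return generate_water_shell(spec)


@pytest.fixture
def single_sphere_topology():
    """One solute atom of SASA radius 1.6 Å at the origin."""
    return SystemTopology(atoms=[make_atom(0, sasa_radius=1.6)])


def random_mixed_system(rng, n_atoms):
    """Random topology + coordinates with mixed roles, safely separated atoms."""
    n_solute = max(1, n_atoms // 2)
    atoms = []
    for i in range(n_atoms):
        role = "solute" if i < n_solute else "solvent"
        atoms.append(
            make_atom(
                i, role,
                charge=rng.uniform(-1, 1),
                rmin_half=rng.uniform(0.5, 2.0),
                epsilon=rng.uniform(0.0, 0.3),
                sasa_radius=rng.uniform(1.0, 2.0),
                mol_id=0 if role == "solute" else i,
            )
        )
    # grid placement with random sub-jitter keeps all pairs > 1 A apart
    side = int(np.ceil(n_atoms ** (1 / 3)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n_atoms] * 3.0
    coords = grid + rng.uniform(-0.5, 0.5, size=(n_atoms, 3))
    return SystemTopology(atoms=atoms), coords
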