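import numpy as np
import pytest

from memshock.system import ParticleFrame, Topology, ForceField


@pytest.fixture
def solvent_frame():
    """A small random soft-sphere fluid at roughly water density."""
    rng = np.random.default_rng(7)
    n = 250
    box_l = (n / 0.008364) ** (1 / 3)
    frame = ParticleFrame(
        positions=rng.uniform(0, box_l, (n, 3)),
        velocities=rng.normal(0, 1.9, (n, 3)),
        masses=np.full(n, 72.0),
        species=np.array(["W"] * n),
        molecule_id=np.arange(n),
        box=np.array([box_l] * 3),
    )
    topo = Topology(
        bead_role=np.zeros(n, np.int8), bonds=np.zeros((0, 2), np.int64),
        bond_r0=[], bond_k=[], lipid_id=np.full(n, -1),
        leaflet_of_lipid=[0, 1], director_pairs=np.zeros((0, 2), np.int64),
        director_lipid=[],
    )
    return frame, topo


@pytest.fixture
def free_topology():
    """Topology factory for non-interacting N-particle systems."""
    def make(n):
        return Topology(
            bead_role=np.zeros(n, np.int8), bonds=np.zeros((0, 2), np.int64),
            bond_r0=[], bond_k=[], lipid_id=np.full(n, -1),
            leaflet_of_lipid=[0, 1], director_pairs=np.zeros((0, 2), np.int64),
            director_lipid=[],
        )
    return make


@pytest.fixture(scope="session")
def small_membrane():
    """Built + briefly equilibrated small bilayer, shared across tests."""
    from memshock import build_system, default_forcefield, equilibrate
    frame, topo = build_system(n_lipids=32, cholesterol_fraction=0.125,
                               solvent_pad_plus_z=45.0, solvent_pad_minus_z=30.0,
                               seed=11)
    ff = default_forcefield()
    eq, rep = equilibrate(frame, topo, ff, 310.0, 2500, seed=12)
    return eq, topo, ff
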