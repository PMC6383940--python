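"""Core containers: particle frames, topology and the CG force field.

A :class:`ParticleFrame` is one time point of the particle system; a
:class:`Topology` carries the time-independent structure (bead roles,
bonds, lipid/leaflet membership and the director pairs used for
order-parameter analysis); a :class:`ForceField` holds the nonbonded
parameters and integration settings of the coarse-grained model.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .units import KB

# bead roles
ROLE_SOLVENT = 0
ROLE_HEAD = 1
ROLE_TAIL = 2

ROLE_NAMES = {ROLE_SOLVENT: "solvent", ROLE_HEAD: "head", ROLE_TAIL: "tail"}

# leaflet labels: proximal faces the incoming shock (-z side)
LEAFLET_PROXIMAL = 0
LEAFLET_DISTAL = 1


class SystemError_(ValueError):
    """Invalid system state (non-finite coordinates, bad box, ...)."""


@dataclass
class ParticleFrame:
    """One snapshot of a particle system in internal units (A, ps, amu).

    positions/velocities are (N, 3); box is (Lx, Ly, Lz) with periodic
    boundaries in all three directions.  ``molecule_id`` groups beads into
    molecules (solvent beads are one-bead molecules).
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.species = np.asarray(self.species)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise SystemError_("positions and velocities must be (N, 3)")
        if not (self.masses.shape == self.species.shape == self.molecule_id.shape == (n,)):
            raise SystemError_("masses, species, molecule_id must be (N,)")
        if not np.all(np.isfinite(self.positions)):
            raise SystemError_("non-finite positions")
        if not np.all(self.masses > 0):
            raise SystemError_("masses must be strictly positive")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise SystemError_("box must be three positive edge lengths")

    # -- convenience ---------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def lateral_area(self) -> float:
        """A = Lx * Ly, the area entering the impulse relation I = dM/A."""
        return float(self.box[0] * self.box[1])

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "ParticleFrame":
        return ParticleFrame(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            self.species.copy(), self.molecule_id.copy(), self.box.copy(), self.time,
        )

    def wrapped(self) -> "ParticleFrame":
        """Return a copy with positions wrapped into [0, L) per dimension."""
        out = self.copy()
        out.positions = np.mod(out.positions, out.box[None, :])
        return out

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    def momentum(self) -> np.ndarray:
        return np.asarray(self.masses @ self.velocities)

    def kinetic_temperature(self) -> float:
        """Instantaneous temperature from equipartition over 3N dof."""
        return 2.0 * self.kinetic_energy() / (3.0 * self.n_particles * KB)


@dataclass
class Topology:
    """Structure shared by all frames of a run.

    ``bonds`` is an (nb, 2) int array with per-bond rest length and
    stiffness in ``bond_r0``/``bond_k``; it includes both nearest-neighbour
    springs and the 1-3 stiffening springs that keep chains straight
    (all interactions are central pair forces, which keeps the virial and
    the local-pressure apportionment exact).  ``director_pairs`` are the
    ordered bead-index pairs whose connecting vectors play the role the
    C-H bonds play in all-atom order-parameter analysis; for the CG model
    they are consecutive tail-bead bonds (``director_kind='chain'``),
    for externally supplied all-atom data they can be genuine C-H pairs
    (``director_kind='ch'``).
    """

    bead_role: np.ndarray
    bonds: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    lipid_id: np.ndarray            # -1 for solvent beads
    leaflet_of_lipid: np.ndarray    # per lipid: LEAFLET_PROXIMAL / LEAFLET_DISTAL
    director_pairs: np.ndarray      # (nd, 2) bead indices
    director_lipid: np.ndarray      # (nd,) owning lipid
    director_kind: str = "chain"
    angles: Optional[np.ndarray] = None  # optional (na, 3) triplets, informational

    def __post_init__(self):
        self.bead_role = np.asarray(self.bead_role, dtype=np.int8)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=np.float64)
        self.bond_k = np.asarray(self.bond_k, dtype=np.float64)
        self.lipid_id = np.asarray(self.lipid_id, dtype=np.int64)
        self.leaflet_of_lipid = np.asarray(self.leaflet_of_lipid, dtype=np.int8)
        self.director_pairs = np.asarray(self.director_pairs, dtype=np.int64).reshape(-1, 2)
        self.director_lipid = np.asarray(self.director_lipid, dtype=np.int64)
        if len(self.bond_r0) != len(self.bonds) or len(self.bond_k) != len(self.bonds):
            raise SystemError_("bond_r0/bond_k must match bonds")
        if len(self.director_lipid) != len(self.director_pairs):
            raise SystemError_("director_lipid must match director_pairs")
        for i, j in self.director_pairs:
            if self.lipid_id[i] != self.lipid_id[j]:
                raise SystemError_("director pair spans two different lipids")

    @property
    def n_particles(self) -> int:
        return len(self.bead_role)

    @property
    def n_lipids(self) -> int:
        return len(self.leaflet_of_lipid)

    def solvent_mask(self) -> np.ndarray:
        return self.bead_role == ROLE_SOLVENT

    def head_mask(self) -> np.ndarray:
        return self.bead_role == ROLE_HEAD

    def lipid_beads(self, lipid: int) -> np.ndarray:
        return np.nonzero(self.lipid_id == lipid)[0]

    def leaflet_lipids(self, leaflet: int) -> np.ndarray:
        return np.nonzero(self.leaflet_of_lipid == leaflet)[0]


@dataclass
class ForceField:
    """Nonbonded parameters of the CG model plus integration settings.

    Pair interactions are DPD-style soft repulsions
    ``U = A_ij (1 - r/r_c)^2`` for ``r < r_c`` with role-pair amplitudes
    ``repulsion[role_i, role_j]`` (energy units, amu A^2 ps^-2), plus a
    smooth tail-tail attraction of depth ``eps_tt`` that is flat for
    ``r < attr_on`` and decays as ``-eps cos^2`` between ``attr_on`` and
    ``r_c``.  Hydrophobicity comes from the solvent-tail repulsion
    contrast; the attraction gives the bilayer its cohesion so it recovers
    after a shock passes.
    """

    repulsion: np.ndarray
    cutoff: float = 7.5
    eps_tt: float = 0.0
    attr_on: float = 4.5
    thermostat_friction: float = 1.0   # ps^-1
    timestep: float = 0.005            # ps
    max_displacement: float = 0.30     # A per step cap used by shock runs

    def __post_init__(self):
        self.repulsion = np.ascontiguousarray(self.repulsion, dtype=np.float64)
        if self.repulsion.shape != (3, 3):
            raise SystemError_("repulsion must be a 3x3 role-pair matrix")
        if not np.allclose(self.repulsion, self.repulsion.T):
            raise SystemError_("repulsion matrix must be symmetric")
        if self.timestep <= 0:
            raise SystemError_("timestep must be positive")
        if not (0 < self.attr_on < self.cutoff):
            raise SystemError_("attr_on must lie inside (0, cutoff)")

    def validate_box(self, box: np.ndarray) -> None:
        if self.cutoff > 0.5 * float(np.min(box)):
            raise SystemError_(
                f"cutoff {self.cutoff} A exceeds half the smallest box edge "
                f"({0.5 * float(np.min(box)):.2f} A)"
            )

    def content_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(self.repulsion.tobytes())
        for v in (self.cutoff, self.eps_tt, self.attr_on,
                  self.thermostat_friction, self.timestep, self.max_displacement):
            h.update(np.float64(v).tobytes())
        return h.hexdigest()[:16]


def default_forcefield(temperature: float = 310.0) -> ForceField:
    """CG force field defaults, expressed in kT at the given temperature.

    The repulsion contrast (solvent-tail >> solvent-solvent) drives the
    hydrophobic segregation; amplitudes follow the usual DPD magnitudes.
    """
    kt = KB * temperature
    a = np.empty((3, 3))
    a[ROLE_SOLVENT, ROLE_SOLVENT] = 12.5 * kt
    a[ROLE_HEAD, ROLE_HEAD] = 12.5 * kt
    a[ROLE_TAIL, ROLE_TAIL] = 12.5 * kt
    a[ROLE_SOLVENT, ROLE_HEAD] = a[ROLE_HEAD, ROLE_SOLVENT] = 12.5 * kt
    a[ROLE_SOLVENT, ROLE_TAIL] = a[ROLE_TAIL, ROLE_SOLVENT] = 40.0 * kt
    a[ROLE_HEAD, ROLE_TAIL] = a[ROLE_TAIL, ROLE_HEAD] = 25.0 * kt
    return ForceField(repulsion=a, eps_tt=1.5 * kt)
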