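"""Coarse-grained bilayer + solvent system builder.

The builder emulates the reference membrane geometry at bead-spring
resolution: a bilayer normal to z (two leaflets of ``n_lipids/2``), a
fraction of shorter/stiffer cholesterol-like lipids, and an asymmetric
explicit-solvent column (long +z pad for the wave to run into, short -z
pad where the shock slab is placed).

Bead conventions: every bead carries 72 amu (one bead ~ four waters or
one acyl-chain segment); phospholipid-like lipids are double-chained
(one head bead with two 3-bead tails, 7 beads, so the lipid volume fills
its lattice cell and the bilayer holds a realistic thickness at fixed
area), cholesterol-like lipids are shorter, stiffer single chains
(H-T1-T2).  Chain stiffness is realised by 1-3 next-nearest-neighbour
springs so all interactions stay central pair forces.
"""
from __future__ import annotations

import math

import numpy as np

from .units import KB, si_density_to_internal
from .system import (ParticleFrame, Topology,
                     ROLE_SOLVENT, ROLE_HEAD, ROLE_TAIL,
                     LEAFLET_PROXIMAL, LEAFLET_DISTAL)


class BuildError(ValueError):
    pass


BEAD_MASS = 72.0          # amu (~4 waters per solvent bead)
BOND_LENGTH = 5.0         # A
CHOL_BOND_LENGTH = 4.5    # A
MEMBRANE_SLAB = 50.0      # A of box height reserved for the bilayer
HEAD_OFFSET = 22.5        # A, head planes at z_mid +/- HEAD_OFFSET
WATER_DENSITY_KG_M3 = 1000.0


def _leaflet_grid(n_half: int) -> tuple[int, int]:
    """Near-square (nx, ny) lattice for one leaflet; exact when possible."""
    best = None
    root = math.isqrt(n_half)
    for d in range(root, 0, -1):
        if n_half % d == 0:
            best = (d, n_half // d)
            break
    if best is None or best[1] > 2 * best[0]:
        nx = math.ceil(math.sqrt(n_half))
        best = (nx, math.ceil(n_half / nx))
    return best


def build_system(n_lipids: int = 240, cholesterol_fraction: float = 0.10,
                 solvent_pad_plus_z: float = 200.0,
                 solvent_pad_minus_z: float = 30.0,
                 seed: int = 0, *,
                 temperature: float = 310.0,
                 lateral_spacing: float = 7.5,
                 bond_k_kt_per_A2: float = 20.0,
                 bend_k_kt_per_A2: float = 15.0,
                 chol_stiffness_factor: float = 3.0,
                 ) -> tuple[ParticleFrame, Topology]:
    """Build the bilayer + solvent start configuration.

    Deterministic for a fixed seed.  Returns an unequilibrated frame with
    Maxwell-Boltzmann velocities at ``temperature`` and the matching
    topology.  Pads are solvent column heights in A; the -z pad must host
    the shock slab, the +z pad gives the wave room to run.
    """
    if n_lipids < 2 or n_lipids % 2:
        raise BuildError("n_lipids must be an even count >= 2")
    if not (0.0 <= cholesterol_fraction < 1.0):
        raise BuildError("cholesterol_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    kt = KB * temperature

    n_half = n_lipids // 2
    nx, ny = _leaflet_grid(n_half)
    lx, ly = nx * lateral_spacing, ny * lateral_spacing
    lz = solvent_pad_minus_z + MEMBRANE_SLAB + solvent_pad_plus_z
    z_mid = solvent_pad_minus_z + 0.5 * MEMBRANE_SLAB

    n_chol = int(round(cholesterol_fraction * n_lipids))
    # even split of cholesterol-like lipids between the leaflets
    chol_per_leaflet = [n_chol // 2 + (1 if i < n_chol % 2 else 0) for i in range(2)]

    positions, species, molecule_id, lipid_id_arr, roles = [], [], [], [], []
    bonds, bond_r0, bond_k = [], [], []
    dir_pairs, dir_lipid = [], []
    leaflet_of_lipid = []

    k_bond = bond_k_kt_per_A2 * kt
    k_bend = bend_k_kt_per_A2 * kt

    lipid = 0
    for ileaf, leaflet in enumerate((LEAFLET_PROXIMAL, LEAFLET_DISTAL)):
        sgn = -1.0 if leaflet == LEAFLET_PROXIMAL else 1.0
        chol_ids = rng.choice(n_half, size=chol_per_leaflet[ileaf], replace=False)
        chol_set = set(int(c) for c in chol_ids)
        offset = 0.5 * lateral_spacing if leaflet == LEAFLET_DISTAL else 0.0
        placed = 0
        for gx in range(nx):
            for gy in range(ny):
                if placed >= n_half:
                    break
                is_chol = placed in chol_set
                x = (gx + 0.5) * lateral_spacing + offset
                y = (gy + 0.5) * lateral_spacing + offset
                x += rng.uniform(-0.5, 0.5)
                y += rng.uniform(-0.5, 0.5)
                bl = CHOL_BOND_LENGTH if is_chol else BOND_LENGTH
                stiff = chol_stiffness_factor if is_chol else 1.0
                first = len(positions)
                head_z = z_mid + sgn * HEAD_OFFSET
                # (x-offset, chain length) per tail chain
                chains = [(0.0, 3)] if is_chol else [(-1.9, 4), (+1.9, 4)]
                beads = [(x, y, head_z, ROLE_HEAD)]
                chain_slices = []
                for dx_c, n_tail in chains:
                    start = len(beads)
                    for t in range(n_tail):
                        beads.append((x + dx_c, y, head_z - sgn * bl * (t + 1),
                                      ROLE_TAIL))
                    chain_slices.append((start, n_tail))
                for (bx, by, bz, role) in beads:
                    positions.append((bx % lx, by % ly, bz))
                    roles.append(role)
                    if is_chol:
                        species.append("HC" if role == ROLE_HEAD else "TC")
                    else:
                        species.append("H" if role == ROLE_HEAD else "T")
                    molecule_id.append(lipid)
                    lipid_id_arr.append(lipid)
                for start, n_tail in chain_slices:
                    # head to first chain bead, then down the chain
                    prev = first
                    for t in range(n_tail):
                        cur = first + start + t
                        bonds.append((prev, cur))
                        bond_r0.append(bl)
                        bond_k.append(k_bond * stiff)
                        prev = cur
                    # 1-3 stiffening springs along head+chain
                    path = [first] + [first + start + t for t in range(n_tail)]
                    for a in range(len(path) - 2):
                        bonds.append((path[a], path[a + 2]))
                        bond_r0.append(2.0 * bl)
                        bond_k.append(k_bend * stiff)
                    # directors: consecutive tail-bead bond vectors
                    for t in range(n_tail - 1):
                        dir_pairs.append((first + start + t, first + start + t + 1))
                        dir_lipid.append(lipid)
                leaflet_of_lipid.append(leaflet)
                lipid += 1
                placed += 1

    # ---- solvent ------------------------------------------------------
    rho_n = si_density_to_internal(WATER_DENSITY_KG_M3) / BEAD_MASS  # beads/A^3
    s = rho_n ** (-1.0 / 3.0)
    mol = lipid
    regions = [(0.0, solvent_pad_minus_z), (z_mid + 0.5 * MEMBRANE_SLAB, lz)]
    for zlo, zhi in regions:
        h = zhi - zlo
        if h <= 0:
            continue
        n_target = int(round(rho_n * lx * ly * h))
        if h < 0.5 * s or n_target < 1:
            raise BuildError(
                f"solvent pad of {h:.1f} A is too thin to host a solvent layer"
            )
        # ceil grid (always at least the target count), then drop the
        # surplus at random so the pad density matches rho_n exactly
        nzx = max(1, math.ceil(lx / s))
        nzy = max(1, math.ceil(ly / s))
        nzz = max(1, math.ceil(h / s))
        sites = []
        for iz in range(nzz):
            for ix in range(nzx):
                for iy in range(nzy):
                    sites.append((ix, iy, iz))
        keep = np.ones(len(sites), dtype=bool)
        surplus = len(sites) - n_target
        if surplus > 0:
            keep[rng.choice(len(sites), size=surplus, replace=False)] = False
        for (ix, iy, iz), used in zip(sites, keep):
            if not used:
                continue
            x = (ix + 0.5) * lx / nzx + rng.uniform(-0.3, 0.3)
            y = (iy + 0.5) * ly / nzy + rng.uniform(-0.3, 0.3)
            z = zlo + (iz + 0.5) * h / nzz + rng.uniform(-0.3, 0.3)
            positions.append((x % lx, y % ly, min(max(z, zlo), zhi - 1e-6)))
            roles.append(ROLE_SOLVENT)
            species.append("W")
            molecule_id.append(mol)
            lipid_id_arr.append(-1)
            mol += 1

    n = len(positions)
    masses = np.full(n, BEAD_MASS)
    velocities = rng.standard_normal((n, 3)) * np.sqrt(kt / BEAD_MASS)
    velocities -= (masses[:, None] * velocities).sum(0) / masses.sum()

    frame = ParticleFrame(
        positions=np.array(positions), velocities=velocities, masses=masses,
        species=np.array(species), molecule_id=np.array(molecule_id),
        box=np.array([lx, ly, lz]), time=0.0,
    )
    topo = Topology(
        bead_role=np.array(roles), bonds=np.array(bonds, dtype=np.int64),
        bond_r0=np.array(bond_r0), bond_k=np.array(bond_k),
        lipid_id=np.array(lipid_id_arr),
        leaflet_of_lipid=np.array(leaflet_of_lipid),
        director_pairs=np.array(dir_pairs, dtype=np.int64),
        director_lipid=np.array(dir_lipid, dtype=np.int64),
        director_kind="chain",
    )
    return frame, topo


def assign_leaflets(frame: ParticleFrame, topology: Topology) -> np.ndarray:
    """Re-assign leaflets by the sign of (head z - head z-median).

    The median split is robust to whole-membrane drift during
    equilibration; returns the new per-lipid leaflet array (also written
    into the topology).
    """
    heads = np.nonzero(topology.head_mask())[0]
    z = frame.positions[heads, 2]
    mid = np.median(z)
    new = topology.leaflet_of_lipid.copy()
    for idx, zh in zip(heads, z):
        lip = topology.lipid_id[idx]
        new[lip] = LEAFLET_PROXIMAL if zh < mid else LEAFLET_DISTAL
    if not ((new == LEAFLET_PROXIMAL).any() and (new == LEAFLET_DISTAL).any()):
        raise BuildError("leaflet assignment failed to produce two leaflets")
    topology.leaflet_of_lipid = new
    return new
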