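"""Pairwise forces of the CG model.

Every interaction is a central pair force (soft repulsion, tail-tail
attraction, harmonic 1-2 and 1-3 springs), so Newton's third law, the
scalar virial and the Irving-Kirkwood apportionment of the local pressure
are all exact by construction.  The production path uses numba cell lists;
``compute_forces_brute`` is an independent pure-numpy O(N^2) oracle kept
for correctness tests.
"""
from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from numba import njit

from .system import ParticleFrame, Topology, ForceField, ROLE_TAIL


@dataclass
class ForceResult:
    forces: np.ndarray
    potential: float
    virial: float  # sum over pairs of r_ij . f_ij


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_eg(r, ri, rj, A, rc, eps_tt, attr_on):
    """Energy and fr = -dU/dr for one pair at distance r (roles ri, rj)."""
    e = 0.0
    fr = 0.0
    if r < rc:
        a = A[ri, rj]
        x = 1.0 - r / rc
        e += a * x * x
        fr += 2.0 * a * x / rc
        if ri == ROLE_TAIL and rj == ROLE_TAIL and eps_tt > 0.0:
            if r < attr_on:
                e += -eps_tt
            else:
                w = rc - attr_on
                t = 0.5 * math.pi * (r - attr_on) / w
                c = math.cos(t)
                e += -eps_tt * c * c
                fr += -eps_tt * math.sin(2.0 * t) * 0.5 * math.pi / w
    return e, fr


@njit(cache=True)
def _minimg(d, L):
    return d - L * round(d / L)


@njit(cache=True)
def _nonbonded_allpairs(pos, box, roles, A, rc, eps_tt, attr_on, forces):
    n = pos.shape[0]
    pot = 0.0
    vir = 0.0
    rc2 = rc * rc
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
            dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
            dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 0.0:
                r = math.sqrt(r2)
                e, fr = _pair_eg(r, roles[i], roles[j], A, rc, eps_tt, attr_on)
                pot += e
                vir += fr * r
                g = fr / r
                forces[i, 0] += g * dx
                forces[i, 1] += g * dy
                forces[i, 2] += g * dz
                forces[j, 0] -= g * dx
                forces[j, 1] -= g * dy
                forces[j, 2] -= g * dz
    return pot, vir


@njit(cache=True)
def _build_cells(pos, box, ncells):
    n = pos.shape[0]
    ncx, ncy, ncz = ncells
    ntot = ncx * ncy * ncz
    head = np.full(ntot, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = int(math.floor(pos[i, 0] / box[0] * ncx)) % ncx
        cy = int(math.floor(pos[i, 1] / box[1] * ncy)) % ncy
        cz = int(math.floor(pos[i, 2] / box[2] * ncz)) % ncz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@njit(cache=True)
def _nonbonded_cells(pos, box, roles, A, rc, eps_tt, attr_on, ncells, forces):
    ncx, ncy, ncz = ncells
    head, nxt = _build_cells(pos, box, ncells)
    pot = 0.0
    vir = 0.0
    rc2 = rc * rc
    # half-shell of 13 neighbour offsets + the self cell
    offs = np.array([
        (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
        (1, -1, -1), (1, -1, 0), (1, -1, 1),
        (1, 0, -1), (1, 0, 0), (1, 0, 1),
        (1, 1, -1), (1, 1, 0), (1, 1, 1),
    ], dtype=np.int64)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                # pairs within the cell
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
                        dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
                        dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2 and r2 > 0.0:
                            r = math.sqrt(r2)
                            e, fr = _pair_eg(r, roles[i], roles[j], A, rc,
                                             eps_tt, attr_on)
                            pot += e
                            vir += fr * r
                            g = fr / r
                            forces[i, 0] += g * dx
                            forces[i, 1] += g * dy
                            forces[i, 2] += g * dz
                            forces[j, 0] -= g * dx
                            forces[j, 1] -= g * dy
                            forces[j, 2] -= g * dz
                        j = nxt[j]
                    i = nxt[i]
                # pairs with half-shell neighbour cells
                for k in range(13):
                    nx = (cx + offs[k, 0]) % ncx
                    ny = (cy + offs[k, 1]) % ncy
                    nz = (cz + offs[k, 2]) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    i = head[c]
                    while i >= 0:
                        j = head[c2]
                        while j >= 0:
                            dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
                            dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
                            dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2 and r2 > 0.0:
                                r = math.sqrt(r2)
                                e, fr = _pair_eg(r, roles[i], roles[j], A, rc,
                                                 eps_tt, attr_on)
                                pot += e
                                vir += fr * r
                                g = fr / r
                                forces[i, 0] += g * dx
                                forces[i, 1] += g * dy
                                forces[i, 2] += g * dz
                                forces[j, 0] -= g * dx
                                forces[j, 1] -= g * dy
                                forces[j, 2] -= g * dz
                            j = nxt[j]
                        i = nxt[i]
    return pot, vir


@njit(cache=True)
def _bonded(pos, box, bonds, bond_k, bond_r0, forces):
    pot = 0.0
    vir = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
        dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
        dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        d = r - bond_r0[b]
        pot += 0.5 * bond_k[b] * d * d
        fr = -bond_k[b] * d
        vir += fr * r
        g = fr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return pot, vir


@njit(cache=True, inline="always")
def _deposit_segment(zi, dz, w, binw, nbins, Lz, bins):
    """Spread weight w over z-bins by fractional overlap of the i->j segment."""
    if abs(dz) < 1e-12:
        b = int((zi % Lz) / binw) % nbins
        bins[b] += w
        return
    z0 = zi
    z1 = zi + dz
    if z1 < z0:
        z0, z1 = z1, z0
    seg = z1 - z0
    b0 = int(math.floor(z0 / binw))
    b1 = int(math.floor((z1 - 1e-12) / binw))
    for b in range(b0, b1 + 1):
        lo = max(z0, b * binw)
        hi = min(z1, (b + 1) * binw)
        if hi > lo:
            bins[b % nbins] += w * (hi - lo) / seg


@njit(cache=True)
def _pair_virial_bins(pos, box, roles, A, rc, eps_tt, attr_on,
                      bonds, bond_k, bond_r0, binw, nbins):
    """Per-z-bin pair-virial sum (1/3) r_ij.f_ij, Irving-Kirkwood apportioned."""
    n = pos.shape[0]
    Lz = box[2]
    bins = np.zeros(nbins)
    rc2 = rc * rc
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
            dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
            dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 0.0:
                r = math.sqrt(r2)
                e, fr = _pair_eg(r, roles[i], roles[j], A, rc, eps_tt, attr_on)
                if fr != 0.0:
                    zi = pos[i, 2] % Lz
                    _deposit_segment(zi, -dz, fr * r / 3.0, binw, nbins, Lz, bins)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _minimg(pos[i, 0] - pos[j, 0], box[0])
        dy = _minimg(pos[i, 1] - pos[j, 1], box[1])
        dz = _minimg(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        fr = -bond_k[b] * (r - bond_r0[b])
        zi = pos[i, 2] % Lz
        _deposit_segment(zi, -dz, fr * r / 3.0, binw, nbins, Lz, bins)
    return bins


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _cell_counts(box: np.ndarray, cutoff: float) -> tuple:
    return tuple(int(box[d] // cutoff) for d in range(3))


def compute_forces(frame: ParticleFrame, topology: Topology, ff: ForceField,
                   method: str = "auto") -> ForceResult:
    """Total forces, potential energy and scalar pair virial.

    ``method``: 'auto' picks cell lists when every box dimension holds at
    least three cells, otherwise the all-pairs kernel; 'cells'/'allpairs'
    force a path.
    """
    ff.validate_box(frame.box)
    pos = frame.positions
    roles = topology.bead_role.astype(np.int64)
    forces = np.zeros_like(pos)
    nc = _cell_counts(frame.box, ff.cutoff)
    use_cells = method == "cells" or (method == "auto" and min(nc) >= 3)
    if use_cells:
        pot, vir = _nonbonded_cells(pos, frame.box, roles, ff.repulsion,
                                    ff.cutoff, ff.eps_tt, ff.attr_on,
                                    np.asarray(nc, dtype=np.int64), forces)
    else:
        pot, vir = _nonbonded_allpairs(pos, frame.box, roles, ff.repulsion,
                                       ff.cutoff, ff.eps_tt, ff.attr_on, forces)
    if len(topology.bonds):
        pb, vb = _bonded(pos, frame.box, topology.bonds,
                         topology.bond_k, topology.bond_r0, forces)
        pot += pb
        vir += vb
    return ForceResult(forces=forces, potential=pot, virial=vir)


def pair_virial_profile(frame: ParticleFrame, topology: Topology,
                        ff: ForceField, bin_width: float) -> np.ndarray:
    """Per-bin pair-virial contribution (1/3) sum r_ij.f_ij along z."""
    nbins = int(round(frame.box[2] / bin_width))
    if abs(nbins * bin_width - frame.box[2]) > 1e-9 * frame.box[2]:
        raise ValueError("bin_width must divide the box length along z")
    roles = topology.bead_role.astype(np.int64)
    bonds = topology.bonds if len(topology.bonds) else np.zeros((0, 2), np.int64)
    return _pair_virial_bins(frame.positions, frame.box, roles, ff.repulsion,
                             ff.cutoff, ff.eps_tt, ff.attr_on,
                             bonds, topology.bond_k, topology.bond_r0,
                             bin_width, nbins)


def compute_forces_brute(frame: ParticleFrame, topology: Topology,
                         ff: ForceField) -> ForceResult:
    """Pure-numpy all-pairs reference, independent of the numba kernels.

    O(N^2) memory; test oracle only.
    """
    pos = frame.positions
    box = frame.box
    n = len(pos)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box[None, None, :] * np.round(d / box[None, None, :])
    r = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(r, np.inf)
    roles = topology.bead_role.astype(int)
    a = ff.repulsion[roles[:, None], roles[None, :]]
    rc = ff.cutoff
    inside = r < rc
    x = np.where(inside, 1.0 - r / rc, 0.0)
    pot = 0.5 * np.sum(a * x**2 * inside)
    fr = np.where(inside, 2.0 * a * x / rc, 0.0)
    # tail-tail attraction
    tt = (roles[:, None] == ROLE_TAIL) & (roles[None, :] == ROLE_TAIL)
    if ff.eps_tt > 0:
        w = rc - ff.attr_on
        t = 0.5 * np.pi * np.clip(np.where(np.isfinite(r), r, rc) - ff.attr_on,
                                  0.0, w) / w
        att_zone = inside & tt & (r >= ff.attr_on)
        flat_zone = tt & (r < ff.attr_on)
        pot += 0.5 * np.sum(np.where(att_zone, -ff.eps_tt * np.cos(t)**2, 0.0))
        pot += 0.5 * np.sum(np.where(flat_zone, -ff.eps_tt, 0.0))
        fr = fr + np.where(att_zone,
                           -ff.eps_tt * np.sin(2 * t) * 0.5 * np.pi / w, 0.0)
    with np.errstate(invalid="ignore"):
        g = np.where(inside, fr / r, 0.0)
    forces = np.einsum("ij,ijk->ik", g, d)
    vir = 0.5 * np.sum(fr * np.where(inside, r, 0.0))
    # bonds
    for b in range(len(topology.bonds)):
        i, j = topology.bonds[b]
        dv = pos[i] - pos[j]
        dv -= box * np.round(dv / box)
        rb = np.linalg.norm(dv)
        if rb == 0:
            continue
        pot += 0.5 * topology.bond_k[b] * (rb - topology.bond_r0[b])**2
        frb = -topology.bond_k[b] * (rb - topology.bond_r0[b])
        vir += frb * rb
        forces[i] += frb / rb * dv
        forces[j] -= frb / rb * dv
    return ForceResult(forces=forces, potential=float(pot), virial=float(vir))
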