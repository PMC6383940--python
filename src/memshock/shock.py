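"""Momentum-impulse shock prescription.

A planar shock pulse is injected by adding a uniform velocity increment
``dv_z`` to the z-velocities of every solvent molecule inside a slab of
thickness ``L_w`` adjacent to the membrane.  The prescription is fully
determined by the pressure impulse ``I`` (the time integral of pressure,
equivalently the momentum delivered per unit area), the slab thickness
and the water density ``rho``:

    dv_z = I / (rho * L_w)          added velocity
    t_p  = L_w / dv_z               nominal pulse duration (square-wave)
    P_n  = rho * dv_z**2            nominal peak pressure
    gamma = 1 / t_p                 loading rate

so that identically ``P_n * t_p == I``.  These nominal quantities
characterise the injected pulse; the actual pressure profile steepens
into a triangular front as the wave propagates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .system import ParticleFrame, Topology


class ShockDomainError(ValueError):
    """A shock-protocol argument is outside its physical domain."""


class SlabRangeError(ValueError):
    """Requested shock slab does not lie inside the simulation box."""


class EmptySlabWarning(UserWarning):
    pass


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ShockDomainError(f"{name} must be strictly positive, got {value!r}")


def added_velocity(impulse: float, density: float, slab_thickness: float) -> float:
    """Velocity increment dv_z = I/(rho L_w) given SI arguments (Pa s, kg/m3, m).

    Returns m/s.  Pure function; raises :class:`ShockDomainError` on
    non-positive input.
    """
    _require_positive("impulse", impulse)
    _require_positive("density", density)
    _require_positive("slab_thickness", slab_thickness)
    return impulse / (density * slab_thickness)


def nominal_pulse_duration(slab_thickness: float, added_velocity: float) -> float:
    """t_p = L_w / dv_z, the slab passing time under the square-wave picture (s)."""
    _require_positive("slab_thickness", slab_thickness)
    _require_positive("added_velocity", added_velocity)
    return slab_thickness / added_velocity


def nominal_peak_pressure(density: float, added_velocity: float) -> float:
    """P_n = rho dv_z^2, order-of-magnitude estimate of the pulse peak (Pa)."""
    _require_positive("density", density)
    if added_velocity < 0:
        raise ShockDomainError("added_velocity must be non-negative")
    return density * added_velocity**2


def loading_rate(pulse_duration: float) -> float:
    """gamma = 1/t_p (s^-1)."""
    _require_positive("pulse_duration", pulse_duration)
    return 1.0 / pulse_duration


@dataclass(frozen=True)
class ShockSpec:
    """An impulse/slab prescription with its derived nominal quantities.

    Stored in SI: impulse (Pa s), slab_thickness and gap (m), water_density
    (kg/m^3).  ``gap`` is the distance between the slab's membrane-proximal
    face and the proximal head-group density peak.
    """

    impulse: float
    slab_thickness: float
    gap: float = 5e-10
    water_density: float = 1000.0

    def __post_init__(self):
        _require_positive("impulse", self.impulse)
        _require_positive("slab_thickness", self.slab_thickness)
        _require_positive("water_density", self.water_density)
        if self.gap < 0:
            raise ShockDomainError("gap must be non-negative")

    # -- derived nominal quantities (SI) -------------------------------
    @property
    def added_velocity(self) -> float:
        """dv_z in m/s."""
        return added_velocity(self.impulse, self.water_density, self.slab_thickness)

    @property
    def pulse_duration(self) -> float:
        """t_p in s."""
        return nominal_pulse_duration(self.slab_thickness, self.added_velocity)

    @property
    def peak_pressure(self) -> float:
        """P_n in Pa."""
        return nominal_peak_pressure(self.water_density, self.added_velocity)

    @property
    def loading_rate(self) -> float:
        """gamma in s^-1."""
        return loading_rate(self.pulse_duration)

    # -- convenience in report units -----------------------------------
    @property
    def impulse_mPa_s(self) -> float:
        return self.impulse * 1e3

    @property
    def slab_thickness_A(self) -> float:
        return self.slab_thickness / units.ANGSTROM_M

    @property
    def gap_A(self) -> float:
        return self.gap / units.ANGSTROM_M

    @property
    def added_velocity_A_ps(self) -> float:
        return self.added_velocity / units.VELOCITY_INTERNAL_M_S

    @property
    def pulse_duration_ps(self) -> float:
        return self.pulse_duration / units.PS_S

    @property
    def peak_pressure_GPa(self) -> float:
        return self.peak_pressure * 1e-9

    @property
    def loading_rate_per_ps(self) -> float:
        return self.loading_rate * units.PS_S

    # -- construction / serialization ----------------------------------
    @classmethod
    def from_angstrom(cls, impulse_mPa_s: float, slab_thickness_A: float,
                      gap_A: float = 5.0, water_density_kg_m3: float = 1000.0
                      ) -> "ShockSpec":
        return cls(
            impulse=impulse_mPa_s * 1e-3,
            slab_thickness=slab_thickness_A * units.ANGSTROM_M,
            gap=gap_A * units.ANGSTROM_M,
            water_density=water_density_kg_m3,
        )

    @classmethod
    def from_config(cls, config: dict) -> "ShockSpec":
        return cls.from_angstrom(
            impulse_mPa_s=float(config["impulse_mPa_s"]),
            slab_thickness_A=float(config["slab_thickness_A"]),
            gap_A=float(config.get("gap_A", 5.0)),
            water_density_kg_m3=float(config.get("water_density_kg_m3", 1000.0)),
        )

    def to_config(self) -> dict:
        """Config block; derived nominal quantities emitted read-only."""
        return {
            "impulse_mPa_s": self.impulse_mPa_s,
            "slab_thickness_A": self.slab_thickness_A,
            "gap_A": self.gap_A,
            "water_density_kg_m3": self.water_density,
            "derived": {
                "added_velocity_m_s": self.added_velocity,
                "pulse_duration_ps": self.pulse_duration_ps,
                "peak_pressure_GPa": self.peak_pressure_GPa,
                "loading_rate_per_ps": self.loading_rate_per_ps,
            },
        }


def select_slab(frame: ParticleFrame, topology: Topology,
                slab_start_z: float, slab_thickness: float) -> np.ndarray:
    """Bead indices of all solvent molecules whose centre of mass lies in
    ``[slab_start_z, slab_start_z + L_w)`` (internal units, A).

    Whole molecules are selected, never partial ones, so the injected
    momentum never stretches intramolecular bonds.  Non-solvent beads are
    never selected.  A zero-thickness slab is a valid empty interval.
    """
    if slab_thickness < 0:
        raise ShockDomainError("slab_thickness must be non-negative")
    lz = float(frame.box[2])
    if slab_start_z < 0 or slab_start_z + slab_thickness > lz:
        raise SlabRangeError(
            f"slab [{slab_start_z:.2f}, {slab_start_z + slab_thickness:.2f}) A "
            f"outside box [0, {lz:.2f}) along z"
        )
    solv = topology.solvent_mask()
    if slab_thickness == 0 or not solv.any():
        out = np.empty(0, dtype=np.int64)
    else:
        z = frame.positions[:, 2]
        m = frame.masses
        mol = frame.molecule_id
        # centre of mass z per solvent molecule
        solv_idx = np.nonzero(solv)[0]
        mols, inverse = np.unique(mol[solv_idx], return_inverse=True)
        mz = np.bincount(inverse, weights=m[solv_idx] * z[solv_idx])
        mm = np.bincount(inverse, weights=m[solv_idx])
        com_z = mz / mm
        inside = (com_z >= slab_start_z) & (com_z < slab_start_z + slab_thickness)
        chosen = set(mols[inside].tolist())
        out = solv_idx[np.fromiter((mol[i] in chosen for i in solv_idx),
                                   dtype=bool, count=len(solv_idx))]
    if len(out) == 0:
        warnings.warn("shock slab selection is empty", EmptySlabWarning)
    return out


def zero_net_momentum(frame: ParticleFrame) -> ParticleFrame:
    """Return a copy with the centre-of-mass velocity removed.

    Applied immediately before the shock so the imparted momentum is
    unambiguous against any drift accumulated during equilibration.
    """
    out = frame.copy()
    v_com = out.momentum() / out.masses.sum()
    out.velocities -= v_com[None, :]
    return out


def apply_shock(frame: ParticleFrame, spec: ShockSpec,
                slab_ids: np.ndarray) -> ParticleFrame:
    """Add dv_z to the z-velocity of every bead in ``slab_ids``.

    Positions are untouched; the total z-momentum increases by exactly
    ``sum(m_i) * dv_z``, which equals ``I * A`` when the slab carries mass
    ``rho * L_w * A``.
    """
    slab_ids = np.asarray(slab_ids, dtype=np.int64)
    if slab_ids.size == 0:
        raise ShockDomainError("cannot apply a shock to an empty slab")
    if not np.all(np.isfinite(frame.velocities)):
        raise ShockDomainError("frame has non-finite velocities")
    out = frame.copy()
    out.velocities[slab_ids, 2] += spec.added_velocity_A_ps
    return out
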