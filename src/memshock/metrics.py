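"""Membrane-response analysis suite.

Thickness from head-group density peaks, maximal compressive strain,
instantaneous orientational order parameter, area per lipid, global and
local (Irving-Kirkwood) virial pressure, moving averages and shock-speed
estimation from tracked pressure-front positions.

The order-parameter operator is director-agnostic: directors come from
the topology.  With genuine C-H pairs (``director_kind='ch'``) it is the
textbook -S_CD = -<(3 cos^2 theta - 1)/2>.  The CG model has no
hydrogens; its directors are consecutive tail-bead bonds, and the
C-H-equivalent order parameter follows from the axial-symmetry relation
S_CH = -S_chain/2 (methylene C-H bonds are distributed uniformly about
the local chain axis), so -S_CD = <P2(cos theta_chain)>/2, which keeps
the reported quantity on the conventional scale with maximum 1/2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .units import internal_pressure_to_gpa
from .system import (ParticleFrame, Topology, ForceField,
                     LEAFLET_PROXIMAL, LEAFLET_DISTAL)
from .forces import compute_forces, pair_virial_profile


class MetricError(ValueError):
    """Raised when a metric is not resolvable from the given frame."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    bin_centers: np.ndarray
    density: np.ndarray           # per-A^3 (count or mass, see weighting)
    bin_width: float
    selection: str = ""

    def integral(self, lateral_area: float) -> float:
        return float(self.density.sum() * self.bin_width * lateral_area)


@dataclass
class MetricSeries:
    times: np.ndarray
    values: np.ndarray
    name: str
    smoothed: Optional[np.ndarray] = None
    window: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise MetricError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise MetricError("times must be strictly increasing")


@dataclass
class PressureProfile:
    bin_centers: np.ndarray
    pressure: np.ndarray          # GPa
    bin_width: float
    time: float


@dataclass
class ShockSpeedFit:
    speed_A_ps: float
    r_squared: float
    method: str                   # 'least-squares' or 'theil-sen'
    peak_times: np.ndarray = field(default=None, repr=False)
    peak_positions: np.ndarray = field(default=None, repr=False)

    @property
    def speed_km_s(self) -> float:
        return self.speed_A_ps * 0.1


# ---------------------------------------------------------------------------
# density & thickness
# ---------------------------------------------------------------------------

def density_profile(frame: ParticleFrame, selection: np.ndarray,
                    bin_width: float, mass_weighted: bool = False,
                    label: str = "") -> DensityProfile:
    """z histogram of the selected particles, normalised per unit volume.

    The integral of the profile over z times the lateral area recovers the
    selected count (or mass when ``mass_weighted``).
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise MetricError("empty selection")
    if bin_width <= 0:
        raise MetricError("bin_width must be positive")
    lz = float(frame.box[2])
    nbins = max(1, int(np.ceil(lz / bin_width)))
    z = np.mod(frame.positions[selection, 2], lz)
    w = frame.masses[selection] if mass_weighted else None
    counts, edges = np.histogram(z, bins=nbins, range=(0.0, nbins * bin_width),
                                 weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vol = frame.lateral_area * bin_width
    return DensityProfile(bin_centers=centers, density=counts / vol,
                          bin_width=bin_width, selection=label)


def _refine_peak(centers: np.ndarray, values: np.ndarray) -> float:
    """Peak position with 3-point parabolic sub-bin refinement."""
    m = int(np.argmax(values))
    if m == 0 or m == len(values) - 1:
        return float(centers[m])
    y0, y1, y2 = values[m - 1], values[m], values[m + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[m])
    delta = 0.5 * (y0 - y2) / denom
    step = centers[1] - centers[0]
    return float(centers[m] + np.clip(delta, -0.5, 0.5) * step)


def head_peak_positions(frame: ParticleFrame, topology: Topology,
                        bin_width: float = 1.0) -> tuple[float, float]:
    """(proximal, distal) head-group density-peak z positions.

    Leaflets are split at the head-bead z-median, which is robust to
    whole-membrane drift.
    """
    heads = np.nonzero(topology.head_mask())[0]
    if heads.size == 0:
        raise MetricError("topology has no head beads")
    z = np.mod(frame.positions[heads, 2], frame.box[2])
    mid = float(np.median(z))
    lower = heads[z < mid]
    upper = heads[z >= mid]
    if lower.size == 0 or upper.size == 0:
        raise MetricError("fewer than two head-density peaks resolvable")
    peaks = []
    for side in (lower, upper):
        prof = density_profile(frame, side, bin_width, label="heads")
        m = int(np.argmax(prof.density))
        neighbours = prof.density[max(0, m - 1)] + prof.density[
            min(len(prof.density) - 1, m + 1)]
        if neighbours < 0.05 * prof.density[m]:
            # degenerate single-bin peak: the parabola carries no sub-bin
            # information, use the mean position inside the peak bin
            zs = np.mod(frame.positions[side, 2], frame.box[2])
            edge = prof.bin_centers[m] - 0.5 * bin_width
            inside = (zs >= edge) & (zs < edge + bin_width)
            peaks.append(float(np.mean(zs[inside])))
        else:
            peaks.append(_refine_peak(prof.bin_centers, prof.density))
    return min(peaks), max(peaks)


def membrane_thickness(frame: ParticleFrame, topology: Topology,
                       bin_width: float = 1.0) -> float:
    """Distance between the two head-group density peaks (A)."""
    lo, hi = head_peak_positions(frame, topology, bin_width)
    if hi <= lo:
        raise MetricError("head-density peaks are not separated")
    return hi - lo


def thickness_series(frames: Sequence[ParticleFrame], topology: Topology,
                     bin_width: float = 1.0) -> MetricSeries:
    return MetricSeries(
        times=[f.time for f in frames],
        values=[membrane_thickness(f, topology, bin_width) for f in frames],
        name="thickness_A",
    )


def max_compressive_strain(series: MetricSeries,
                           reference_thickness: float) -> float:
    """max over t of (h_ref - h(t)) / h_ref; negative if only thickening."""
    if reference_thickness <= 0:
        raise MetricError("reference_thickness must be positive")
    if len(series.values) == 0:
        raise MetricError("empty thickness series")
    return float(np.max((reference_thickness - series.values)
                        / reference_thickness))


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def instantaneous_order_parameter(frame: ParticleFrame, topology: Topology,
                                  leaflet: Optional[int] = None) -> float:
    """-<(3 cos^2 theta - 1)/2> over the (filtered) director pairs.

    theta is the instantaneous angle between each director vector and the
    membrane normal (z).  Range [-1, 1/2]: 1/2 for directors in the x-y
    plane, -1 for directors along z, 0 at the magic angle.  Zero-length
    directors are excluded (with a warning carrying the count).
    """
    pairs = topology.director_pairs
    if leaflet is not None:
        keep = topology.leaflet_of_lipid[topology.director_lipid] == leaflet
        pairs = pairs[keep]
    if len(pairs) == 0:
        raise MetricError("no director pairs in the filtered set")
    d = frame.positions[pairs[:, 1]] - frame.positions[pairs[:, 0]]
    d -= frame.box[None, :] * np.round(d / frame.box[None, :])
    norm = np.linalg.norm(d, axis=1)
    ok = norm > 1e-12
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"excluded {n_bad} zero-length director(s)")
        if not ok.any():
            raise MetricError("all director vectors have zero length")
    cos2 = (d[ok, 2] / norm[ok]) ** 2
    return float(-np.mean(1.5 * cos2 - 0.5))


def order_parameter_sch(frame: ParticleFrame, topology: Topology,
                        leaflet: Optional[int] = None) -> float:
    """-S_CD on the conventional C-H scale (max 1/2).

    For 'ch' directors this is the raw operator; for 'chain' directors the
    axial-symmetry mapping -S_CD = <P2(cos theta_chain)>/2 is applied.
    """
    raw = instantaneous_order_parameter(frame, topology, leaflet)
    if topology.director_kind == "ch":
        return raw
    return -0.5 * raw


def order_series(frames: Sequence[ParticleFrame], topology: Topology,
                 leaflet: Optional[int] = None) -> MetricSeries:
    tag = {LEAFLET_PROXIMAL: "proximal", LEAFLET_DISTAL: "distal",
           None: "bilayer"}[leaflet]
    return MetricSeries(
        times=[f.time for f in frames],
        values=[order_parameter_sch(f, topology, leaflet) for f in frames],
        name=f"neg_scd_{tag}",
    )


# ---------------------------------------------------------------------------
# area per lipid
# ---------------------------------------------------------------------------

STEROL_HEAD_SPECIES = ("HC", "CHL")


def area_per_lipid(frame: ParticleFrame, topology: Topology,
                   exclude_sterol: bool = False) -> float:
    """Lx*Ly divided by the lipids per leaflet (averaged over leaflets).

    ``exclude_sterol=True`` removes cholesterol-like lipids from the
    denominator (the per-phospholipid convention).
    """
    counts = []
    for leaf in (LEAFLET_PROXIMAL, LEAFLET_DISTAL):
        lipids = topology.leaflet_lipids(leaf)
        if exclude_sterol:
            keep = []
            for lip in lipids:
                beads = topology.lipid_beads(lip)
                head = beads[topology.bead_role[beads] == 1]
                sp = str(frame.species[head[0]]) if head.size else ""
                if sp not in STEROL_HEAD_SPECIES:
                    keep.append(lip)
            lipids = np.asarray(keep)
        if len(lipids) == 0:
            raise MetricError("empty leaflet in area-per-lipid denominator")
        counts.append(len(lipids))
    return frame.lateral_area / float(np.mean(counts))


# ---------------------------------------------------------------------------
# pressure
# ---------------------------------------------------------------------------

def mean_pressure(frame: ParticleFrame, topology: Topology,
                  ff: ForceField) -> float:
    """Global virial pressure of the box in GPa.

    P = (2 KE / 3 + W / 3) / V with W the minimum-image pair virial
    (nonbonded + springs).  Positive = compression.
    """
    res = compute_forces(frame, topology, ff)
    p_int = (2.0 * frame.kinetic_energy() / 3.0 + res.virial / 3.0) / frame.volume
    return internal_pressure_to_gpa(p_int)


def local_pressure_profile(frame: ParticleFrame, topology: Topology,
                           ff: ForceField, bin_width: float = 5.0,
                           streaming_corrected: bool = False
                           ) -> PressureProfile:
    """Local pressure P(z) in GPa on bins of ``bin_width``.

    Kinetic contributions are assigned to the particle's bin; the pair
    virial is apportioned to bins by the fractional overlap of each i-j
    segment (Irving-Kirkwood).  The volume-weighted bin average equals the
    global virial pressure exactly.  With ``streaming_corrected`` the
    kinetic term uses velocities peculiar to each bin's mass-weighted
    streaming velocity, separating thermal pressure from bulk flow.
    """
    if bin_width <= 0:
        raise MetricError("bin_width must be positive")
    lz = float(frame.box[2])
    nbins = int(round(lz / bin_width))
    if abs(nbins * bin_width - lz) > 1e-9 * lz:
        raise MetricError("bin_width must divide the box height")
    z = np.mod(frame.positions[:, 2], lz)
    ibin = np.minimum((z / bin_width).astype(int), nbins - 1)
    v = frame.velocities
    m = frame.masses
    if streaming_corrected:
        mom = np.zeros((nbins, 3))
        mass = np.zeros(nbins)
        np.add.at(mom, ibin, m[:, None] * v)
        np.add.at(mass, ibin, m)
        u = np.zeros((nbins, 3))
        nz = mass > 0
        u[nz] = mom[nz] / mass[nz, None]
        pec = v - u[ibin]
        ke_term = (m[:, None] * pec**2).sum(1) / 3.0
    else:
        ke_term = (m[:, None] * v**2).sum(1) / 3.0
    kin = np.zeros(nbins)
    np.add.at(kin, ibin, ke_term)
    vir = pair_virial_profile(frame, topology, ff, bin_width)
    vbin = frame.lateral_area * bin_width
    p = internal_pressure_to_gpa((kin + vir) / vbin)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return PressureProfile(bin_centers=centers, pressure=p,
                           bin_width=bin_width, time=frame.time)


def pressure_series(frames: Sequence[ParticleFrame], topology: Topology,
                    ff: ForceField) -> MetricSeries:
    return MetricSeries(
        times=[f.time for f in frames],
        values=[mean_pressure(f, topology, ff) for f in frames],
        name="pressure_GPa",
    )


# ---------------------------------------------------------------------------
# smoothing & shock speed
# ---------------------------------------------------------------------------

def moving_average(series: MetricSeries, window: float = 0.25) -> MetricSeries:
    """Centred boxcar over samples within +/- window/2.

    Edges use the truncated window (no padding), so the smoothed series
    has the same length as the raw one.
    """
    t = series.times
    if len(t) > 1:
        min_dt = float(np.min(np.diff(t)))
        if window < min_dt:
            raise MetricError(
                f"window {window} ps smaller than sample spacing {min_dt} ps")
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return MetricSeries(times=t, values=series.values, name=series.name,
                        smoothed=smoothed, window=window)


def response_time(series: MetricSeries, window: float = 0.25,
                  drop: Optional[float] = None,
                  depth_fraction: float = 0.5) -> float:
    """Onset time of a downward response, relative to the series start.

    With ``drop`` set, returns the first time the smoothed series falls
    ``drop`` (absolute units) below its initial value; otherwise the first
    crossing of ``depth_fraction`` of the maximal depression.  Either way
    the onset localises the response even when slow monotone drift places
    the literal global minimum at the end of the record; ``inf`` when the
    absolute threshold is never reached.
    """
    sm = moving_average(series, window) if len(series.times) > 2 else series
    vals = sm.smoothed if sm.smoothed is not None else sm.values
    base = vals[0]
    if drop is not None:
        thresh = base - drop
    else:
        vmin = float(np.min(vals))
        if vmin >= base:
            return float(sm.times[-1] - sm.times[0])
        thresh = base - depth_fraction * (base - vmin)
    below = vals <= thresh
    if not below.any():
        return float("inf")
    k = int(np.argmax(below))
    return float(sm.times[k] - sm.times[0])


def shock_speed(profiles: Sequence[PressureProfile]) -> ShockSpeedFit:
    """Wave speed from the trajectory of the maximum-pressure bin.

    Tracks the (parabolically refined) peak position over time and fits
    z_peak(t) by least squares; if the track is not monotonic in z a
    Theil-Sen median-of-slopes fit is used instead (with a warning).
    """
    if len(profiles) < 3:
        raise MetricError("need at least three profiles")
    times = np.array([p.time for p in profiles])
    if len(np.unique(times)) != len(times):
        raise MetricError("profiles must have distinct times")
    zpk = np.array([_refine_peak(p.bin_centers, p.pressure) for p in profiles])
    order = np.argsort(times)
    times, zpk = times[order], zpk[order]
    monotonic = np.all(np.diff(zpk) >= 0)
    if monotonic:
        slope, intercept = np.polyfit(times, zpk, 1)
        method = "least-squares"
    else:
        warnings.warn("pressure-peak track not monotonic; using Theil-Sen")
        slope, intercept, _, _ = stats.theilslopes(zpk, times)
        method = "theil-sen"
    pred = slope * times + intercept
    ss_res = float(np.sum((zpk - pred) ** 2))
    ss_tot = float(np.sum((zpk - zpk.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ShockSpeedFit(speed_A_ps=float(slope), r_squared=r2, method=method,
                         peak_times=times, peak_positions=zpk)
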