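"""Trajectory input/output: GRO, multi-frame XYZ and an internal container.

GRO is the primary interchange format because it carries velocities in
the GROMACS-87 fixed-column layout, and velocities are what the shock
protocol modifies.  XYZ is a light species+positions stream.  The
internal ``.npz`` container keeps full double precision for analysis
fidelity; GRO/XYZ are interchange-only (GRO quantises positions to
0.001 nm and velocities to 0.0001 nm/ps).
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np

from .system import ParticleFrame, Topology


class FormatError(ValueError):
    """Unsupported or inconsistent trajectory format."""


class WriteError(ValueError):
    """A value does not fit the fixed-column layout."""


class ParseError(ValueError):
    """Malformed record; carries the offending line or frame index."""


GRO, XYZ, NPZ = "gro", "xyz", "npz"
_FORMATS = (GRO, XYZ, NPZ)

_RESNAME = {"W": "SOL", "H": "POP", "T": "POP", "HC": "CHL", "TC": "CHL"}
DEFAULT_MASS = 72.0


def _detect_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        f = format.lower()
        if f not in _FORMATS:
            raise FormatError(f"unsupported format {format!r}; use one of {_FORMATS}")
        return f
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    if ext in _FORMATS:
        return ext
    raise FormatError(f"cannot infer trajectory format from {path!r}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_gro_frame(frame: ParticleFrame) -> str:
    lines = [f"memshock frame, t= {frame.time:.6f} ps", f"{frame.n_particles:5d}"]
    for i in range(frame.n_particles):
        resid = int(frame.molecule_id[i]) % 100000 + 1
        sp = str(frame.species[i])
        resname = _RESNAME.get(sp, sp[:5])
        x, y, z = frame.positions[i] / 10.0          # A -> nm
        vx, vy, vz = frame.velocities[i] / 10.0      # A/ps -> nm/ps
        pos = [f"{c:8.3f}" for c in (x, y, z)]
        vel = [f"{c:8.4f}" for c in (vx, vy, vz)]
        for fldset in (pos, vel):
            for fld in fldset:
                if len(fld) > 8:
                    raise WriteError(
                        f"coordinate {fld.strip()} overflows the 8-column GRO field")
        lines.append(
            f"{resid:5d}{resname:<5s}{sp:>5s}{(i % 99999) + 1:5d}"
            + "".join(pos) + "".join(vel)
        )
    bx = frame.box / 10.0
    lines.append(f"{bx[0]:10.5f}{bx[1]:10.5f}{bx[2]:10.5f}")
    return "\n".join(lines) + "\n"


def _format_xyz_frame(frame: ParticleFrame) -> str:
    bx = frame.box
    lines = [f"{frame.n_particles}",
             f"time= {frame.time:.6f} ps box= {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}"]
    for i in range(frame.n_particles):
        x, y, z = frame.positions[i]
        lines.append(f"{str(frame.species[i]):<4s} {x:14.6f} {y:14.6f} {z:14.6f}")
    return "\n".join(lines) + "\n"


def write_frame(frame: ParticleFrame, path: str, format: Optional[str] = None,
                topology: Optional[Topology] = None, append: bool = False) -> None:
    """Write one frame; ``append=True`` streams frames into a multi-frame file."""
    if frame.n_particles == 0:
        raise FormatError("refusing to write an empty frame")
    fmt = _detect_format(path, format)
    if fmt == NPZ:
        write_trajectory([frame], path, format=NPZ)
        return
    text = _format_gro_frame(frame.wrapped()) if fmt == GRO \
        else _format_xyz_frame(frame.wrapped())
    with open(path, "a" if append else "w") as fh:
        fh.write(text)


def write_trajectory(frames: Sequence[ParticleFrame], path: str,
                     format: Optional[str] = None,
                     topology: Optional[Topology] = None) -> None:
    if len(frames) == 0:
        raise FormatError("refusing to write an empty trajectory")
    fmt = _detect_format(path, format)
    if fmt == NPZ:
        f0 = frames[0]
        np.savez_compressed(
            path,
            positions=np.stack([f.positions for f in frames]),
            velocities=np.stack([f.velocities for f in frames]),
            times=np.array([f.time for f in frames]),
            boxes=np.stack([f.box for f in frames]),
            masses=f0.masses, species=f0.species.astype("U8"),
            molecule_id=f0.molecule_id,
        )
        return
    for k, fr in enumerate(frames):
        write_frame(fr, path, format=fmt, topology=topology, append=k > 0)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_gro_stream(lines: List[str]) -> List[ParticleFrame]:
    frames = []
    k = 0
    nline = len(lines)
    iframe = 0
    while k < nline:
        if lines[k].strip() == "":
            k += 1
            continue
        title = lines[k]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        if k + 1 >= nline:
            raise ParseError(f"truncated frame {iframe}: missing atom count")
        try:
            natoms = int(lines[k + 1])
        except ValueError as exc:
            raise ParseError(
                f"line {k + 2}: expected atom count, got {lines[k + 1]!r}") from exc
        if k + 2 + natoms >= nline:
            raise ParseError(f"truncated frame {iframe}: expected {natoms} atoms")
        pos = np.empty((natoms, 3))
        vel = np.zeros((natoms, 3))
        species = []
        molid = np.empty(natoms, dtype=np.int64)
        for a in range(natoms):
            ln = lines[k + 2 + a]
            lineno = k + 3 + a
            try:
                molid[a] = int(ln[0:5]) - 1
                species.append(ln[10:15].strip())
                pos[a] = [float(ln[20 + 8 * d: 28 + 8 * d]) * 10.0 for d in range(3)]
                if len(ln.rstrip("\n")) >= 68:
                    vel[a] = [float(ln[44 + 8 * d: 52 + 8 * d]) * 10.0
                              for d in range(3)]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed GRO atom record") from exc
        try:
            box = np.array([float(v) * 10.0
                            for v in lines[k + 2 + natoms].split()[:3]])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"line {k + 3 + natoms}: malformed GRO box line") from exc
        frames.append(ParticleFrame(
            positions=pos, velocities=vel, masses=np.full(natoms, DEFAULT_MASS),
            species=np.array(species), molecule_id=molid, box=box, time=time))
        k += 3 + natoms
        iframe += 1
    if not frames:
        raise ParseError("no frames found")
    return frames


def _parse_xyz_stream(lines: List[str]) -> List[ParticleFrame]:
    frames = []
    k = 0
    nline = len(lines)
    iframe = 0
    while k < nline:
        if lines[k].strip() == "":
            k += 1
            continue
        try:
            natoms = int(lines[k])
        except ValueError as exc:
            raise ParseError(f"line {k + 1}: expected atom count") from exc
        if k + 1 + natoms >= nline:
            raise ParseError(f"truncated frame {iframe}: expected {natoms} atoms")
        comment = lines[k + 1]
        time = 0.0
        box = np.array([1.0, 1.0, 1.0])
        if "time=" in comment:
            try:
                time = float(comment.split("time=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        if "box=" in comment:
            try:
                box = np.array([float(v)
                                for v in comment.split("box=")[1].split()[:3]])
            except (ValueError, IndexError):
                pass
        pos = np.empty((natoms, 3))
        species = []
        for a in range(natoms):
            parts = lines[k + 2 + a].split()
            try:
                species.append(parts[0])
                pos[a] = [float(v) for v in parts[1:4]]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {k + 3 + a}: malformed XYZ record") from exc
        frames.append(ParticleFrame(
            positions=pos, velocities=np.zeros((natoms, 3)),
            masses=np.full(natoms, DEFAULT_MASS), species=np.array(species),
            molecule_id=np.arange(natoms), box=box, time=time))
        k += 2 + natoms
        iframe += 1
    if not frames:
        raise ParseError("no frames found")
    return frames


@dataclass
class TrajectoryHandle:
    """Uniform view of an on-disk trajectory (lazy frame iteration)."""

    path: str
    format: str
    n_frames: int
    times: np.ndarray
    species: np.ndarray

    _frames: Optional[List[ParticleFrame]] = None
    _npz: Optional[object] = None

    def __iter__(self) -> Iterator[ParticleFrame]:
        return self.iter_frames()

    def iter_frames(self) -> Iterator[ParticleFrame]:
        if self._frames is not None:
            yield from self._frames
        else:
            data = self._npz
            for k in range(self.n_frames):
                yield ParticleFrame(
                    positions=data["positions"][k],
                    velocities=data["velocities"][k],
                    masses=data["masses"], species=data["species"],
                    molecule_id=data["molecule_id"], box=data["boxes"][k],
                    time=float(data["times"][k]))

    def frames(self) -> List[ParticleFrame]:
        return list(self.iter_frames())


def read_trajectory(path: str, format: Optional[str] = None) -> TrajectoryHandle:
    """Parse a trajectory file into a handle.

    Frame times must be strictly increasing and every frame must share the
    particle count and ordering of the first.
    """
    fmt = _detect_format(path, format)
    if fmt == NPZ:
        data = np.load(path, allow_pickle=False)
        times = np.asarray(data["times"], dtype=float)
        handle = TrajectoryHandle(path=path, format=fmt, n_frames=len(times),
                                  times=times, species=data["species"],
                                  _npz=data)
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        frames = _parse_gro_stream(lines) if fmt == GRO else _parse_xyz_stream(lines)
        times = np.array([f.time for f in frames])
        handle = TrajectoryHandle(path=path, format=fmt, n_frames=len(frames),
                                  times=times, species=frames[0].species,
                                  _frames=frames)
    if handle.n_frames > 1 and not np.all(np.diff(handle.times) > 0):
        raise ParseError("frame times are not strictly increasing")
    counts = {len(f.species) if fmt != NPZ else None for f in ([] if fmt == NPZ
              else handle._frames)}
    if fmt != NPZ and len(counts) > 1:
        raise ParseError("frames disagree on particle count")
    return handle
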