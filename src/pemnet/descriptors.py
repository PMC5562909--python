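"""Trajectory I/O and dihedral-angle molecular descriptors.

Conformers are described by a small set of internal coordinates — signed
torsion (dihedral) angles in degrees — which are invariant under rigid-body
motion and capture the slow conformational degrees of freedom that
distinguish metastable states of a photoexcited molecule.

Conventions
-----------
* Torsion sign follows the IUPAC convention: looking down the b->c bond,
  a positive angle means the far bond (c->d) is rotated clockwise from the
  near bond (b->a).  Computed with the standard atan2 formulation so the
  result is numerically stable near 0 and 180 degrees.
* All angles are wrapped to the half-open interval [-180, 180), so the cis
  arrangement is 0 and trans is -180 (the single canonical representative
  of the +/-180 pair).
* Atom and frame indices are 0-based throughout the library; file formats
  that conventionally use 1-based atom numbering (the dihedral config) are
  converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Trajectory",
    "DihedralSpec",
    "TrajectoryError",
    "DegenerateGeometryError",
    "wrap_angle",
    "wrap_difference",
    "dihedral_angle",
    "compute_descriptors",
    "filter_local_minima",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_dihedral_specs",
    "write_dihedral_specs",
    "read_property_table",
    "write_property_table",
    "join_properties",
]


class TrajectoryError(ValueError):
    """Malformed trajectory file or inconsistent frame data."""


class DegenerateGeometryError(ValueError):
    """Torsion undefined: coincident points or collinear bond vectors."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One snapshot: element symbols, Cartesian coordinates (A), time (fs).

    ``properties`` holds optional named scalars (e.g. potential energy,
    excitation energy in eV); ``charges`` optional per-atom partial charges
    in units of elementary charge.
    """

    atom_symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    time: float = 0.0
    properties: dict[str, float] = field(default_factory=dict)
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError(
                f"coords must be (n_atoms, 3), got {self.coords.shape}"
            )
        if len(self.atom_symbols) != self.coords.shape[0]:
            raise TrajectoryError(
                f"{len(self.atom_symbols)} symbols vs {self.coords.shape[0]} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames from one dynamics run."""

    trajectory_id: str
    frames: list[Frame]
    timestep: float = 0.5  # fs

    def __post_init__(self) -> None:
        if self.frames:
            n0 = self.frames[0].n_atoms
            sym0 = self.frames[0].atom_symbols
            for i, fr in enumerate(self.frames):
                if fr.n_atoms != n0:
                    raise TrajectoryError(
                        f"frame {i}: atom count {fr.n_atoms} != {n0}"
                    )
                if fr.atom_symbols != sym0:
                    raise TrajectoryError(f"frame {i}: symbol order differs")
            times = [fr.time for fr in self.frames]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise TrajectoryError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


@dataclass(frozen=True)
class DihedralSpec:
    """A named torsion defined by four distinct 0-based atom indices."""

    name: str
    atoms: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError(f"dihedral {self.name!r}: atom indices must be distinct")
        if any(a < 0 for a in self.atoms):
            raise ValueError(f"dihedral {self.name!r}: negative atom index")

    def validate(self, n_atoms: int) -> None:
        if max(self.atoms) >= n_atoms:
            raise ValueError(
                f"dihedral {self.name!r}: atom index {max(self.atoms)} "
                f">= atom count {n_atoms}"
            )


# ---------------------------------------------------------------------------
# Angle arithmetic
# ---------------------------------------------------------------------------

def wrap_angle(theta):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_difference(a, b):
    """Signed angular difference a - b wrapped to [-180, 180) degrees.

    The magnitude is the shortest arc between the two angles, so a
    difference of 179 vs -179 degrees is 2, not 358.
    """
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral_angle(a, b, c, d) -> float:
    """Signed torsion angle (degrees, in [-180, 180)) of four points.

    Uses the praxeolitic atan2 formulation: with b1 = b-a, b2 = c-b,
    b3 = d-c, the angle is atan2(|b2| b1.(b2 x b3), (b1 x b2).(b2 x b3)).
    cis (all four points coplanar, a and d on the same side) gives 0;
    trans gives 180, wrapped to -180.

    Raises
    ------
    DegenerateGeometryError
        If consecutive points coincide or three consecutive points are
        collinear (the torsion plane is undefined).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    for name, v in (("a-b", b1), ("b-c", b2), ("c-d", b3)):
        if np.linalg.norm(v) < 1e-10:
            raise DegenerateGeometryError(f"coincident points on bond {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear bond vectors: torsion undefined")
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def compute_descriptors(
    traj: Trajectory, specs: Sequence[DihedralSpec]
) -> np.ndarray:
    """Dihedral descriptor matrix, one row per frame.

    Returns an (n_frames, p) array of wrapped angles in degrees, columns
    ordered as ``specs``.
    """
    if not specs:
        raise ValueError("no dihedral specs given")
    for s in specs:
        s.validate(traj.n_atoms)
    out = np.empty((len(traj), len(specs)))
    for i, fr in enumerate(traj.frames):
        for j, s in enumerate(specs):
            ia, ib, ic, id_ = s.atoms
            try:
                out[i, j] = dihedral_angle(
                    fr.coords[ia], fr.coords[ib], fr.coords[ic], fr.coords[id_]
                )
            except DegenerateGeometryError as exc:
                raise DegenerateGeometryError(
                    f"frame {i}, dihedral {s.name!r}: {exc}"
                ) from exc
    return out


# ---------------------------------------------------------------------------
# Local-minimum snapshot filtering
# ---------------------------------------------------------------------------

def filter_local_minima(series, strict: bool = True) -> list[int]:
    """Indices of interior local minima of a per-frame scalar series.

    With ``strict`` (default) index i qualifies iff
    series[i] < series[i-1] and series[i] < series[i+1]; endpoints are
    never returned.  With ``strict=False`` an interior plateau that is a
    minimum relative to its non-equal neighbours contributes its first
    index.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite values")
    if strict:
        mask = (s[1:-1] < s[:-2]) & (s[1:-1] < s[2:])
        return list(np.flatnonzero(mask) + 1)
    # plateau mode: walk runs of equal values
    out: list[int] = []
    i = 1
    n = len(s)
    while i < n - 1:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        if j < n - 1 and s[i] < s[i - 1] and s[i] < s[j + 1]:
            out.append(i)
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# Multi-frame XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz_trajectory(
    path, timestep_fs: float = 0.5, trajectory_id: str | None = None
) -> Trajectory:
    """Read a multi-frame XYZ file (repeated count / comment / atom blocks).

    Frame times are assigned as ``i * timestep_fs``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryError(
                f"{path.name}, frame {len(frames)}: expected atom count, "
                f"got {lines[pos]!r}"
            )
        block = lines[pos + 2 : pos + 2 + natoms]
        if len(block) < natoms:
            raise TrajectoryError(
                f"{path.name}, frame {len(frames)}: truncated block "
                f"({len(block)}/{natoms} atom lines)"
            )
        symbols: list[str] = []
        coords = np.empty((natoms, 3))
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"{path.name}, frame {len(frames)}, atom {k}: "
                    f"malformed line {line!r}"
                )
            symbols.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise TrajectoryError(
                    f"{path.name}, frame {len(frames)}, atom {k}: "
                    f"non-numeric coordinate in {line!r}"
                )
        frames.append(
            Frame(symbols, coords, time=len(frames) * timestep_fs)
        )
        pos += 2 + natoms
    if not frames:
        raise TrajectoryError(f"{path.name}: no frames")
    return Trajectory(
        trajectory_id=trajectory_id or path.stem,
        frames=frames,
        timestep=timestep_fs,
    )


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame XYZ (coordinates to 1e-10 A)."""
    with open(path, "w") as fh:
        for i, fr in enumerate(traj.frames):
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"{traj.trajectory_id} frame {i} t= {fr.time:.4f} fs\n")
            for sym, xyz in zip(fr.atom_symbols, fr.coords):
                fh.write(
                    f"{sym:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n"
                )


# ---------------------------------------------------------------------------
# Dihedral config I/O (1-based atom indices on disk, chemistry convention)
# ---------------------------------------------------------------------------

def read_dihedral_specs(path) -> list[DihedralSpec]:
    """Read dihedral definitions: lines of ``name i j k l`` (1-based)."""
    specs: list[DihedralSpec] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {ln}: expected 'name i j k l', got {raw!r}")
        try:
            idx = tuple(int(p) - 1 for p in parts[1:])
        except ValueError:
            raise ValueError(f"line {ln}: non-integer atom index in {raw!r}")
        if any(i < 0 for i in idx):
            raise ValueError(f"line {ln}: atom indices are 1-based, got 0 or less")
        specs.append(DihedralSpec(parts[0], idx))  # type: ignore[arg-type]
    if not specs:
        raise ValueError(f"{path}: no dihedral definitions")
    return specs


def write_dihedral_specs(specs: Sequence[DihedralSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name  atom indices (1-based)\n")
        for s in specs:
            fh.write(f"{s.name} {' '.join(str(a + 1) for a in s.atoms)}\n")


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

def read_property_table(path) -> pd.DataFrame:
    """Read a delimited property table keyed by (trajectory_id, frame).

    Columns: ``trajectory_id``, ``frame``, then named scalar properties;
    per-atom charges as ``charge_1 .. charge_A`` (1-based atom columns).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("trajectory_id", "frame"):
        if col not in df.columns:
            raise ValueError(f"property table missing column {col!r}")
    df["trajectory_id"] = df["trajectory_id"].astype(str)
    df["frame"] = df["frame"].astype(int)
    return df


def write_property_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def charge_columns(df: pd.DataFrame) -> list[str]:
    """Charge columns charge_1..charge_A in atom order."""
    cols = [c for c in df.columns if c.startswith("charge_")]
    return sorted(cols, key=lambda c: int(c.split("_", 1)[1]))


def join_properties(
    traj: Trajectory, table: pd.DataFrame
) -> int:
    """Attach table rows to ``traj`` frames matched on (trajectory_id, frame).

    Frames without a matching row keep empty properties; the number of
    matched frames is returned and a count of missing ones logged.
    """
    sub = table[table["trajectory_id"] == traj.trajectory_id]
    by_frame = {int(r["frame"]): r for _, r in sub.iterrows()}
    qcols = charge_columns(table)
    scalar_cols = [
        c for c in table.columns
        if c not in ("trajectory_id", "frame") and c not in qcols
    ]
    matched = 0
    for i, fr in enumerate(traj.frames):
        row = by_frame.get(i)
        if row is None:
            continue
        matched += 1
        for c in scalar_cols:
            v = row[c]
            if pd.notna(v):
                fr.properties[c] = float(v)
        if qcols:
            q = np.array([row[c] for c in qcols], dtype=float)
            if np.all(np.isfinite(q)):
                fr.charges = q
    if matched < len(traj):
        logger.info(
            "trajectory %s: %d/%d frames have properties",
            traj.trajectory_id, matched, len(traj),
        )
    return matched
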