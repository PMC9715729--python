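"""Trajectory and coordinate-file handling.

Two formats are supported:

* GRO coordinate files (fixed-width, nm) for single frames.  Residue
  names map to roles through a configurable table: by default water
  residues contribute their oxygen atom as ``water-oxygen`` and cellulose
  residues contribute their carbons as ``fibril-carbon``; everything else
  is ``other``.
* An internal tabular frame format (CSV) that is the canonical format for
  tests and synthetic trajectories: one row per atom per frame with
  ``time_ps, role, mol, x, y, z`` plus one box record per frame (role
  ``box``, mol -1, coordinates = box edge lengths).

Coordinates are stored as-is; no wrapping or unwrapping is applied on
read (unwrapping is the diffusion module's contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "ROLE_FIBRIL_CARBON",
    "ROLE_WATER_OXYGEN",
    "ROLE_OTHER",
    "DEFAULT_ROLE_TABLE",
    "read_gro",
    "read_frames",
    "write_frames",
    "select",
]

ROLE_FIBRIL_CARBON = "fibril-carbon"
ROLE_WATER_OXYGEN = "water-oxygen"
ROLE_OTHER = "other"
_ROLES = (ROLE_FIBRIL_CARBON, ROLE_WATER_OXYGEN, ROLE_OTHER)

#: residue-name -> ('water' | 'cellulose') classification used by read_gro
DEFAULT_ROLE_TABLE = {
    "SOL": "water",
    "WAT": "water",
    "HOH": "water",
    "TIP4": "water",
    "GLC": "cellulose",
    "CEL": "cellulose",
    "BGLC": "cellulose",
}


@dataclass
class Frame:
    """One role-tagged snapshot in a periodic box."""

    time: float  # ps
    box: np.ndarray  # (3,) edge lengths, nm
    positions: np.ndarray  # (n, 3) nm
    roles: np.ndarray  # (n,) strings from _ROLES
    mol_index: np.ndarray  # (n,) int, stable across frames

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,) or (self.box <= 0).any():
            raise ValueError(f"box lengths must be three positive values, got {self.box}")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class Trajectory:
    """Time-ordered frames with constant atom identity and spacing.

    Stored column-major over time: ``positions[f, i]`` is atom ``i`` in
    frame ``f``; roles and molecule indices are frame-invariant.
    """

    times: np.ndarray  # (F,) ps, strictly increasing, constant spacing
    box: np.ndarray  # (3,) nm (constant box)
    positions: np.ndarray  # (F, N, 3)
    roles: np.ndarray  # (N,)
    mol_index: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) == 0:
            raise ValueError("trajectory has no frames")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if (dt <= 0).any():
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-9):
                raise ValueError(f"non-constant frame spacing: {sorted(set(np.round(dt, 9)))}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, f: int) -> Frame:
        return Frame(
            time=float(self.times[f]),
            box=self.box,
            positions=self.positions[f],
            roles=self.roles,
            mol_index=self.mol_index,
        )

    def __iter__(self):
        return (self.frame(f) for f in range(self.n_frames))


class GroFormatError(ValueError):
    pass


def read_gro(path: str | Path, role_table: dict[str, str] | None = None) -> Frame:
    """Parse one GRO file into a role-tagged Frame.

    Roles: for residues classed ``water`` in the table, atoms whose name
    starts with O get ``water-oxygen``; for ``cellulose`` residues, atoms
    whose name starts with C get ``fibril-carbon``; all remaining atoms
    are ``other``.  Each water residue gets its own molecule index.
    """
    role_table = DEFAULT_ROLE_TABLE if role_table is None else role_table
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GroFormatError(f"{path}: GRO file needs title, count and box lines")
    try:
        declared = int(lines[1].strip())
    except ValueError as exc:
        raise GroFormatError(f"{path}, line 2: atom count is not an integer: {lines[1]!r}") from exc
    atom_lines = lines[2:-1]
    if len(atom_lines) != declared:
        raise GroFormatError(
            f"{path}: header declares {declared} atoms but file has {len(atom_lines)} atom lines"
        )
    box_fields = lines[-1].split()
    if len(box_fields) < 3:
        raise GroFormatError(f"{path}, last line: box must have >= 3 fields, got {lines[-1]!r}")
    box = np.array([float(v) for v in box_fields[:3]])

    pos = np.empty((declared, 3))
    roles = np.empty(declared, dtype=object)
    mols = np.empty(declared, dtype=int)
    water_ids: dict[int, int] = {}
    next_mol = 0
    next_carbon = 0
    for i, ln in enumerate(atom_lines):
        lineno = i + 3
        if len(ln) < 44:
            raise GroFormatError(f"{path}, line {lineno}: atom line too short ({len(ln)} chars)")
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            atomname = ln[10:15].strip()
            pos[i] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except ValueError as exc:
            raise GroFormatError(f"{path}, line {lineno}: malformed fixed-width atom line") from exc
        kind = role_table.get(resname)
        if kind == "water" and atomname.startswith("O"):
            roles[i] = ROLE_WATER_OXYGEN
            if resid not in water_ids:
                water_ids[resid] = next_mol
                next_mol += 1
            mols[i] = water_ids[resid]
        elif kind == "cellulose" and atomname.startswith("C"):
            roles[i] = ROLE_FIBRIL_CARBON
            mols[i] = next_carbon  # indices are per-role
            next_carbon += 1
        else:
            roles[i] = ROLE_OTHER
            mols[i] = -1
    return Frame(time=0.0, box=box, positions=pos, roles=np.array(roles, dtype=str), mol_index=mols)


_COLUMNS = ["time_ps", "role", "mol", "x", "y", "z"]


def write_frames(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory in the internal tabular (CSV) format."""
    path = Path(path)
    n = len(traj.roles)
    chunks = []
    for f in range(traj.n_frames):
        t = traj.times[f]
        chunks.append(
            pd.DataFrame(
                {
                    "time_ps": [t],
                    "role": ["box"],
                    "mol": [-1],
                    "x": [traj.box[0]],
                    "y": [traj.box[1]],
                    "z": [traj.box[2]],
                }
            )
        )
        chunks.append(
            pd.DataFrame(
                {
                    "time_ps": np.full(n, t),
                    "role": traj.roles,
                    "mol": traj.mol_index,
                    "x": traj.positions[f, :, 0],
                    "y": traj.positions[f, :, 1],
                    "z": traj.positions[f, :, 2],
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    return path


def read_frames(path: str | Path) -> Trajectory:
    """Read the internal tabular frame format into a Trajectory.

    Row order within a frame is irrelevant: atoms are ordered by
    (role, molecule index).  Raises if frame spacing is not constant or a
    molecule present in one frame is missing from another.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    boxes = df[df["role"] == "box"]
    atoms = df[df["role"] != "box"].copy()
    if boxes.empty:
        raise ValueError(f"{path}: no box records")
    box = boxes.iloc[0][["x", "y", "z"]].to_numpy(dtype=float)

    times = np.sort(atoms["time_ps"].unique())
    if len(times) > 1:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-9):
            raise ValueError(f"{path}: non-constant frame spacing {sorted(set(np.round(dt, 6)))}")

    # Canonical atom identity from the first frame.
    first = atoms[atoms["time_ps"] == times[0]].sort_values(["role", "mol"], kind="stable")
    key = list(zip(first["role"], first["mol"]))
    n = len(first)
    positions = np.empty((len(times), n, 3))
    for f, t in enumerate(times):
        sub = atoms[atoms["time_ps"] == t].sort_values(["role", "mol"], kind="stable")
        if len(sub) != n or list(zip(sub["role"], sub["mol"])) != key:
            have = set(zip(sub["role"], sub["mol"]))
            lost = [k for k in key if k not in have]
            raise ValueError(
                f"{path}: frame at t={t} ps does not match atom identity of first frame; "
                f"missing {lost[:5]}{'...' if len(lost) > 5 else ''}"
            )
        positions[f] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    return Trajectory(
        times=times,
        box=box,
        positions=positions,
        roles=first["role"].to_numpy(dtype=str),
        mol_index=first["mol"].to_numpy(dtype=int),
    )


def from_mdanalysis(topology, trajectory=None, role_table: dict[str, str] | None = None) -> Trajectory:
    """Optional adapter: load a binary MD trajectory (XTC/TRR/...) via MDAnalysis.

    Roles are assigned from residue names with the same table as
    ``read_gro``.  MDAnalysis positions (Angstrom) are converted to nm.
    The internal tabular format remains the canonical test surface; this
    adapter exists for ingesting real MD output.
    """
    import MDAnalysis as mda  # deferred: optional dependency

    role_table = DEFAULT_ROLE_TABLE if role_table is None else role_table
    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(str(topology), str(trajectory))
    roles = np.full(len(u.atoms), ROLE_OTHER, dtype=object)
    mols = np.full(len(u.atoms), -1, dtype=int)
    next_water = next_carbon = 0
    for i, atom in enumerate(u.atoms):
        kind = role_table.get(str(atom.resname))
        if kind == "water" and atom.name.startswith("O"):
            roles[i] = ROLE_WATER_OXYGEN
            mols[i] = next_water
            next_water += 1
        elif kind == "cellulose" and atom.name.startswith("C"):
            roles[i] = ROLE_FIBRIL_CARBON
            mols[i] = next_carbon
            next_carbon += 1
    times, frames = [], []
    for ts in u.trajectory:
        times.append(float(ts.time))
        frames.append(u.atoms.positions / 10.0)
    times = np.asarray(times)
    if len(times) > 1 and np.allclose(times, times[0]):
        times = np.arange(len(times), dtype=float)  # formats without time stamps
    return Trajectory(
        times=times,
        box=u.dimensions[:3] / 10.0,
        positions=np.stack(frames),
        roles=np.array(roles, dtype=str),
        mol_index=mols,
    )


def select(frame: Frame, role: str) -> np.ndarray:
    """Positions of atoms with the given role, ordered by molecule index.

    An absent role yields an empty (0, 3) array; an unknown role name is
    an error.
    """
    if role not in _ROLES:
        raise ValueError(f"unknown role {role!r}; valid roles: {_ROLES}")
    mask = frame.roles == role
    pos = frame.positions[mask]
    order = np.argsort(frame.mol_index[mask], kind="stable")
    return pos[order].reshape(-1, 3)
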