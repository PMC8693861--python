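"""Structure, trajectory, grid and plate-table I/O.

All lengths are ångström internally; GRO files (nm) are converted on read
and write. Atom/residue numbering stays 1-based as in the source files,
while every index the API returns is 0-based.

Supported text formats
----------------------
* fixed-column PDB (ATOM/HETATM records; HETATM kept as ordinary atoms,
  since ligands, heme and waters are first-class in every analysis here)
* GRO single structures and concatenated GRO frame series
* multi-model PDB trajectories
* a plain-text trajectory dialect, ``xyzt``::

      N T
      t=<ns> box=<lx> <ly> <lz>      # one header per frame, lengths in Å
      name x y z                     # N atom lines per frame
      ...

* OpenDX scalar grids ("gridpositions counts", z fastest)
* CSV plate tables with columns well,condition,cofactor,replicate,time_min,signal
"""

from __future__ import annotations

import io
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import infer_element, vdw_radius_for

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "DensityGrid",
    "PlateTable",
    "SelectionError",
    "ParseError",
    "parse_selection",
    "select",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_xyzt",
    "write_density_dx",
    "read_density_dx",
    "read_plate_csv",
    "write_plate_csv",
]


class ParseError(ValueError):
    """Malformed file content; message names the offending line."""


class SelectionError(ValueError):
    """Selection expression failed to parse; message points at the column."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: identity plus the bundled van der Waals radius."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


@dataclass
class Structure:
    """Atoms plus an N×3 coordinate array and an optional orthorhombic box (Å)."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, expr: str) -> np.ndarray:
        return select(self, expr)

    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])


@dataclass
class Trajectory:
    """A topology plus T frames of coordinates, boxes and time stamps (ns)."""

    topology: Structure
    frames: np.ndarray
    boxes: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms} atoms"
            )
        if self.times is None:
            self.times = np.arange(self.frames.shape[0], dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.frames.shape[0],):
                raise ValueError("times length does not match frame count")
            if self.frames.shape[0] > 1 and not (np.diff(self.times) > 0).all():
                raise ValueError("times must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (self.frames.shape[0], 3):
                raise ValueError("boxes must be T×3")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def select(self, expr: str) -> np.ndarray:
        return select(self.topology, expr)


@dataclass
class DensityGrid:
    """Regular 3D grid of time-averaged occupancy.

    ``values[i, j, k]`` is the mean per-frame count in the voxel whose centre
    is ``origin + (i+.5, j+.5, k+.5) * spacing`` (counts mode), or a density
    per Å³ when normalised. ``spill`` tallies atoms that fell outside the
    grid during accumulation.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]
    values: np.ndarray
    n_frames: int = 1
    spill: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        self.values = np.asarray(self.values, dtype=float)
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if self.values.shape != self.dims:
            raise ValueError("values shape does not match dims")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(axes)  # type: ignore[return-value]


@dataclass
class PlateTable:
    """Plate-reader time courses: one row per (well, time point).

    Columns: well, condition, cofactor ("+PalmCoA"/"-PalmCoA"), replicate,
    time_min, signal.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("well", "condition", "cofactor", "replicate", "time_min", "signal")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        keys = ["well", "condition", "cofactor", "replicate"]
        n_times = self.data.groupby(keys)["time_min"].nunique()
        bad = n_times[n_times < 3]
        if len(bad):
            raise ValueError(
                f"well {bad.index[0][0]}: fewer than 3 distinct time points"
            )

    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------
#
# term   := (chain X+ | resid N[-M]+ | resname S+ | name S+ | element S+)
# expr   := term {and|or term} ; "not" negates the following term;
# parentheses are accepted for grouping. A term keyword followed by several
# values matches any of them ("resid 335 372", "name O OW OH2").

_KEYWORDS = {"chain", "resid", "resname", "name", "element", "and", "or", "not", "(", ")"}
_RESID_RANGE = re.compile(r"^(-?\d+)-(-?\d+)$")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _SelParser:
    def __init__(self, expr: str, structure: Structure):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.s = structure

    def _err(self, msg: str, col: int) -> SelectionError:
        pointer = " " * col + "^"
        return SelectionError(f"{msg} at column {col}:\n  {self.expr}\n  {pointer}")

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of expression", len(self.expr))
        self.pos += 1
        return tok

    # expr := and_expr {or and_expr}
    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            tok, col = self.peek()  # type: ignore[misc]
            raise self._err(f"unexpected token {tok!r}", col)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() is not None and self.peek()[0].lower() == "or":  # type: ignore[index]
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_unary()
        while self.peek() is not None and self.peek()[0].lower() == "and":  # type: ignore[index]
            self.take()
            mask = mask & self.parse_unary()
        return mask

    def parse_unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of expression", len(self.expr))
        if tok[0].lower() == "not":
            self.take()
            return ~self.parse_unary()
        if tok[0] == "(":
            self.take()
            mask = self.parse_or()
            nxt = self.peek()
            if nxt is None or nxt[0] != ")":
                raise self._err("missing closing parenthesis", len(self.expr))
            self.take()
            return mask
        return self.parse_term()

    def parse_term(self) -> np.ndarray:
        word, col = self.take()
        key = word.lower()
        if key not in ("chain", "resid", "resname", "name", "element"):
            raise self._err(f"expected a selection keyword, got {word!r}", col)
        values: list[str] = []
        while True:
            nxt = self.peek()
            if nxt is None:
                break
            w = nxt[0]
            if w.lower() in _KEYWORDS or w in "()":
                break
            values.append(w)
            self.take()
        if not values:
            raise self._err(f"keyword {word!r} needs at least one value", col)
        return self._term_mask(key, values, col)

    def _term_mask(self, key: str, values: list[str], col: int) -> np.ndarray:
        atoms = self.s.atoms
        n = len(atoms)
        mask = np.zeros(n, dtype=bool)
        if key == "resid":
            resids = np.array([a.resid for a in atoms])
            for v in values:
                m = _RESID_RANGE.match(v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (resids >= lo) & (resids <= hi)
                else:
                    try:
                        mask |= resids == int(v)
                    except ValueError:
                        raise self._err(f"bad resid {v!r}", col) from None
            return mask
        getter = {
            "chain": lambda a: a.chain,
            "resname": lambda a: a.resname,
            "name": lambda a: a.name,
            "element": lambda a: a.element,
        }[key]
        wanted = {v.upper() for v in values}
        attr = np.array([getter(a).strip().upper() for a in atoms])
        for w in wanted:
            mask |= attr == w
        return mask


def parse_selection(expr: str, structure: Structure) -> np.ndarray:
    """Evaluate a selection expression to a boolean mask over atoms."""
    return _SelParser(expr, structure).parse()


def select(structure: Structure, expr: str) -> np.ndarray:
    """Evaluate a selection expression to a sorted 0-based index array."""
    mask = parse_selection(expr, structure)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21:22].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed PDB record on line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, resname)
    radius, known = vdw_radius_for(element, name)
    if not known:
        warnings.warn(
            f"line {lineno}: unknown element {element!r} for atom {name!r}; "
            f"using fallback vdW radius {radius} Å",
            stacklevel=2,
        )
    rec = AtomRecord(serial, name, resname, resid, chain, element, radius)
    return rec, np.array([x, y, z])


def _read_pdb_models(text: str, path: str) -> tuple[list[AtomRecord], list[np.ndarray], np.ndarray | None]:
    """Parse a PDB into (atoms of first model, per-model coords, box)."""
    atoms: list[AtomRecord] = []
    models: list[np.ndarray] = []
    current: list[np.ndarray] = []
    box = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            except ValueError as exc:
                raise ParseError(f"malformed CRYST1 on line {lineno}") from exc
        elif rec == "MODEL ":
            current = []
        elif rec == "ENDMDL":
            models.append(np.array(current))
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            atom, xyz = _parse_pdb_atom_line(line, lineno)
            if not models and len(current) == len(atoms):
                atoms.append(atom)
            current.append(xyz)
    if current:
        models.append(np.array(current))
    if not models or not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    for k, m in enumerate(models):
        if len(m) != len(atoms):
            raise ParseError(
                f"{path}: model {k} has {len(m)} atoms, expected {len(atoms)}"
            )
    return atoms, models, box


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

_GRO_TIME = re.compile(r"\bt\s*=\s*([0-9.eE+-]+)")


def _read_gro_block(lines: list[str], start: int):
    """Parse one GRO frame starting at ``lines[start]``.

    Returns (atoms, coords Å, box Å, time_ns or None, next_index).
    """
    if start >= len(lines):
        raise ParseError("unexpected end of GRO file")
    title = lines[start]
    m = _GRO_TIME.search(title)
    time_ns = float(m.group(1)) / 1000.0 if m else None  # GRO t= is ps
    try:
        natoms = int(lines[start + 1].strip())
    except (ValueError, IndexError) as exc:
        raise ParseError(
            f"malformed GRO atom count on line {start + 2}"
        ) from exc
    atoms: list[AtomRecord] = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        lineno = start + 2 + i
        try:
            line = lines[lineno]
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28]) * 10.0
            y = float(line[28:36]) * 10.0
            z = float(line[36:44]) * 10.0
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed GRO atom on line {lineno + 1}") from exc
        element = infer_element(name, resname)
        radius, _ = vdw_radius_for(element, name)
        atoms.append(AtomRecord(serial, name, resname, resid, " ", element, radius))
        coords[i] = (x, y, z)
    boxline = lines[start + 2 + natoms].split()
    box = np.array([float(v) * 10.0 for v in boxline[:3]])
    return atoms, coords, box, time_ns, start + 3 + natoms


# ---------------------------------------------------------------------------
# public structure I/O
# ---------------------------------------------------------------------------

def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gro":
        return "gro"
    return "pdb"


def read_structure(path: str, format: str = "auto") -> Structure:
    """Read a PDB or GRO file into a Structure (first model if several)."""
    if format == "auto":
        format = _sniff_format(path)
    with open(path) as fh:
        text = fh.read()
    if format == "pdb":
        atoms, models, box = _read_pdb_models(text, path)
        return Structure(atoms, models[0], box)
    if format == "gro":
        lines = text.splitlines()
        atoms, coords, box, _, _ = _read_gro_block(lines, 0)
        return Structure(atoms, coords, box)
    raise ValueError(f"unknown structure format {format!r}")


def write_structure(structure: Structure, path: str, format: str = "auto") -> None:
    """Write a Structure as fixed-column PDB or GRO."""
    if format == "auto":
        format = _sniff_format(path)
    if format == "pdb":
        with open(path, "w") as fh:
            _write_pdb_frame(fh, structure, structure.coords, box=structure.box)
            fh.write("END\n")
    elif format == "gro":
        with open(path, "w") as fh:
            _write_gro_frame(fh, structure, structure.coords, time_ns=None)
    else:
        raise ValueError(f"unknown structure format {format!r}")


def _write_pdb_frame(fh, structure: Structure, coords: np.ndarray, box=None) -> None:
    if box is not None:
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"  90.00  90.00  90.00 P 1           1\n"
        )
    for a, xyz in zip(structure.atoms, coords):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        fh.write(
            f"ATOM  {a.serial % 100000:5d} {name:<4.4s} {a.resname:<4.4s}"
            f"{a.chain:1.1s}{a.resid % 10000:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
        )


def _write_gro_frame(fh, structure: Structure, coords: np.ndarray, time_ns) -> None:
    title = "memgate"
    if time_ns is not None:
        title += f" t= {time_ns * 1000.0:.3f}"
    fh.write(title + "\n")
    fh.write(f"{structure.n_atoms:5d}\n")
    for a, xyz in zip(structure.atoms, coords):
        fh.write(
            f"{a.resid % 100000:5d}{a.resname:<5.5s}{a.name:>5.5s}"
            f"{a.serial % 100000:5d}"
            f"{xyz[0] / 10:8.3f}{xyz[1] / 10:8.3f}{xyz[2] / 10:8.3f}\n"
        )
    box = structure.box if structure.box is not None else np.zeros(3)
    fh.write(f"{box[0] / 10:10.5f}{box[1] / 10:10.5f}{box[2] / 10:10.5f}\n")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def read_trajectory(
    topology_path: str | None,
    traj_path: str,
    format: str = "auto",
) -> Trajectory:
    """Read a trajectory.

    ``format`` is one of multi_model_pdb, gro_series, xyzt or auto (sniffed
    from the extension: .pdb, .gro, .xyzt). The topology path may be None
    for self-describing files; when given, frame atom counts are checked
    against it.
    """
    if format == "auto":
        ext = os.path.splitext(traj_path)[1].lower()
        format = {".pdb": "multi_model_pdb", ".gro": "gro_series", ".xyzt": "xyzt"}.get(
            ext, "multi_model_pdb"
        )
    topology = read_structure(topology_path) if topology_path else None

    with open(traj_path) as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError(f"{traj_path}: empty trajectory file")

    if format == "multi_model_pdb":
        atoms, models, box = _read_pdb_models(text, traj_path)
        top = topology or Structure(atoms, models[0], box)
        frames = np.array(models)
        boxes = np.tile(box, (len(models), 1)) if box is not None else None
    elif format == "gro_series":
        lines = text.splitlines()
        pos = 0
        frames_list, boxes_list, times_list = [], [], []
        atoms = None
        k = 0
        while pos < len(lines) and lines[pos].strip():
            a, coords, box, t, pos = _read_gro_block(lines, pos)
            if atoms is None:
                atoms = a
            elif len(a) != len(atoms):
                raise ParseError(
                    f"{traj_path}: atom count mismatch at frame {k} "
                    f"({len(a)} vs {len(atoms)})"
                )
            frames_list.append(coords)
            boxes_list.append(box)
            times_list.append(t)
            k += 1
        top = topology or Structure(atoms, frames_list[0], boxes_list[0])
        frames = np.array(frames_list)
        boxes = np.array(boxes_list)
        times = (
            np.array([t for t in times_list])
            if all(t is not None for t in times_list)
            else None
        )
        return _finish_traj(top, frames, boxes, times, traj_path)
    elif format == "xyzt":
        return _read_xyzt(io.StringIO(text), topology, traj_path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")

    return _finish_traj(top, frames, boxes, None, traj_path)


def _finish_traj(top, frames, boxes, times, path) -> Trajectory:
    for k, f in enumerate(frames):
        if len(f) != top.n_atoms:
            raise ParseError(
                f"{path}: frame {k} has {len(f)} atoms, topology has {top.n_atoms}"
            )
    return Trajectory(top, frames, boxes=boxes, times=times)


def _read_xyzt(fh, topology: Structure | None, path: str) -> Trajectory:
    header = fh.readline().split()
    if len(header) != 2:
        raise ParseError(f"{path}: xyzt header must be 'N T' on line 1")
    n_atoms, n_frames = int(header[0]), int(header[1])
    names: list[str] = []
    frames = np.empty((n_frames, n_atoms, 3))
    boxes = np.empty((n_frames, 3))
    times = np.empty(n_frames)
    have_box = True
    for k in range(n_frames):
        line = fh.readline()
        if not line:
            raise ParseError(f"{path}: truncated at frame {k}")
        parts = line.split()
        if not parts or not parts[0].startswith("t="):
            raise ParseError(f"{path}: bad frame header at frame {k}: {line.rstrip()!r}")
        times[k] = float(parts[0][2:])
        if len(parts) >= 4 and parts[1].startswith("box="):
            boxes[k] = (float(parts[1][4:]), float(parts[2]), float(parts[3]))
        else:
            have_box = False
        for i in range(n_atoms):
            aline = fh.readline()
            if not aline:
                raise ParseError(f"{path}: atom-count mismatch at frame {k}")
            fields = aline.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: bad atom line at frame {k}: {aline.rstrip()!r}"
                )
            if k == 0:
                names.append(fields[0])
            frames[k, i] = [float(v) for v in fields[1:4]]
    if topology is None:
        atoms = []
        for i, name in enumerate(names):
            element = infer_element(name)
            radius, _ = vdw_radius_for(element, name)
            atoms.append(AtomRecord(i + 1, name, "UNK", i + 1, " ", element, radius))
        topology = Structure(atoms, frames[0], boxes[0] if have_box else None)
    elif topology.n_atoms != n_atoms:
        raise ParseError(
            f"{path}: topology has {topology.n_atoms} atoms, file declares {n_atoms}"
        )
    return Trajectory(
        topology, frames, boxes=boxes if have_box else None, times=times
    )


def write_trajectory_xyzt(traj: Trajectory, path: str) -> None:
    """Write the plain-text xyzt dialect (bitwise-stable %.6f coordinates)."""
    names = [a.name for a in traj.topology.atoms]
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for k in range(traj.n_frames):
            box = (
                traj.boxes[k]
                if traj.boxes is not None
                else (traj.topology.box if traj.topology.box is not None else np.zeros(3))
            )
            fh.write(
                f"t={traj.times[k]:.6f} box={box[0]:.6f} {box[1]:.6f} {box[2]:.6f}\n"
            )
            for name, xyz in zip(names, traj.frames[k]):
                fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# ---------------------------------------------------------------------------
# OpenDX grids
# ---------------------------------------------------------------------------

def write_density_dx(grid: DensityGrid, path: str) -> None:
    """Serialize a DensityGrid as an OpenDX scalar field (z fastest)."""
    if not np.isfinite(grid.values).all():
        raise ValueError("grid contains non-finite values")
    nx, ny, nz = grid.dims
    flat = grid.values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"# memgate density grid, n_frames={grid.n_frames} spill={grid.spill}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(
            f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}\n"
        )
        fh.write(f"delta {grid.spacing[0]:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {grid.spacing[1]:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {grid.spacing[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for i in range(0, flat.size, 3):
            chunk = flat[i : i + 3]
            fh.write(" ".join(f"{v:.9g}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_density_dx(path: str) -> DensityGrid:
    """Read an OpenDX "gridpositions counts" scalar grid."""
    dims = None
    origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    n_items = None
    n_frames = 1
    spill = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                m = re.search(r"n_frames=(\d+)", s)
                if m:
                    n_frames = int(m.group(1))
                m = re.search(r"spill=(\d+)", s)
                if m:
                    spill = int(m.group(1))
                continue
            if s.startswith("object 1"):
                dims = tuple(int(v) for v in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append(np.array([float(v) for v in s.split()[1:4]]))
            elif s.startswith("object 3"):
                n_items = int(s.split()[-3])
            elif s.startswith(("object", "attribute")):
                continue
            elif n_items is not None and len(values) < n_items:
                values.extend(float(v) for v in s.split())
    if dims is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ParseError(f"{path}: not a recognised OpenDX grid")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    arr = np.array(values[:n_items]).reshape(dims, order="C")
    return DensityGrid(origin, spacing, dims, arr, n_frames=n_frames, spill=spill)


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

def read_plate_csv(path: str) -> PlateTable:
    return PlateTable(pd.read_csv(path))


def write_plate_csv(plate: PlateTable, path: str) -> None:
    plate.data.to_csv(path, index=False)
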