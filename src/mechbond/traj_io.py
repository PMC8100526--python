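"""Structure/trajectory containers, PDB and DCD readers, and atom selection.

The central container is :class:`Trajectory`: a static per-atom topology plus
an ``(n_frames, n_atoms, 3)`` coordinate array in Å.  Frames of one trajectory
always share the same atoms in the same order.  Multi-model PDB files (one
MODEL per frame) are the primary text format; DCD + PDB topology pairs are
supported for binary trajectories.

Selections use a small deterministic expression language::

    chain A
    resid 1-10 25
    resname GLY ALA
    name CA CB
    chain A and name CA
    not (chain B or resname HOH)
    all / none

Residue ids follow the input file verbatim (author numbering, 1-based).
"""

from __future__ import annotations

import dataclasses
import io
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "TrajectoryError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]


class TrajectoryError(ValueError):
    """Malformed structure/trajectory input."""


class SelectionError(ValueError):
    """Syntax error in a selection expression; carries the token position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at token position {position})"
        super().__init__(message)


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom of one frame; positions in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise TrajectoryError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


_ELEMENT_FROM_NAME = re.compile(r"[A-Z]")


def _guess_element(atom_name: str) -> str:
    """PDB-convention fallback: first alphabetic character of the atom name.

    Handles the common biomolecular elements (H/C/N/O/S/P); two-letter
    elements must carry an explicit element column.
    """
    stripped = atom_name.strip()
    if stripped[:1].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    m = _ELEMENT_FROM_NAME.search(stripped.upper())
    return m.group(0) if m else "C"


class Frame:
    """A single snapshot: a view onto one row of the trajectory coordinates."""

    def __init__(self, topology: "Topology", coords: np.ndarray, time: float | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (topology.n_atoms, 3):
            raise TrajectoryError(
                f"frame has {coords.shape[0]} coordinate rows for {topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("frame contains non-finite coordinates")
        self.topology = topology
        self.coords = coords
        self.time = time

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def atoms(self) -> list[Atom]:
        top = self.topology
        return [
            Atom(
                serial=int(top.serial[i]),
                name=str(top.name[i]),
                element=str(top.element[i]),
                residue_name=str(top.residue_name[i]),
                residue_id=int(top.residue_id[i]),
                chain_id=str(top.chain_id[i]),
                position=self.coords[i],
            )
            for i in range(top.n_atoms)
        ]


class Topology:
    """Static per-atom metadata shared by all frames of a trajectory."""

    def __init__(
        self,
        name: Sequence[str],
        element: Sequence[str],
        residue_name: Sequence[str],
        residue_id: Sequence[int],
        chain_id: Sequence[str],
        serial: Sequence[int] | None = None,
    ):
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray([e.strip().upper() or "C" for e in element], dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_id = np.asarray(residue_id, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        n = len(self.name)
        if not (len(self.element) == len(self.residue_name) == len(self.residue_id) == len(self.chain_id) == n):
            raise TrajectoryError("topology field lengths differ")
        self.serial = (
            np.asarray(serial, dtype=int) if serial is not None else np.arange(1, n + 1)
        )
        keys = list(zip(self.chain_id, self.residue_id, self.name))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise TrajectoryError(
                        f"duplicate atom (chain={k[0]!r}, resid={k[1]}, name={k[2]!r}) in topology"
                    )
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.name)


class Trajectory:
    """Ordered frames of a (typically two-chain) complex.

    Parameters
    ----------
    topology : Topology
    coords : ndarray, shape (n_frames, n_atoms, 3), Å
    frame_interval : float, ns
        Time between saved frames (the saving stride is a user parameter and
        is never inferred from the input).
    """

    def __init__(self, topology: Topology, coords: np.ndarray, frame_interval: float = 1.0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[0] < 1 or coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames>=1, n_atoms, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"coordinate atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("trajectory contains non-finite coordinates")
        self.topology = topology
        self.coords = coords
        self.frame_interval = float(frame_interval)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], time=float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def select(self, expression: str) -> "AtomSelection":
        return select(self, expression)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.topology.chain_id:
            if c not in seen:
                seen.append(c)
        return seen


@dataclasses.dataclass
class AtomSelection:
    """A resolved selection: its expression and the sorted atom indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(sorted(set(int(i) for i in np.ravel(self.indices))), dtype=int)

    def __len__(self) -> int:
        return len(self.indices)

    def union(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(
            f"({self.expression}) or ({other.expression})",
            np.union1d(self.indices, other.indices),
        )

    def intersection(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(
            f"({self.expression}) and ({other.expression})",
            np.intersect1d(self.indices, other.indices),
        )


# ---------------------------------------------------------------------------
# selection expression parser
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[str]:
    return _TOKEN.findall(expression)


class _Parser:
    """Recursive-descent parser producing a boolean mask over atoms.

    Grammar (lowest to highest precedence)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := "not" factor | "(" expr ")" | primary
        primary := "chain" ID+ | "resid" RANGE+ | "resname" ID+
                 | "name" ID+ | "all" | "none"
    """

    _KEYWORDS = {"and", "or", "not", "chain", "resid", "resname", "name", "all", "none", "(", ")"}

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}", self.pos)
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        if tok.lower() == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionError("missing closing parenthesis", self.pos)
            self.take()
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek().lower() not in self._KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword requires at least one value", self.pos)
        return vals

    def primary(self) -> np.ndarray:
        tok = self.take().lower()
        n = self.top.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "chain":
            vals = set(self._values())
            return np.isin(self.top.chain_id, list(vals))
        if tok == "resname":
            vals = {v.upper() for v in self._values()}
            return np.isin([r.upper() for r in self.top.residue_name], list(vals))
        if tok == "name":
            vals = {v.upper() for v in self._values()}
            return np.isin([a.upper() for a in self.top.name], list(vals))
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad resid token {v!r}", self.pos - 1)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                # an empty range (e.g. "1-0") is a legal empty selection
                mask |= (self.top.residue_id >= lo) & (self.top.residue_id <= hi)
            return mask
        raise SelectionError(f"unknown keyword {tok!r}", self.pos - 1)


def select(traj: Trajectory, expression: str) -> AtomSelection:
    """Resolve a selection expression on a trajectory's topology.

    Resolution is deterministic: indices are returned sorted, and AND/OR are
    commutative on the resulting sets.  Empty selections are legal.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty expression", 0)
    mask = _Parser(tokens, traj.topology).parse()
    return AtomSelection(expression, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _stack_to_trajectory(stack, frame_interval: float) -> Trajectory:
    import biotite.structure as struc

    if stack.array_length() == 0:
        raise TrajectoryError("structure contains no atoms")
    if isinstance(stack, struc.AtomArray):
        coords = np.asarray(stack.coord, dtype=float)[None, :, :]
        first = stack
    else:
        coords = np.asarray(stack.coord, dtype=float)
        first = stack[0]
    element = [
        e if e else _guess_element(n)
        for e, n in zip(first.element, first.atom_name)
    ]
    top = Topology(
        name=list(first.atom_name),
        element=element,
        residue_name=list(first.res_name),
        residue_id=list(first.res_id),
        chain_id=list(first.chain_id),
    )
    return Trajectory(top, coords, frame_interval=frame_interval)


def read_structure(path: str | Path, format: str = "pdb", frame_interval: float = 1.0) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory, one frame per MODEL.

    Chain ids, author residue numbering, atom names and element symbols are
    preserved verbatim; coordinates are Å.  Alternate locations: only the
    blank/first altloc is kept.  Models that differ in atom count are an
    error (frames of one trajectory must share a topology).
    """
    if format.lower() != "pdb":
        raise TrajectoryError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import biotite.structure.io.pdb as pdb

    _check_model_sizes(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises various parse errors
        raise TrajectoryError(_annotate_pdb_error(path, exc)) from exc
    return _stack_to_trajectory(stack, frame_interval)


def _check_model_sizes(path: Path) -> None:
    """All MODEL blocks of a multi-model PDB must have the same atom count."""
    counts: list[int] = []
    current: int | None = None
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            current = 0
        elif line.startswith("ENDMDL"):
            if current is not None:
                counts.append(current)
            current = None
        elif line.startswith(("ATOM", "HETATM")) and current is not None:
            current += 1
    if counts and len(set(counts)) > 1:
        raise TrajectoryError(
            f"models in {path} differ in atom count: {sorted(set(counts))}"
        )


def _annotate_pdb_error(path: Path, exc: Exception) -> str:
    """Best-effort line-number diagnosis for malformed ATOM records."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return f"malformed ATOM record at line {lineno} of {path}: {line!r}"
    return f"cannot parse PDB file {path}: {exc}"


def write_structure(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    top = traj.topology
    stack.chain_id = np.asarray(top.chain_id, dtype="U4")
    stack.res_id = np.asarray(top.residue_id)
    stack.res_name = np.asarray(top.residue_name, dtype="U5")
    stack.atom_name = np.asarray(top.name, dtype="U6")
    stack.element = np.asarray(top.element, dtype="U2")
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path,
    format: str = "dcd",
    frame_interval: float = 1.0,
) -> Trajectory:
    """Read a binary trajectory (DCD) with a PDB/PSF topology.

    The topology atom count must equal the trajectory atom count.
    Coordinates are returned in Å, frames in file order.
    """
    if format.lower() != "dcd":
        raise TrajectoryError(f"unsupported trajectory format {format!r}")
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path), str(coords_path))
    ref = read_structure(topology_path) if str(topology_path).endswith(".pdb") else None
    if ref is not None and ref.n_atoms != len(u.atoms):
        raise TrajectoryError(
            f"topology atom count {ref.n_atoms} != trajectory atom count {len(u.atoms)}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if ref is not None:
        return Trajectory(ref.topology, coords, frame_interval=frame_interval)
    atoms = u.atoms
    top = Topology(
        name=[a.name for a in atoms],
        element=[getattr(a, "element", "") or _guess_element(a.name) for a in atoms],
        residue_name=[a.resname for a in atoms],
        residue_id=[int(a.resid) for a in atoms],
        chain_id=[getattr(a, "chainID", "") or getattr(a, "segid", "A")[:1] for a in atoms],
    )
    return Trajectory(top, coords, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, topology_path: str | Path, coords_path: str | Path) -> None:
    """Write topology as single-model PDB and coordinates as DCD."""
    import MDAnalysis as mda

    single = Trajectory(traj.topology, traj.coords[:1], traj.frame_interval)
    write_structure(single, topology_path)
    u = mda.Universe(str(topology_path))
    with mda.Writer(str(coords_path), n_atoms=traj.n_atoms) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coords[i]
            w.write(u.atoms)
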