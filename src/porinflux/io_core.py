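"""Structures, trajectories, atom selections and formal charges.

This module defines the in-memory data model every analysis stage consumes:
:class:`StructureModel` (a static channel / ion system), :class:`Trajectory`
(time-ordered coordinate frames), a small deterministic atom-selection
mini-language, and a pH-7 formal-charge assignment for the standard amino
acids.

Structures are read and written as PDB through :mod:`gemmi`; binary
trajectories (XTC/DCD/TRR) are read through :mod:`MDAnalysis`.  A plain-text
trajectory dialect ("fixture-text") is provided so that hand-written oracle
trajectories stay diffable: one header line ``n_atoms dt_ns``, then per frame
a box line ``box bx by bz`` followed by one line per atom ``id x y z``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Van der Waals radii by element symbol (A).  Values follow the common
# Bondi/row tables; elements not listed fall back to DEFAULT_VDW_RADIUS.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.63,
    "X": 1.50,
}
DEFAULT_VDW_RADIUS = 1.50

# residue -> (formal charge at pH 7, designated side-chain carrier atom)
PH7_CHARGES = {
    "ASP": (-1, "CG"),
    "GLU": (-1, "CD"),
    "LYS": (+1, "NZ"),
    "ARG": (+1, "CZ"),
    "HIS": (0, "NE2"),
}

# monatomic ions commonly present as HETATM records; kept when stripping
ION_RESNAMES = {"K", "CL", "NA", "MG", "CA", "ZN", "MN", "FE", "BR", "IOD", "CS"}


class SelectionError(ValueError):
    """Raised on a malformed selection expression."""


class StructureParseError(ValueError):
    """Raised on an unreadable or malformed structure file."""


@dataclass
class AtomRecord:
    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray  # (3,) A
    vdw_radius: float = DEFAULT_VDW_RADIUS
    formal_charge: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_id}: vdw_radius must be > 0")


@dataclass
class StructureModel:
    atoms: list[AtomRecord]
    box: np.ndarray | None = None  # (3,) A

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("atom_ids must be unique")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_by_id(self, atom_id: int) -> AtomRecord:
        try:
            return self._id_index[atom_id]
        except AttributeError:
            self._id_index = {a.atom_id: a for a in self.atoms}
            return self._id_index[atom_id]

    def index_of(self, atom_id: int) -> int:
        try:
            return self._pos_index[atom_id]
        except AttributeError:
            self._pos_index = {a.atom_id: i for i, a in enumerate(self.atoms)}
            return self._pos_index[atom_id]

    def total_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)


@dataclass
class Trajectory:
    """Time-ordered coordinate frames over a fixed atom set.

    ``coords`` has shape (n_frames, n_atoms, 3) in A; ``times`` are strictly
    increasing, in ns; ``boxes`` has shape (n_frames, 3).
    """

    structure: StructureModel
    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != structure atom "
                f"count {self.structure.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.boxes.shape != (len(self.times), 3):
            raise ValueError("boxes must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SelectionExpr:
    expression: str


# ---------------------------------------------------------------------------
# selection mini-language
#
# grammar:   expr    := term ("or" term)*
#            term    := factor ("and" factor)*
#            factor  := "not" factor | "(" expr ")" | primary
#            primary := "all" | "chain" ID+ | "resname" ID+ | "name" ID+
#                       | "resid" RANGE+        (RANGE = N or N-M)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")
_KEYWORDS = {"and", "or", "not", "(", ")", "all", "chain", "resname", "name", "resid"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, structure: StructureModel, expr: str):
        self.structure = structure
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0
        self.n = structure.n_atoms

    def _peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _fail(self, msg, pos=None):
        if pos is None:
            pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expr)
        raise SelectionError(f"{msg} at position {pos} in {self.expr!r}")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self._fail("empty selection", 0)
        mask = self._expr()
        if self.i < len(self.tokens):
            self._fail(f"unexpected token {self._peek()!r}")
        return mask

    def _expr(self):
        mask = self._term()
        while self._peek() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self):
        mask = self._factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            if self._peek() != ")":
                self._fail("expected ')'")
            self._next()
            return mask
        return self._primary()

    def _values(self):
        vals = []
        while self._peek() is not None and self._peek() not in _KEYWORDS:
            vals.append(self._next()[0])
        if not vals:
            self._fail("expected at least one value")
        return vals

    def _primary(self):
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of expression")
        if tok == "all":
            self._next()
            return np.ones(self.n, dtype=bool)
        if tok in ("chain", "resname", "name"):
            self._next()
            vals = set(self._values())
            attr = {"chain": "chain_id", "resname": "residue_name", "name": "name"}[tok]
            return np.array([getattr(a, attr) in vals for a in self.structure.atoms])
        if tok == "resid":
            self._next()
            ranges = []
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    self._fail(f"bad resid range {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                ranges.append((lo, hi))
            return np.array(
                [any(lo <= a.residue_id <= hi for lo, hi in ranges)
                 for a in self.structure.atoms]
            )
        self._fail(f"unknown keyword {tok!r}")


def select_atoms(structure: StructureModel, expr: SelectionExpr | str) -> list[int]:
    """Resolve a selection expression to a sorted list of atom_ids.

    The result is deterministic and sorted by atom_id; an empty selection is
    legal and returns ``[]``.
    """
    text = expr.expression if isinstance(expr, SelectionExpr) else expr
    mask = _Parser(structure, text).parse()
    ids = [a.atom_id for a, m in zip(structure.atoms, mask) if m]
    return sorted(ids)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def vdw_for(element: str) -> float:
    """Van der Waals radius for an element symbol (table lookup, with a
    documented 1.50 A default for unknown elements)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


_vdw_for = vdw_for


def read_structure(path: str | Path, format: str = "pdb",
                   keep_hetatm_ions: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    All ATOM records are kept; HETATM records are stripped except monatomic
    ions (waters and ligands are not part of the analyses here — the choice
    is logged).  Only the first altloc of each atom is kept; insertion codes
    are rejected.
    """
    import gemmi

    path = Path(path)
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no model records")

    atoms: list[AtomRecord] = []
    n_stripped = 0
    atom_id = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.seqid.icode not in ("", " "):
                raise StructureParseError(
                    f"{path}: insertion code on residue {chain.name} "
                    f"{residue.seqid.num}{residue.seqid.icode} is not supported"
                )
            het = residue.het_flag == "H"
            resname = residue.name.strip()
            if het and resname not in ION_RESNAMES:
                n_stripped += 1
                continue
            seen_names = set()
            for atom in residue:
                if atom.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(atom.name)
                element = atom.element.name.upper() if atom.element else "X"
                atoms.append(AtomRecord(
                    atom_id=atom_id,
                    name=atom.name,
                    element=element,
                    residue_name=resname,
                    residue_id=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    vdw_radius=_vdw_for(element),
                ))
                atom_id += 1
    if n_stripped:
        logger.info("read_structure: stripped %d non-ion HETATM residues", n_stripped)
    if not atoms:
        raise StructureParseError(f"{path}: no atoms parsed")
    box = None
    if st.cell and st.cell.a > 1.0:
        box = np.array([st.cell.a, st.cell.b, st.cell.c])
    return StructureModel(atoms=atoms, box=box)


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as a single-model PDB file."""
    import gemmi

    st = gemmi.Structure()
    if structure.box is not None:
        st.cell = gemmi.UnitCell(*structure.box, 90, 90, 90)
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        if (len(chain) == 0 or chain[-1].seqid.num != a.residue_id
                or chain[-1].name != a.residue_name):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_id, " ")
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(*a.position)
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, structure: StructureModel,
                    format: str | None = None) -> Trajectory:
    """Read a trajectory; format inferred from the extension if not given.

    Supported: ``xtc``, ``dcd``, ``trr`` (via MDAnalysis; times converted
    from ps to ns) and ``fixture-text`` (extension ``.traj``).
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower().lstrip(".")
        format = "fixture-text" if ext in ("traj", "txt") else ext
    if format == "fixture-text":
        return _read_fixture_text(path, structure)
    if format not in ("xtc", "dcd", "trr"):
        raise ValueError(f"unsupported trajectory format {format!r}")

    import MDAnalysis as mda

    u = mda.Universe.empty(structure.n_atoms, trajectory=True)
    u.load_new(str(path))
    if u.trajectory.n_atoms != structure.n_atoms:
        raise ValueError(
            f"{path}: atom count {u.trajectory.n_atoms} != structure "
            f"atom count {structure.n_atoms}"
        )
    coords, times, boxes = [], [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        times.append(ts.time / 1000.0)  # ps -> ns
        dims = ts.dimensions
        if dims is None or not np.any(dims[:3]):
            boxes.append(np.full(3, np.nan))
        else:
            boxes.append(np.asarray(dims[:3], dtype=float))
    return Trajectory(structure=structure, times=np.array(times),
                      coords=np.array(coords), boxes=np.array(boxes))


def _read_fixture_text(path: Path, structure: StructureModel) -> Trajectory:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty trajectory file")
    header = lines[0].split()
    n_atoms, dt = int(header[0]), float(header[1])
    if n_atoms != structure.n_atoms:
        raise ValueError(
            f"{path}: atom count {n_atoms} != structure atom count "
            f"{structure.n_atoms}"
        )
    frame_len = n_atoms + 1  # box line + atoms
    body = lines[1:]
    if len(body) % frame_len:
        raise ValueError(f"{path}: truncated frame (got {len(body)} lines)")
    n_frames = len(body) // frame_len
    coords = np.empty((n_frames, n_atoms, 3))
    boxes = np.empty((n_frames, 3))
    for f in range(n_frames):
        block = body[f * frame_len:(f + 1) * frame_len]
        btok = block[0].split()
        if btok[0] != "box":
            raise ValueError(f"{path}: frame {f}: expected box line, got {block[0]!r}")
        boxes[f] = [float(x) for x in btok[1:4]]
        for j, ln in enumerate(block[1:]):
            tok = ln.split()
            coords[f, j] = [float(x) for x in tok[1:4]]
    times = np.arange(n_frames) * dt
    return Trajectory(structure=structure, times=times, coords=coords, boxes=boxes)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the fixture-text dialect.

    Assumes uniformly spaced frames; dt is taken from the first interval
    (0 for a single frame).
    """
    dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(f"{traj.coords.shape[1]} {dt:.9g}\n")
        for f in range(traj.n_frames):
            bx, by, bz = traj.boxes[f]
            fh.write(f"box {bx:.6f} {by:.6f} {bz:.6f}\n")
            for j, a in enumerate(traj.structure.atoms):
                x, y, z = traj.coords[f, j]
                fh.write(f"{a.atom_id} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# formal charges
# ---------------------------------------------------------------------------

def assign_formal_charges(structure: StructureModel,
                          scheme: str = "pH7-standard") -> StructureModel:
    """Assign per-residue formal charges for the standard pH-7 protonation.

    ASP/GLU carry -1, LYS/ARG +1, HIS 0; the charge is attached to one
    designated side-chain atom per residue (falling back to CA, then to the
    residue's first atom).  Termini are left neutral.  Unknown residues get
    0 and are logged.  The operation is idempotent and returns a new model.
    """
    if scheme != "pH7-standard":
        raise ValueError(f"unknown charge scheme {scheme!r}")
    new_atoms = [replace(a, formal_charge=0) for a in structure.atoms]
    by_residue: dict[tuple, list[AtomRecord]] = {}
    for a in new_atoms:
        by_residue.setdefault((a.chain_id, a.residue_id, a.residue_name), []).append(a)
    unknown: set[str] = set()
    for (chain, resid, resname), res_atoms in by_residue.items():
        entry = PH7_CHARGES.get(resname)
        if entry is None:
            if resname in ION_RESNAMES:
                q = {"K": 1, "NA": 1, "CS": 1, "CL": -1, "BR": -1, "IOD": -1,
                     "MG": 2, "CA": 2, "ZN": 2, "MN": 2, "FE": 2}.get(resname, 0)
                if q:
                    res_atoms[0].formal_charge = q
            elif resname not in ("GLY", "ALA", "VAL", "LEU", "ILE", "PRO",
                                 "PHE", "TRP", "MET", "SER", "THR", "CYS",
                                 "TYR", "ASN", "GLN", "HOH"):
                unknown.add(resname)
            continue
        q, carrier = entry
        if q == 0:
            continue
        target = next((a for a in res_atoms if a.name == carrier), None)
        if target is None:
            target = next((a for a in res_atoms if a.name == "CA"), res_atoms[0])
        target.formal_charge = q
    if unknown:
        logger.info("assign_formal_charges: unknown residues assigned 0: %s",
                    ", ".join(sorted(unknown)))
    return StructureModel(atoms=new_atoms, box=structure.box)
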