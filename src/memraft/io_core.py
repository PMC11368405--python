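"""Domain types, structure/trajectory I/O, atom selection, and periodic-distance utilities.

All coordinates are stored in nanometers internally.  PDB files (which use
Angstrom) are converted at the boundary; reporting helpers elsewhere emit
Angstrom where crystallographic convention calls for it.

File parsing is delegated to MDAnalysis; the light-weight containers here
only keep what the analysis stages need (labeled atoms, per-frame coordinates,
orthorhombic box vectors and times).
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "ParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "select",
    "min_image_distance",
    "minimum_image",
]

ANGSTROM_PER_NM = 10.0


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is malformed."""


@dataclass
class AtomRecord:
    """One atom: identity, coordinates (nm) and the PDB bookkeeping columns.

    ``radius`` is optional per-atom metadata (nm) used by pseudo-atom sphere
    clusters for surface-area work; ordinary file readers leave it ``None``.
    """

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    radius: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")


@dataclass
class Structure:
    """An ordered set of atoms with an optional orthorhombic box (nm)."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive orthorhombic edge lengths")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in Structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in nm."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """Frames of coordinates (nm) over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``boxes`` is (n_frames, 3) in
    nm or ``None`` for non-periodic data; ``times`` is in ps and must be
    strictly increasing.
    """

    topology: Structure
    coords: np.ndarray
    boxes: np.ndarray | None
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (self.coords.shape[0], 3):
                raise ValueError("boxes must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box_at(self, frame: int) -> np.ndarray | None:
        return None if self.boxes is None else self.boxes[frame]


@dataclass
class Selection:
    """Ordered, duplicate-free atom indices into an owning topology."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("Selection indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("Selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.upper()
        if f not in {"PDB", "GRO", "XTC"}:
            raise ValueError(f"unknown format {fmt!r}; expected PDB, GRO or XTC")
        return f
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in {"pdb", "ent"}:
        return "PDB"
    if ext in {"gro", "xtc"}:
        return ext.upper()
    raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")


def _check_orthorhombic(dimensions) -> np.ndarray | None:
    """MDAnalysis dimensions [lx,ly,lz,alpha,beta,gamma] (A, deg) -> box nm."""
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ParseError(
            f"triclinic box (angles {dims[3:]}) not supported; orthorhombic only"
        )
    return dims[:3] / ANGSTROM_PER_NM


def _universe_to_structure(u) -> Structure:
    atoms = []
    n = len(u.atoms)
    names = getattr(u.atoms, "names", ["X"] * n)
    resnames = getattr(u.atoms, "resnames", ["UNK"] * n)
    resids = getattr(u.atoms, "resids", np.arange(1, n + 1))
    try:
        chains = u.atoms.chainIDs
    except AttributeError:
        try:
            chains = u.atoms.segids
        except AttributeError:
            chains = [""] * n
    try:
        elements = u.atoms.elements
    except AttributeError:
        elements = [_element_from_name(nm) for nm in names]
    try:
        occ = u.atoms.occupancies
    except AttributeError:
        occ = np.ones(n)
    try:
        bf = u.atoms.tempfactors
    except AttributeError:
        bf = np.zeros(n)
    pos_nm = u.atoms.positions / ANGSTROM_PER_NM
    for i in range(n):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(names[i]),
                resname=str(resnames[i]),
                resid=int(resids[i]),
                chain=str(chains[i]).strip(),
                element=str(elements[i]).strip(),
                coords=pos_nm[i],
                occupancy=float(occ[i]),
                bfactor=float(bf[i]),
            )
        )
    box = _check_orthorhombic(u.dimensions)
    return Structure(atoms=atoms, box=box)


def _element_from_name(name: str) -> str:
    m = re.search(r"[A-Za-z]", name)
    return m.group(0).upper() if m else "X"


def read_structure(path: str, fmt: str | None = None) -> Structure:
    """Read a single-model PDB or GRO file into a :class:`Structure` (nm)."""
    import MDAnalysis as mda

    f = _guess_format(path, fmt)
    if f == "XTC":
        raise ValueError("XTC carries no topology; use read_trajectory")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=f)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ParseError(f"could not parse {path!r} as {f}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ParseError(f"{path!r} contains no atoms")
    return _universe_to_structure(u)


def write_structure(structure: Structure, path: str) -> None:
    """Write a Structure as a single-model PDB file (coordinates nm -> A)."""
    import MDAnalysis as mda

    n = structure.n_atoms
    if n == 0:
        raise ValueError("cannot write an empty Structure")
    # residues are runs of identical (chain, resid, resname)
    res_keys, atom_resindex = [], []
    for a in structure.atoms:
        key = (a.chain, a.resid, a.resname)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex.append(len(res_keys) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(res_keys),
            atom_resindex=np.array(atom_resindex),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in structure.atoms])
        u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
        u.add_TopologyAttr("occupancies", [a.occupancy for a in structure.atoms])
        u.add_TopologyAttr("tempfactors", [a.bfactor for a in structure.atoms])
        u.add_TopologyAttr("chainIDs", [(a.chain or "A")[:1] for a in structure.atoms])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.atoms.positions = structure.coords * ANGSTROM_PER_NM
        if structure.box is not None:
            u.dimensions = np.concatenate(
                [structure.box * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
            )
        u.atoms.write(path)


def _pdb_model_atom_counts(path: str) -> list[int]:
    """Atom counts per MODEL block (or one count for a single-model file)."""
    counts, current, in_model, seen_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model, in_model, current = True, True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in {"ATOM", "HETATM"}:
                current += 1
    if not seen_model:
        return [current]
    if in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_trajectory(
    frames_path,
    topology_path: str | None = None,
    fmt: str | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, GRO sequence, or XTC) in nm/ps.

    Parameters
    ----------
    frames_path : str or list of str
        Multi-model PDB, XTC file, or an ordered list of GRO/PDB frame files.
    topology_path : str, optional
        Topology file (required for XTC; defaults to the first frame file).
    dt : float, optional
        Frame spacing in ps used when the format carries no time stamps
        (times become ``index * dt``); defaults to 1 ps.
    """
    import MDAnalysis as mda

    paths = list(frames_path) if isinstance(frames_path, (list, tuple)) else [frames_path]
    first = paths[0]
    f = _guess_format(first, fmt)

    if f == "PDB" and len(paths) == 1:
        counts = _pdb_model_atom_counts(first)
        if len(set(counts)) > 1:
            bad = next(i for i, c in enumerate(counts) if c != counts[0])
            raise ParseError(
                f"frame {bad} atom-count mismatch ({counts[bad]} vs {counts[0]} atoms)"
            )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if f == "XTC":
                if topology_path is None:
                    raise ValueError("XTC trajectories require a topology file")
                u = mda.Universe(topology_path, *paths)
            elif len(paths) > 1:
                u = mda.Universe(topology_path or first, paths)
            else:
                u = mda.Universe(topology_path or first, first, format=f)
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not read trajectory {first!r}: {exc}") from exc

    topology = _universe_to_structure(u)
    n = topology.n_atoms
    coords, boxes, times, has_time = [], [], [], True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, ts in enumerate(u.trajectory):
            if len(u.atoms) != n:
                raise ParseError(f"frame {k} atom-count mismatch")
            coords.append(u.atoms.positions / ANGSTROM_PER_NM)
            box = _check_orthorhombic(ts.dimensions)
            boxes.append(box if box is not None else np.full(3, np.nan))
            t = getattr(ts, "time", None)
            if t is None:
                has_time = False
                t = float(k)
            times.append(float(t))
            has_time = has_time and getattr(ts, "data", {}).get("time") is not None
    coords = np.array(coords)
    boxes_arr = np.array(boxes)
    if np.all(np.isnan(boxes_arr)):
        boxes_out = None
    else:
        boxes_out = boxes_arr
    if f == "XTC" and has_time and dt is None:
        times_out = np.array(times)
    else:
        step = dt if dt is not None else 1.0
        times_out = np.arange(len(coords)) * step
    return Trajectory(topology=topology, coords=coords, boxes=boxes_out, times=times_out)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"resname", "name", "resid", "chain", "all", "none"}
_OPERATORS = {"and", "or", "not"}


def _tokenize(expression: str):
    tokens = []
    for m in re.finditer(r"\(|\)|[^\s()]+", expression):
        tokens.append((m.group(0), m.start()))
    return tokens


class _Parser:
    """Recursive-descent parser for the tiny selection grammar.

    expr  := term (('and'|'or') term)*   with 'and' binding tighter than 'or'
    term  := 'not' term | '(' expr ')' | keyword value+
    """

    def __init__(self, tokens, topology: Structure, expression: str):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.expr = expression

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _error(self, msg):
        col = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expr)
        raise SelectionError(f"{msg} at position {col} in {self.expr!r}")

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.pos < len(self.tokens):
            self._error(f"unexpected token {self._peek()!r}")
        return mask

    def parse_or(self):
        mask = self.parse_and()
        while self._peek() == "or":
            self.pos += 1
            mask = mask | self.parse_and()
        return mask

    def parse_and(self):
        mask = self.parse_unary()
        while self._peek() == "and":
            self.pos += 1
            mask = mask & self.parse_unary()
        return mask

    def parse_unary(self):
        tok = self._peek()
        if tok is None:
            self._error("unexpected end of expression")
        if tok == "not":
            self.pos += 1
            return ~self.parse_unary()
        if tok == "(":
            self.pos += 1
            mask = self.parse_or()
            if self._peek() != ")":
                self._error("expected ')'")
            self.pos += 1
            return mask
        if tok in _KEYWORDS:
            return self.parse_keyword()
        self._error(f"unexpected token {tok!r}")

    def _collect_values(self):
        values = []
        while True:
            tok = self._peek()
            if tok is None or tok in _KEYWORDS or tok in _OPERATORS or tok in "()":
                break
            values.append(tok)
            self.pos += 1
        if not values:
            self._error("keyword requires at least one value")
        return values

    def parse_keyword(self):
        kw = self._peek()
        self.pos += 1
        n = self.top.n_atoms
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw == "none":
            return np.zeros(n, dtype=bool)
        values = self._collect_values()
        if kw == "resname":
            wanted = set(values)
            return np.array([a.resname in wanted for a in self.top.atoms])
        if kw == "name":
            wanted = set(values)
            return np.array([a.name in wanted for a in self.top.atoms])
        if kw == "chain":
            wanted = set(values)
            return np.array([a.chain in wanted for a in self.top.atoms])
        if kw == "resid":
            allowed = set()
            for v in values:
                m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", v)
                if m is None:
                    self._error(f"bad resid specifier {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                allowed.update(range(lo, hi + 1))
            return np.array([a.resid in allowed for a in self.top.atoms])
        self._error(f"unknown keyword {kw!r}")


def select(topology: Structure, expression: str, label: str | None = None) -> Selection:
    """Select atoms with a boolean mini-language.

    Supported keywords: ``resname``, ``name``, ``chain`` (one or more values),
    ``resid`` (values or ``lo-hi`` ranges), ``all``, ``none``; combined with
    ``and``/``or``/``not`` and parentheses.  Empty selections are allowed.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology, expression).parse()
    return Selection(indices=np.flatnonzero(mask), label=label or expression)


# ---------------------------------------------------------------------------
# periodic-distance utilities (orthorhombic minimum-image convention)
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vector(s) into the minimum-image cell."""
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0) or np.any(~np.isfinite(box)):
        return delta
    return delta - box * np.round(delta / box)


def min_image_distance(a, b, box=None) -> float:
    """Euclidean distance under the orthorhombic minimum-image convention.

    With no box the plain Euclidean distance is returned.
    """
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), box)
    return float(np.linalg.norm(d))


def min_image_distance_matrix(xa: np.ndarray, xb: np.ndarray, box=None) -> np.ndarray:
    """All-pairs minimum-image distances between two coordinate sets (nm)."""
    delta = xa[:, None, :] - xb[None, :, :]
    delta = minimum_image(delta, box)
    return np.sqrt(np.sum(delta * delta, axis=-1))
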