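"""Structure, trajectory and parameter-table I/O plus atom selection.

The reference on-disk trajectory format is multi-model PDB (one ``MODEL``
block per frame), read and written through :mod:`biotite`.  Per-atom force
field style parameters (partial charge, Lennard-Jones sigma/epsilon, Born
radius) are not part of PDB and are supplied separately as a TSV table keyed
by ``(res_name, atom_name)``.

Coordinates are in Angstrom, times in nanoseconds, residue numbering is
1-based per PDB convention and ``resid`` ranges in the selection grammar are
inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "FormatError",
    "SelectionError",
    "WATER_RES_NAMES",
    "WATER_OXYGEN_NAMES",
    "BACKBONE_NAMES",
    "DEFAULT_DT_NS",
    "read_pdb_models",
    "write_pdb_models",
    "read_param_table",
    "apply_param_table",
    "select",
]

#: Default frame spacing in ns when the source file carries no times
#: (160 ns sampled as 1600 snapshots).
DEFAULT_DT_NS = 0.1

WATER_RES_NAMES = frozenset({"HOH", "WAT", "SOL"})
WATER_OXYGEN_NAMES = frozenset({"O", "OW", "OH2"})
BACKBONE_NAMES = ("N", "CA", "C", "O")

PARAM_COLUMNS = (
    "res_name",
    "atom_name",
    "charge",
    "lj_sigma",
    "lj_epsilon",
    "born_radius",
    "mass",
)


class FormatError(ValueError):
    """Raised for malformed structure files or parameter tables."""


class SelectionError(ValueError):
    """Raised for syntax errors in selection expressions."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass
class Atom:
    """One atom with identity and (optional) energetic parameters.

    Parameters default to zero until a parameter table is applied;
    zero LJ epsilon simply means the atom contributes no van der Waals
    term, and zero Born radius means no Born screening function.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str
    mass: float = 0.0
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    born_radius: float = 0.0

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError(f"atom {self.serial}: negative mass")
        for attr in ("lj_sigma", "lj_epsilon", "born_radius"):
            if getattr(self, attr) < 0:
                raise ValueError(f"atom {self.serial}: negative {attr}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Topology:
    """Ordered atom list plus named atom-index groups.

    Standard group names are ``"carrier"``, ``"ligand"`` and ``"solvent"``;
    water residues (HOH/WAT/SOL) always belong to the solvent group.
    """

    atoms: list[Atom]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        seen: set[int] = set()
        for gname, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {gname!r}: index out of range")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(
                    f"group {gname!r} overlaps another group at indices {sorted(overlap)[:5]}"
                )
            seen.update(idx.tolist())
            self.groups[gname] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of the oxygen atom representing each water molecule."""
        return np.array(
            [
                i
                for i, a in enumerate(self.atoms)
                if a.res_name.upper() in WATER_RES_NAMES
                and a.name.upper() in WATER_OXYGEN_NAMES
            ],
            dtype=int,
        )

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def default_groups(self) -> None:
        """Populate carrier/ligand/solvent groups by residue identity.

        Solvent = water residues; ligand = chain L; carrier = the rest.
        Only used when the caller supplies no explicit grouping.
        """
        solvent, ligand, carrier = [], [], []
        for i, a in enumerate(self.atoms):
            if a.res_name.upper() in WATER_RES_NAMES:
                solvent.append(i)
            elif a.chain_id == "L":
                ligand.append(i)
            else:
                carrier.append(i)
        self.groups = {
            "carrier": np.array(carrier, dtype=int),
            "ligand": np.array(ligand, dtype=int),
            "solvent": np.array(solvent, dtype=int),
        }


@dataclass
class Trajectory:
    """Ordered frames of coordinates with timestamps and optional box.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times`` is in
    ns and strictly increasing; ``box`` is either None or an (n_frames, 3)
    array of orthorhombic box edge lengths in Angstrom.
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.coords.shape[0], 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_box(self, f: int) -> np.ndarray | None:
        return None if self.box is None else self.box[f]


@dataclass(frozen=True)
class AtomSelection:
    """A sorted, duplicate-free set of indices into a Topology."""

    indices: np.ndarray

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __and__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.intersect1d(self.indices, other.indices))

    def __or__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.union1d(self.indices, other.indices))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb_models(path, dt: float = DEFAULT_DT_NS) -> tuple[Topology, Trajectory]:
    """Read a multi-model PDB into a (Topology, Trajectory) pair.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  Frame times are ``frame_index * dt`` (ns).  Charges and LJ/Born
    parameters are zero until :func:`apply_param_table` is called; masses are
    filled from the element.
    """
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged models
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no atoms")

    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]) or _guess_element(str(stack.atom_name[i]))
        try:
            mass = float(struc_info.mass(element))
        except Exception:
            mass = 0.0
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(stack.atom_name[i]),
                element=element,
                res_name=str(stack.res_name[i]),
                res_id=int(stack.res_id[i]),
                chain_id=str(stack.chain_id[i]),
                mass=mass,
            )
        )
    topology = Topology(atoms)
    topology.default_groups()

    n_frames = stack.stack_depth()
    times = np.arange(n_frames) * dt
    box = None
    if stack.box is not None:
        diag = np.array([np.diag(stack.box[f]) for f in range(n_frames)])
        if np.any(diag > 0):
            box = diag
    trajectory = Trajectory(coords=stack.coord.copy(), times=times, box=box)
    return topology, trajectory


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_pdb_models(topology: Topology, trajectory: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (coordinates to 3 decimals)."""
    if trajectory.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    if trajectory.n_atoms != topology.n_atoms:
        raise ValueError("trajectory/topology atom count mismatch")
    if not np.all(np.isfinite(trajectory.coords)):
        raise ValueError("non-finite coordinates")

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in topology.atoms])
    arr.res_id = np.array([a.res_id for a in topology.atoms])
    arr.res_name = np.array([a.res_name for a in topology.atoms])
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.array(
        [a.res_name.upper() in WATER_RES_NAMES for a in topology.atoms]
    )
    arrays = []
    for f in range(trajectory.n_frames):
        frame = arr.copy()
        frame.coord = trajectory.coords[f]
        arrays.append(frame)
    stack = struc.stack(arrays)
    if trajectory.box is not None:
        stack.box = np.array([np.diag(b) for b in trajectory.box])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def read_param_table(path) -> dict[tuple[str, str], dict[str, float]]:
    """Read a TSV per-atom parameter table keyed by (res_name, atom_name).

    Required columns: res_name, atom_name, charge, lj_sigma, lj_epsilon,
    born_radius, mass.  Duplicate keys and missing columns are format errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"res_name": str, "atom_name": str})
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing columns: {missing}")
    table: dict[tuple[str, str], dict[str, float]] = {}
    for _, row in df.iterrows():
        key = (str(row["res_name"]), str(row["atom_name"]))
        if key in table:
            raise FormatError(f"duplicate parameter key {key}")
        table[key] = {
            "charge": float(row["charge"]),
            "lj_sigma": float(row["lj_sigma"]),
            "lj_epsilon": float(row["lj_epsilon"]),
            "born_radius": float(row["born_radius"]),
            "mass": float(row["mass"]),
        }
    return table


def apply_param_table(
    topology: Topology, table: dict[tuple[str, str], dict[str, float]]
) -> list[int]:
    """Set per-atom parameters from a table; return unmatched atom indices.

    Idempotent: applying the same table twice leaves the topology unchanged.
    """
    unmatched = []
    for i, atom in enumerate(topology.atoms):
        params = table.get((atom.res_name, atom.name))
        if params is None:
            unmatched.append(i)
            continue
        atom.charge = params["charge"]
        atom.lj_sigma = params["lj_sigma"]
        atom.lj_epsilon = params["lj_epsilon"]
        atom.born_radius = params["born_radius"]
        atom.mass = params["mass"]
    return unmatched


def params_table_to_tsv(table: dict[tuple[str, str], dict[str, float]], path) -> None:
    """Write a parameter mapping back out as the canonical TSV."""
    rows = [
        {"res_name": rn, "atom_name": an, **params}
        for (rn, an), params in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=list(PARAM_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar:
#   expr    := or_expr
#   or_expr := and_expr ("or" and_expr)*
#   and_expr:= not_expr ("and" not_expr)*
#   not_expr:= "not" not_expr | primary
#   primary := "(" expr ")" | "chain" ID | "resid" INT["-"INT]
#            | "resname" NAME+ | "name" NAME+ | "backbone" | "water"

_KEYWORDS = {"chain", "resid", "resname", "name", "backbone", "water",
             "and", "or", "not", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, topology: Topology, expression: str):
        self.topology = topology
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expression))

    def advance(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        mask = self.parse_or()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek()[0] == "or":
            self.advance()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek()[0] == "and":
            self.advance()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek()[0] == "not":
            self.advance()
            return ~self.parse_not()
        return self.parse_primary()

    def parse_primary(self) -> np.ndarray:
        tok, at = self.advance()
        atoms = self.topology.atoms
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        if tok == "(":
            mask = self.parse_or()
            close, cat = self.advance()
            if close != ")":
                raise SelectionError("expected ')'", cat)
            return mask
        if tok == "backbone":
            return np.array([a.name in BACKBONE_NAMES for a in atoms])
        if tok == "water":
            return np.array([a.res_name.upper() in WATER_RES_NAMES for a in atoms])
        if tok == "chain":
            value, vat = self.advance()
            if value is None or value in _KEYWORDS:
                raise SelectionError("'chain' needs a chain id", vat)
            return np.array([a.chain_id == value for a in atoms])
        if tok == "resid":
            value, vat = self.advance()
            if value is None or value in _KEYWORDS:
                raise SelectionError("'resid' needs an integer or range", vat)
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value)
            if m is None:
                raise SelectionError(f"bad resid {value!r}", vat)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise SelectionError(f"empty resid range {value!r}", vat)
            return np.array([lo <= a.res_id <= hi for a in atoms])
        if tok in ("resname", "name"):
            names = []
            while self.peek()[0] is not None and self.peek()[0] not in _KEYWORDS:
                names.append(self.advance()[0])
            if not names:
                raise SelectionError(f"'{tok}' needs at least one name", at)
            names_set = set(names)
            if tok == "resname":
                return np.array([a.res_name in names_set for a in atoms])
            return np.array([a.name in names_set for a in atoms])
        raise SelectionError(f"unknown token {tok!r}", at)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Supported terms: ``chain <id>``, ``resid <a>[-<b>]`` (inclusive),
    ``resname <names...>``, ``name <names...>``, ``backbone`` (N/CA/C/O),
    ``water``; combined with ``and``/``or``/``not`` and parentheses.
    """
    mask = _Parser(topology, expression).parse()
    return AtomSelection(np.nonzero(mask)[0])
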