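"""Coordinate I/O, atom selection and inter-structure atom pairing.

Structures are held in a flat, explicit container (:class:`Structure` holding
an ordered list of :class:`Atom`) rather than a deep hierarchy: every
downstream operation works on labelled coordinate arrays, and a flat list
keeps selection and pairing semantics unambiguous.  Parsing of PDB/mmCIF and
space-group lookups are delegated to :mod:`gemmi`; writing emits plain PDB
text so that synthetic fixtures round-trip byte-identically.

Conventions (applied at read time):

* only the first model of multi-model files is kept;
* hydrogens (and deuterium) are dropped — all distance criteria downstream
  are defined on heavy atoms;
* alternate locations other than blank or 'A' are dropped, so selections are
  single-conformer and deterministic.

Residue numbering is taken verbatim from the source file, 1-based, and all
residue ranges are inclusive on both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    InsufficientPairsError,
    MissingChainError,
    StructureFormatError,
    SymmetryUnavailableError,
)

__all__ = [
    "Atom",
    "Structure",
    "DomainDefinition",
    "LabeledCoordinates",
    "PairedCoordinates",
    "read_structure",
    "write_structure",
    "structure_to_pdb_string",
    "select_atoms",
    "select",
    "pair_atoms",
    "apply_transform",
    "detect_protein_chain",
    "space_group_operators",
]

#: residue names recognised as ligands of interest by convention
LIGAND_RESIDUES = {"ANP", "ADP", "PO4", "BEF", "MG", "SO4"}

_WATER_RESIDUES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    """One heavy atom with its full crystallographic identity."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coord: np.ndarray
    icode: str = ""
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom coordinate must be a finite 3-vector, got {self.coord!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def label(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.atom_name)

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


# a symmetry operator: 3x3 fractional rotation matrix + fractional translation
SymOp = tuple[np.ndarray, np.ndarray]


@dataclass
class Structure:
    """An ordered collection of atoms plus optional crystal metadata."""

    id: str
    atoms: list[Atom]
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    symmetry_ops: list[SymOp] | None = None

    def __post_init__(self) -> None:
        if self.cell is not None:
            if len(self.cell) != 6 or any(v <= 0 for v in self.cell):
                raise ValueError(f"all six cell parameters must be positive, got {self.cell}")

    def coords(self) -> np.ndarray:
        """All atomic coordinates as an (n, 3) array, in atom order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coord for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coord = row.copy()

    def copy(self, new_id: str | None = None) -> "Structure":
        return Structure(
            id=new_id if new_id is not None else self.id,
            atoms=[a.copy() for a in self.atoms],
            cell=self.cell,
            space_group=self.space_group,
            symmetry_ops=None if self.symmetry_ops is None
            else [(r.copy(), t.copy()) for r, t in self.symmetry_ops],
        )

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def unit_cell(self) -> gemmi.UnitCell:
        if self.cell is None:
            raise SymmetryUnavailableError(f"structure {self.id!r} has no unit cell")
        return gemmi.UnitCell(*self.cell)


@dataclass(frozen=True)
class DomainDefinition:
    """A named rigid body: residue ranges on one chain, filtered by atom name.

    ``chain_id=None`` means "the unique protein chain", resolved per
    structure with :func:`detect_protein_chain`.  The default atom filter is
    C-alpha only, which is what domain superpositions use.
    """

    name: str
    residue_ranges: tuple[tuple[int, int], ...]
    chain_id: str | None = None
    atom_names: frozenset[str] = frozenset({"CA"})

    def __post_init__(self) -> None:
        if not self.residue_ranges:
            raise ValueError("domain must contain at least one residue range")
        for start, end in self.residue_ranges:
            if start > end:
                raise ValueError(f"range start {start} exceeds end {end}")
        object.__setattr__(self, "residue_ranges", tuple(tuple(r) for r in self.residue_ranges))
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def contains_residue(self, res_seq: int) -> bool:
        return any(start <= res_seq <= end for start, end in self.residue_ranges)


#: the two rigid bodies of the GyrB43 fragment (ATP-binding domain and the
#: transducer domain that follows it), the defaults used throughout
ATPASE_DOMAIN = DomainDefinition("atpase", ((20, 220),))
TRANSDUCER_DOMAIN = DomainDefinition("transducer", ((221, 392),))


@dataclass
class LabeledCoordinates:
    """An ordered atom selection with stable labels."""

    labels: list[tuple[str, int, str, str]]
    coords: np.ndarray
    atoms: list[Atom]

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PairedCoordinates:
    """Equivalent atoms of two structures, matched by residue number and
    atom name, ready for least-squares superposition."""

    labels: list[tuple[str, int, str, str]]
    coords_a: np.ndarray
    coords_b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coords_a) != len(self.coords_b) or len(self.coords_a) != len(self.labels):
            raise ValueError("paired coordinate arrays must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("paired labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def swapped(self) -> "PairedCoordinates":
        return PairedCoordinates(list(self.labels), self.coords_b.copy(), self.coords_a.copy())


# ---------------------------------------------------------------------------
# reading


def _gemmi_format(fmt: str | None, path: Path) -> gemmi.CoorFormat:
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    try:
        return {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[fmt]
    except KeyError:
        raise StructureFormatError(f"unknown coordinate format {fmt!r}") from None


def space_group_operators(symbol: str) -> list[SymOp]:
    """Symmetry operators (fractional rotation + translation) for a
    Hermann-Mauguin symbol, via gemmi's space-group tables."""
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SymmetryUnavailableError(f"unknown space-group symbol {symbol!r}")
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    return ops


def read_structure(
    path: str | Path,
    format: str | None = None,
    *,
    require_symmetry: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is kept; hydrogens and non-'A' alternate locations
    are dropped.  Cell and space group are taken from the header when
    present and symmetry operators resolved from gemmi's space-group table.
    With ``require_symmetry=True`` an unresolvable space group raises
    :class:`SymmetryUnavailableError` instead of returning a structure
    without operators.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_gemmi_format(format, path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                altloc = atom.altloc if atom.altloc != "\0" else ""
                if altloc not in ("", "A"):
                    continue
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        altloc=altloc,
                        b_factor=atom.b_iso,
                        is_hetero=(res.het_flag == "H"),
                    )
                )

    cell = None
    if st.cell and st.cell.a > 0 and st.cell.volume > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    space_group = st.spacegroup_hm or None
    sym_ops = None
    if space_group:
        try:
            sym_ops = space_group_operators(space_group)
        except SymmetryUnavailableError:
            if require_symmetry:
                raise
    elif require_symmetry:
        raise SymmetryUnavailableError(f"{path} carries no space-group record")

    return Structure(
        id=path.stem,
        atoms=atoms,
        cell=cell,
        space_group=space_group,
        symmetry_ops=sym_ops,
    )


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-aligned into cols 13-14 means
    # single-letter elements with short names start at column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def structure_to_pdb_string(s: Structure) -> str:
    """Serialize to PDB text (CRYST1 + ATOM/HETATM + TER/END)."""
    lines: list[str] = []
    if s.cell is not None:
        sg = s.space_group or "P 1"
        a, b, c, al, be, ga = s.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    serial = 0
    prev_chain: str | None = None
    for atom in s.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain and not atom.is_hetero:
            pass  # TER records are cosmetic; omit for deterministic round trips
        prev_chain = atom.chain_id
        serial += 1
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = _format_atom_name(atom.atom_name, atom.element)
        x, y, z = atom.coord
        lines.append(
            f"{record}{serial % 100000:5d} {name}{atom.altloc or ' ':1s}"
            f"{atom.res_name:<3s} {atom.chain_id[:1]:1s}{atom.res_seq:4d}{atom.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure to disk.  Only PDB output is supported; it is the
    lossless interchange format for every fixture in this package."""
    if format != "pdb":
        raise StructureFormatError(f"unsupported output format {format!r}")
    Path(path).write_text(structure_to_pdb_string(s))


# ---------------------------------------------------------------------------
# selection and pairing


def detect_protein_chain(s: Structure) -> str:
    """The chain with the most polymer (non-HETATM) residues."""
    counts: dict[str, set[tuple[int, str]]] = {}
    for a in s.atoms:
        if not a.is_hetero:
            counts.setdefault(a.chain_id, set()).add((a.res_seq, a.icode))
    if not counts:
        raise MissingChainError(f"structure {s.id!r} contains no polymer atoms")
    return max(counts, key=lambda ch: len(counts[ch]))


def select_atoms(
    s: Structure,
    d: DomainDefinition,
    *,
    min_atoms: int = 0,
) -> LabeledCoordinates:
    """Resolve a domain definition against a structure.

    Atoms are ordered by (res_seq, icode) then atom name; the order is a
    pure function of the structure content, not of file order within a
    residue.  Raises :class:`EmptySelectionError` if fewer than ``min_atoms``
    atoms match.
    """
    chain = d.chain_id if d.chain_id is not None else detect_protein_chain(s)
    picked = [
        a
        for a in s.atoms
        if a.chain_id == chain
        and not a.is_hetero
        and d.contains_residue(a.res_seq)
        and (not d.atom_names or a.atom_name in d.atom_names)
    ]
    picked.sort(key=lambda a: (a.res_seq, a.icode, a.atom_name))
    if len(picked) < min_atoms:
        raise EmptySelectionError(
            f"domain {d.name!r} on {s.id!r} chain {chain!r} matched "
            f"{len(picked)} atoms, need >= {min_atoms}"
        )
    return LabeledCoordinates(
        labels=[a.label for a in picked],
        coords=np.array([a.coord for a in picked]) if picked else np.empty((0, 3)),
        atoms=picked,
    )


def select(
    s: Structure,
    *,
    chain: str | None = None,
    res_seq: int | Iterable[int] | None = None,
    res_name: str | Iterable[str] | None = None,
    atom_names: Iterable[str] | None = None,
    elements: Iterable[str] | None = None,
    hetero: bool | None = None,
    exclude_water: bool = False,
) -> list[Atom]:
    """General attribute-based atom selection (returns atoms in file order)."""
    res_seqs = {res_seq} if isinstance(res_seq, int) else (set(res_seq) if res_seq else None)
    res_names = {res_name} if isinstance(res_name, str) else (set(res_name) if res_name else None)
    names = set(atom_names) if atom_names else None
    elems = {e.upper() for e in elements} if elements else None
    out = []
    for a in s.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if res_seqs is not None and a.res_seq not in res_seqs:
            continue
        if res_names is not None and a.res_name not in res_names:
            continue
        if names is not None and a.atom_name not in names:
            continue
        if elems is not None and a.element not in elems:
            continue
        if hetero is not None and a.is_hetero != hetero:
            continue
        if exclude_water and a.res_name in _WATER_RESIDUES:
            continue
        out.append(a)
    return out


def pair_atoms(a: Structure, b: Structure, d: DomainDefinition) -> PairedCoordinates:
    """Pair equivalent atoms of two structures within a domain.

    Equivalence is by (res_seq, icode, atom_name) — all structures of one
    study share a numbering scheme, so no sequence alignment is attempted.
    Residues missing from either structure simply drop out of the
    intersection.
    """
    sel_a = select_atoms(a, d)
    sel_b = select_atoms(b, d)
    key = lambda atom: (atom.res_seq, atom.icode, atom.atom_name)  # noqa: E731
    map_a = {key(at): at for at in sel_a.atoms}
    map_b = {key(at): at for at in sel_b.atoms}
    common = sorted(map_a.keys() & map_b.keys())
    if len(common) < 3:
        raise InsufficientPairsError(
            f"only {len(common)} common atoms between {a.id!r} and {b.id!r} "
            f"for domain {d.name!r}; need >= 3"
        )
    atoms_a = [map_a[k] for k in common]
    atoms_b = [map_b[k] for k in common]
    return PairedCoordinates(
        labels=[at.label for at in atoms_a],
        coords_a=np.array([at.coord for at in atoms_a]),
        coords_b=np.array([at.coord for at in atoms_b]),
    )


def apply_transform(s: Structure, rotation: np.ndarray, translation: np.ndarray,
                    *, new_id: str | None = None) -> Structure:
    """Return a copy of ``s`` with every atom mapped to R.x + t."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    out = s.copy(new_id=new_id)
    if out.atoms:
        out.set_coords(out.coords() @ rotation.T + translation)
    return out
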