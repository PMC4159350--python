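"""Dimer construction, molecular dyad determination and inter-subunit
distance tables.

A two-fold (C2) homodimer can come from three places: two chains deposited
in one coordinate file, a crystallographic two-fold applied to a single
subunit in the asymmetric unit, or the synthetic generator.  Once built,
the molecular dyad is found by superimposing subunit A onto subunit B and
requiring the relating rotation to be (close to) 180 degrees; the screw
axis of that transform is the dyad.

Inter-subunit distance tables quantify opening/closing of the dimer between
two nucleotide states: for a panel of residues, the distance between the
two symmetry-equivalent C-alpha atoms is measured in each state and the
change reported relative to the reference state.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingChainError, NotADyadError, SymmetryUnavailableError
from .rotation_analysis import screw_decomposition
from .structure_io import (
    DomainDefinition,
    Structure,
    pair_atoms,
    select,
)
from .superpose import kabsch

__all__ = [
    "Dimer",
    "DyadResult",
    "build_dimer",
    "molecular_dyad",
    "intersubunit_distance_table",
    "DEFAULT_RESIDUE_PANEL",
]

#: transducer-domain residues whose inter-subunit separation tracks the
#: opening of the dimer: the QTK-loop pair that closes up and the chamber/
#: C-terminal residues that move apart
DEFAULT_RESIDUE_PANEL = ("Q335", "T336", "L282", "N294", "D377")

#: a dyad must be within this many degrees of a perfect two-fold
DYAD_MIN_KAPPA_DEG = 175.0


@dataclass
class Dimer:
    subunit_a: Structure
    subunit_b: Structure
    provenance: str  # {"crystallographic-op", "second-chain", "synthetic"}
    dyad: tuple[np.ndarray, np.ndarray] | None = None  # (axis_unit, axis_point)


@dataclass
class DyadResult:
    axis_unit: np.ndarray
    axis_point: np.ndarray
    residual_deg: float  # deviation of the relating rotation from 180


def _extract_chain(s: Structure, chain_id: str, new_chain: str, sid: str) -> Structure:
    atoms = [a.copy() for a in s.atoms if a.chain_id == chain_id]
    if not atoms:
        raise MissingChainError(f"structure {s.id!r} has no chain {chain_id!r}")
    for a in atoms:
        a.chain_id = new_chain
    return Structure(id=sid, atoms=atoms, cell=s.cell, space_group=s.space_group,
                     symmetry_ops=s.symmetry_ops)


def _is_twofold(rot_frac: np.ndarray) -> bool:
    return bool(np.allclose(rot_frac @ rot_frac, np.eye(3), atol=1e-9)
                and not np.allclose(rot_frac, np.eye(3), atol=1e-9))


def build_dimer(
    s: Structure,
    *,
    chains: tuple[str, str] | None = None,
    operator_index: int | None = None,
) -> Dimer:
    """Assemble a C2 dimer.

    ``chains=(A, B)`` takes two chains from one file (the deposited-dimer
    case).  ``operator_index=k`` applies the k-th space-group operator —
    which must be a two-fold — to the whole structure, choosing the lattice
    translation that brings the mate closest to the original (the
    crystallographic-dimer case).
    """
    if (chains is None) == (operator_index is None):
        raise ValueError("specify exactly one of chains= or operator_index=")

    if chains is not None:
        a = _extract_chain(s, chains[0], "A", f"{s.id}_A")
        b = _extract_chain(s, chains[1], "B", f"{s.id}_B")
        return Dimer(subunit_a=a, subunit_b=b, provenance="second-chain")

    if s.symmetry_ops is None or s.cell is None:
        raise SymmetryUnavailableError(
            f"structure {s.id!r} lacks cell/symmetry for crystallographic dimer"
        )
    rot_frac, tran_frac = s.symmetry_ops[operator_index]
    if not _is_twofold(rot_frac):
        raise NotADyadError(f"operator {operator_index} of {s.space_group!r} is not a 2-fold")

    cell = s.unit_cell()
    orth = np.array(cell.orth.mat.tolist())
    frac = np.linalg.inv(orth)
    xyz = s.coords()
    fr = xyz @ frac.T
    centroid_f = fr.mean(axis=0)
    base = centroid_f @ rot_frac.T + tran_frac
    # lattice translation bringing the mate's centroid closest to the source
    best = min(
        itertools.product((-1, 0, 1), repeat=3),
        key=lambda shift: np.linalg.norm((base + shift - centroid_f) @ orth.T),
    )
    mate_f = fr @ rot_frac.T + tran_frac + np.array(best, dtype=float)
    mate_xyz = mate_f @ orth.T

    a = _extract_chain(s, _single_chain(s), "A", f"{s.id}_A")
    b = s.copy(new_id=f"{s.id}_B")
    b.set_coords(mate_xyz)
    b = _extract_chain(b, _single_chain(b), "B", f"{s.id}_B")
    return Dimer(subunit_a=a, subunit_b=b, provenance="crystallographic-op")


def _single_chain(s: Structure) -> str:
    chains = s.chains()
    if len(chains) != 1:
        from .structure_io import detect_protein_chain

        return detect_protein_chain(s)
    return chains[0]


def molecular_dyad(d: Dimer, domain: DomainDefinition | None = None) -> DyadResult:
    """Locate the two-fold axis relating the two subunits.

    Subunit A is superimposed onto subunit B over all shared C-alpha atoms
    (or a given domain); the transform must be a rotation of at least
    175 degrees, and its screw axis — positioned at the point closest to
    the dimer centroid — is the molecular dyad.
    """
    if domain is None:
        domain = DomainDefinition("all-ca", ((-10000, 100000),))
    pairs = pair_atoms(d.subunit_a, d.subunit_b, domain)
    transform = kabsch(pairs).transform
    centroid = 0.5 * (pairs.coords_a.mean(axis=0) + pairs.coords_b.mean(axis=0))
    screw = screw_decomposition(transform, reference_point=centroid)
    if screw.kappa_deg < DYAD_MIN_KAPPA_DEG:
        raise NotADyadError(
            f"subunits are related by a {screw.kappa_deg:.1f} degree rotation; "
            f"not a two-fold (need >= {DYAD_MIN_KAPPA_DEG})"
        )
    result = DyadResult(
        axis_unit=screw.axis_unit,
        axis_point=screw.axis_point,
        residual_deg=180.0 - screw.kappa_deg,
    )
    d.dyad = (result.axis_unit, result.axis_point)
    return result


_RESIDUE_LABEL = re.compile(r"^([A-Za-z]?)(\d+)$")


def parse_residue_label(label: str | int) -> int:
    """'D377' or 377 -> 377 (the one-letter code is decorative)."""
    if isinstance(label, int):
        return label
    m = _RESIDUE_LABEL.match(str(label).strip())
    if not m:
        raise ValueError(f"cannot parse residue label {label!r}")
    return int(m.group(2))


def _subunit_atom(s: Structure, res_seq: int, atom_name: str) -> np.ndarray | None:
    hits = select(s, res_seq=res_seq, atom_names=[atom_name], hetero=False)
    if not hits:
        return None
    return hits[0].coord


def intersubunit_distance_table(
    ref_dimer: Dimer,
    alt_dimer: Dimer,
    residues: tuple[str, ...] | list[str] = DEFAULT_RESIDUE_PANEL,
    atom_name: str = "CA",
) -> pd.DataFrame:
    """Distance between symmetry-equivalent atoms of the two subunits, in a
    reference and an alternative state, with the change (alt - ref).

    Residues absent from either dimer yield rows with NaN distances and
    ``present=False`` rather than an error, since different states are
    routinely missing different disordered segments.
    """
    if not residues:
        raise ValueError("residue panel must not be empty")
    rows = []
    for label in residues:
        res_seq = parse_residue_label(label)
        dists = {}
        present = True
        for name, dim in (("d_ref", ref_dimer), ("d_alt", alt_dimer)):
            pa = _subunit_atom(dim.subunit_a, res_seq, atom_name)
            pb = _subunit_atom(dim.subunit_b, res_seq, atom_name)
            if pa is None or pb is None:
                present = False
                dists[name] = np.nan
            else:
                dists[name] = float(np.linalg.norm(pa - pb))
        rows.append(
            {
                "residue": str(label),
                "atom": atom_name,
                "d_ref": dists["d_ref"],
                "d_alt": dists["d_alt"],
                "delta": dists["d_alt"] - dists["d_ref"],
                "present": present,
            }
        )
    return pd.DataFrame(rows)
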