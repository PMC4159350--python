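"""Quantitative active-site geometry between nucleotide states.

All measurements are plain heavy-atom distances: the deposited models carry
no hydrogens, so hydrogen bonds are called on donor/acceptor heavy-atom
separation alone (default cutoff 3.5 A, no angle term), and metal
coordination on a tighter cutoff with a "weak" band above it.  Cross-state
measurements (how far a side chain moved, or how badly one state's side
chain would clash with the other state's ligand) first superimpose the two
structures on an anchor domain so the comparison is made in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AtomResolutionError, EmptySelectionError
from .structure_io import Atom, DomainDefinition, Structure, pair_atoms, select
from .superpose import kabsch

__all__ = [
    "AtomSpec",
    "ContactRecord",
    "resolve_atom",
    "atom_distance",
    "hydrogen_bonds",
    "mg_coordination",
    "displacement_after_anchor_fit",
    "virtual_clash",
]

HBOND_MAX_DEFAULT = 3.5  # A, heavy-atom donor-acceptor
# inner-sphere Mg-O/N bonds cluster near 2.1 A; contacts out to 3.4 A are
# reported as weak (distorted outer-sphere) coordination
MG_COORDINATION_CUTOFF = 2.6  # A
MG_WEAK_LIMIT = 3.4  # A

#: elements that can act as H-bond donors/acceptors or metal ligands
_POLAR_ELEMENTS = {"N", "O", "F"}


@dataclass(frozen=True)
class AtomSpec:
    """A recipe that must resolve to exactly one atom in a structure."""

    res_seq: int
    atom_name: str
    chain_id: str | None = None
    res_name: str | None = None

    def __str__(self) -> str:
        parts = []
        if self.chain_id:
            parts.append(f"{self.chain_id}/")
        if self.res_name:
            parts.append(f"{self.res_name} ")
        parts.append(f"{self.res_seq}:{self.atom_name}")
        return "".join(parts)


@dataclass
class ContactRecord:
    atom_1: Atom
    atom_2: Atom
    distance: float
    kind: str  # {"hbond", "salt-bridge", "coordination", "weak-coordination", "clash", "generic"}

    def to_dict(self) -> dict:
        def tag(a: Atom) -> str:
            return f"{a.chain_id}/{a.res_name}{a.res_seq}:{a.atom_name}"

        return {"atom_1": tag(self.atom_1), "atom_2": tag(self.atom_2),
                "distance_A": round(self.distance, 3), "kind": self.kind}


def resolve_atom(s: Structure, spec: AtomSpec) -> Atom:
    hits = select(
        s,
        chain=spec.chain_id,
        res_seq=spec.res_seq,
        res_name=spec.res_name,
        atom_names=[spec.atom_name],
    )
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise AtomResolutionError(f"{spec} matches no atom in {s.id!r}")
    cands = ", ".join(f"{a.chain_id}/{a.res_name}{a.res_seq}:{a.atom_name}" for a in hits)
    raise AtomResolutionError(f"{spec} is ambiguous in {s.id!r}: {cands}")


def atom_distance(s: Structure, a: AtomSpec, b: AtomSpec) -> float:
    """Euclidean distance between two uniquely-resolved atoms."""
    return float(np.linalg.norm(resolve_atom(s, a).coord - resolve_atom(s, b).coord))


def hydrogen_bonds(
    s: Structure,
    focus: Sequence[Atom],
    partner: Sequence[Atom],
    d_max: float = HBOND_MAX_DEFAULT,
) -> list[ContactRecord]:
    """All polar-atom (N/O/F) pairs across two selections within ``d_max``,
    excluding pairs within the same residue, sorted by distance."""
    if not focus or not partner:
        raise EmptySelectionError("hydrogen-bond selections must be non-empty")
    records = []
    seen = set()
    for fa in focus:
        if fa.element not in _POLAR_ELEMENTS:
            continue
        for pa in partner:
            if pa.element not in _POLAR_ELEMENTS:
                continue
            if fa.residue_key == pa.residue_key:
                continue
            pair_id = tuple(sorted((fa.label + (fa.chain_id,), pa.label + (pa.chain_id,))))
            if pair_id in seen:
                continue
            dist = float(np.linalg.norm(fa.coord - pa.coord))
            if dist <= d_max:
                seen.add(pair_id)
                records.append(ContactRecord(fa, pa, dist, "hbond"))
    records.sort(key=lambda r: r.distance)
    return records


def mg_coordination(
    s: Structure,
    cutoff: float = MG_COORDINATION_CUTOFF,
    weak_limit: float = MG_WEAK_LIMIT,
) -> list[ContactRecord]:
    """N/O partners of each magnesium ion.

    Contacts within ``cutoff`` are inner-sphere coordination; contacts in
    (cutoff, weak_limit] are flagged as weak (distorted) interactions.
    Returns an empty list when the structure has no magnesium.
    """
    mgs = select(s, elements=["MG"])
    records = []
    for mg in mgs:
        for a in s.atoms:
            if a.element not in ("N", "O"):
                continue
            dist = float(np.linalg.norm(a.coord - mg.coord))
            if dist <= cutoff:
                records.append(ContactRecord(mg, a, dist, "coordination"))
            elif dist <= weak_limit:
                records.append(ContactRecord(mg, a, dist, "weak-coordination"))
    records.sort(key=lambda r: r.distance)
    return records


def _fit_mob_into_ref_frame(ref: Structure, mob: Structure, anchor: DomainDefinition) -> Structure:
    pairs = pair_atoms(ref, mob, anchor)
    # kabsch maps ref coords onto mob coords; the inverse carries mob into ref's frame
    return kabsch(pairs).transform.inverse().apply_to_structure(mob)


def displacement_after_anchor_fit(
    ref: Structure,
    mob: Structure,
    anchor: DomainDefinition,
    probe: AtomSpec,
) -> float:
    """How far a named atom moves between states once the structures share
    the anchor-domain frame."""
    anchored = _fit_mob_into_ref_frame(ref, mob, anchor)
    return float(
        np.linalg.norm(resolve_atom(ref, probe).coord - resolve_atom(anchored, probe).coord)
    )


def virtual_clash(
    ref: Structure,
    mob: Structure,
    anchor: DomainDefinition,
    probe_sel: Sequence[Atom],
    target_sel: Sequence[Atom],
) -> tuple[float, tuple[Atom, Atom]]:
    """Transplant atoms from one state into the other and measure the
    closest approach.

    The probe atoms (taken from ``mob``) are mapped into ``ref``'s frame by
    the anchor-domain fit; the minimum distance to the target atoms of
    ``ref`` quantifies the steric conflict the reference state would suffer
    if the mobile state's conformation were retained.
    """
    if not probe_sel or not target_sel:
        raise EmptySelectionError("virtual-clash selections must be non-empty")
    pairs = pair_atoms(ref, mob, anchor)
    into_ref = kabsch(pairs).transform.inverse()
    probe_xyz = into_ref.apply(np.array([a.coord for a in probe_sel]))
    target_xyz = np.array([a.coord for a in target_sel])
    diff = probe_xyz[:, None, :] - target_xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
    return float(dist[i, j]), (probe_sel[i], target_sel[j])
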