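"""Deterministic synthetic structures with known ground truth.

The generator produces coordinate fixtures that have exactly the geometric
structure the analysis modules assume — two rigid domains related by a
known screw motion, C2 dimers with a known dyad, crystal cells with known
special positions, and a toy nucleotide site with exact hand-placed
distances — so that every pipeline stage can be verified by parameter
recovery, entirely offline.

The polypeptide fold is idealized: alpha-helical segments whose axis
re-aims smoothly every ~15 residues along a seeded random walk.  This
yields generic, non-collinear C-alpha clouds of realistic density (3.8 A
spacing, ~2.3 A helix radius) without attempting chemical realism; four
backbone atoms (N, CA, C, O) are laid down per residue from local frame
offsets.  Residue numbering mirrors the GyrB43 fragment: anchor domain
20-220 (201 residues), mobile domain 221-392 (172 residues).

Everything is a pure function of (spec, seed): the same spec written twice
gives byte-identical PDB files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dimer_geometry import Dimer
from .errors import SyntheticSpecError
from .rotation_analysis import (
    RotationDescriptor,
    axis_angle_to_matrix,
    polar_angles,
)
from .structure_io import Atom, Structure

__all__ = [
    "Motion",
    "DimerSpec",
    "SyntheticSpec",
    "DimerFixture",
    "make_two_domain_structure",
    "make_dimer_fixture",
    "make_toy_site",
    "make_octahedral_mg_site",
    "TOY_SITE_DISTANCES",
]

_HELIX_RISE = 1.5  # A per residue along the local axis
_HELIX_RADIUS = 2.3  # A
_HELIX_TURN = math.radians(100.0)  # per residue
_SEGMENT_LEN = 15  # residues between axis re-aims


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(axis, ref))
    v = np.cross(axis, u)
    return u, v


@dataclass(frozen=True)
class Motion:
    """A rigid screw motion of the mobile domain (the ground truth)."""

    kappa_deg: float = 12.0
    axis_unit: tuple[float, float, float] | None = None  # None: long axis of the fold
    axis_point: tuple[float, float, float] | None = None  # None: inter-domain centroid
    screw_translation: float = 0.0


@dataclass(frozen=True)
class DimerSpec:
    """C2-dimer construction parameters.

    The dyad runs along ``axis_unit`` through ``axis_point``; when a cell is
    present on the parent spec the default axis is the Cartesian b
    direction through fractional (0.25 + frac_offset_x, *, 0.25), i.e. on
    the crystallographic special position unless an offset is requested.
    ``open_deg`` rotates the subunit's mobile domain about an axis parallel
    to the dyad through its domain interface before the C2 copy is made, so
    both transducer arms swing symmetrically.
    """

    axis_unit: tuple[float, float, float] = (0.0, 1.0, 0.0)
    axis_point: tuple[float, float, float] | None = None
    frac_offset_x: float = 0.0
    open_deg: float = 0.0
    perturb_sigma: float = 0.0  # extra noise on subunit B only
    centroid_offset: float = 16.0  # A from dyad axis to subunit centroid


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_res_anchor: int = 201
    n_res_mobile: int = 172
    first_res: int = 20
    motion: Motion = Motion()
    noise_sigma: float = 0.0
    gaps: tuple[tuple[int, int], ...] = ()
    gaps_moved: tuple[tuple[int, int], ...] | None = None  # defaults to ``gaps``
    dimer: DimerSpec | None = None
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    @property
    def anchor_range(self) -> tuple[int, int]:
        return (self.first_res, self.first_res + self.n_res_anchor - 1)

    @property
    def mobile_range(self) -> tuple[int, int]:
        start = self.first_res + self.n_res_anchor
        return (start, start + self.n_res_mobile - 1)


# ---------------------------------------------------------------------------
# fold construction


def _ca_trace(n_res: int, rng: np.random.Generator) -> np.ndarray:
    axis = _unit(rng.normal(size=3))
    u, v = _perp_basis(axis)
    base = np.zeros(3)
    points = np.empty((n_res, 3))
    t_local = 0
    for i in range(n_res):
        if i > 0 and i % _SEGMENT_LEN == 0:
            # smoothly re-aim the helix axis and rebase for continuity
            axis = _unit(axis + 0.6 * rng.normal(size=3))
            u, v = _perp_basis(axis)
            base = points[i - 1] + _HELIX_RISE * axis - _HELIX_RADIUS * u
            t_local = 0
        ang = _HELIX_TURN * t_local
        points[i] = (
            base
            + _HELIX_RISE * t_local * axis
            + _HELIX_RADIUS * (math.cos(ang) * u + math.sin(ang) * v)
        )
        t_local += 1
    return points


def _backbone_atoms(ca: np.ndarray, first_res: int, chain_id: str) -> list[Atom]:
    n_res = len(ca)
    atoms: list[Atom] = []
    for i in range(n_res):
        if i + 1 < n_res:
            d = _unit(ca[i + 1] - ca[i])
        else:
            d = _unit(ca[i] - ca[i - 1])
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        n = _unit(np.cross(d, ref))
        res_seq = first_res + i
        positions = {
            "N": ca[i] - 1.2 * d + 0.8 * n,
            "CA": ca[i],
            "C": ca[i] + 1.2 * d + 0.8 * n,
            "O": ca[i] + 1.2 * d + 2.0 * n,
        }
        for name, pos in positions.items():
            atoms.append(
                Atom(
                    chain_id=chain_id,
                    res_seq=res_seq,
                    res_name="ALA",
                    atom_name=name,
                    element=name[0],
                    coord=pos,
                )
            )
    return atoms


def _build_monomer(spec: SyntheticSpec, rng: np.random.Generator, *, sid: str,
                   chain_id: str = "A") -> Structure:
    n_res = spec.n_res_anchor + spec.n_res_mobile
    ca = _ca_trace(n_res, rng)
    atoms = _backbone_atoms(ca, spec.first_res, chain_id)
    return Structure(
        id=sid,
        atoms=atoms,
        cell=spec.cell,
        space_group=spec.space_group,
    )


def _apply_gaps(s: Structure, gaps: tuple[tuple[int, int], ...]) -> None:
    if not gaps:
        return
    s.atoms = [
        a for a in s.atoms
        if not any(start <= a.res_seq <= end for start, end in gaps)
    ]


def _domain_ca_centroid(s: Structure, rng_range: tuple[int, int]) -> np.ndarray:
    pts = [a.coord for a in s.atoms
           if a.atom_name == "CA" and rng_range[0] <= a.res_seq <= rng_range[1]]
    return np.mean(pts, axis=0)


def _resolve_motion(spec: SyntheticSpec, ref: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Concrete (axis_unit, axis_point) for the spec's motion."""
    m = spec.motion
    if m.axis_unit is not None:
        axis = _unit(np.array(m.axis_unit, dtype=float))
    else:
        # long axis of the monomer: principal direction of the CA cloud
        ca = np.array([a.coord for a in ref.atoms if a.atom_name == "CA"])
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if axis @ np.ones(3) < 0:  # deterministic sign
            axis = -axis
    if m.axis_point is not None:
        point = np.array(m.axis_point, dtype=float)
    else:
        # through the domain interface: midpoint of the two domain centroids
        point = 0.5 * (
            _domain_ca_centroid(ref, spec.anchor_range)
            + _domain_ca_centroid(ref, spec.mobile_range)
        )
    return axis, point


def _rotate_about_axis(coords: np.ndarray, axis: np.ndarray, point: np.ndarray,
                       kappa_deg: float, pitch: float = 0.0) -> np.ndarray:
    r = axis_angle_to_matrix(axis, kappa_deg)
    return (coords - point) @ r.T + point + pitch * axis


def _count_domain_ca(s: Structure, rng_range: tuple[int, int]) -> int:
    return sum(1 for a in s.atoms
               if a.atom_name == "CA" and rng_range[0] <= a.res_seq <= rng_range[1])


def make_two_domain_structure(
    spec: SyntheticSpec,
) -> tuple[Structure, Structure, RotationDescriptor]:
    """A reference structure, a copy whose mobile domain underwent the
    spec's screw motion, and the exact ground-truth descriptor.

    Gaussian noise (``noise_sigma``) is added to *all* atoms of both copies
    independently, after the rigid motion; gaps are deleted from each copy
    (``gaps`` / ``gaps_moved``).
    """
    if not 0.0 <= spec.motion.kappa_deg <= 180.0:
        raise SyntheticSpecError("kappa must lie in [0, 180] degrees")
    rng = np.random.default_rng(spec.seed)
    ref = _build_monomer(spec, rng, sid=f"synth{spec.seed}_ref")
    axis, point = _resolve_motion(spec, ref)

    moved = ref.copy(new_id=f"synth{spec.seed}_moved")
    if spec.motion.kappa_deg != 0.0 or spec.motion.screw_translation != 0.0:
        mob_lo, mob_hi = spec.mobile_range
        idx = [i for i, a in enumerate(moved.atoms) if mob_lo <= a.res_seq <= mob_hi]
        xyz = moved.coords()
        xyz[idx] = _rotate_about_axis(
            xyz[idx], axis, point, spec.motion.kappa_deg, spec.motion.screw_translation
        )
        moved.set_coords(xyz)

    gaps_moved = spec.gaps_moved if spec.gaps_moved is not None else spec.gaps
    _apply_gaps(ref, spec.gaps)
    _apply_gaps(moved, gaps_moved)
    if spec.gaps or gaps_moved:
        for s in (ref, moved):
            if (_count_domain_ca(s, spec.anchor_range) < 3
                    or _count_domain_ca(s, spec.mobile_range) < 3):
                raise SyntheticSpecError("gaps leave fewer than 3 CA atoms in a domain")

    if spec.noise_sigma > 0:
        for s in (ref, moved):
            s.set_coords(s.coords() + rng.normal(0.0, spec.noise_sigma, (len(s.atoms), 3)))

    truth = RotationDescriptor(
        kappa_deg=spec.motion.kappa_deg,
        axis_unit=axis,
        axis_point=point,
        screw_translation=spec.motion.screw_translation,
        omega_phi=polar_angles(axis, spec.cell),
        degenerate=spec.motion.kappa_deg < 0.1,
        source_pair=(ref.id, moved.id, "anchor", "mobile"),
    )
    return ref, moved, truth


# ---------------------------------------------------------------------------
# dimers


@dataclass
class DimerFixture:
    dimer: Dimer
    structure: Structure  # both chains in one structure (with CRYST1 if cell set)
    dyad_axis_unit: np.ndarray
    dyad_axis_point: np.ndarray
    spec: SyntheticSpec


def make_dimer_fixture(spec: SyntheticSpec) -> DimerFixture:
    """An exact (or perturbed) C2 dimer with known dyad.

    Subunit A is a two-domain monomer placed ``centroid_offset`` A off the
    dyad axis; subunit B is its exact 180-degree image about the dyad
    (plus optional Gaussian perturbation).  With a cell, the dyad runs
    along Cartesian b through fractional x = 0.25 + frac_offset_x, z = 0.25
    unless an explicit axis point is given.
    """
    if spec.dimer is None:
        raise SyntheticSpecError("spec.dimer must be provided")
    ds = spec.dimer
    rng = np.random.default_rng(spec.seed)

    axis = _unit(np.array(ds.axis_unit, dtype=float))
    if ds.axis_point is not None:
        axis_point = np.array(ds.axis_point, dtype=float)
    elif spec.cell is not None:
        a_len, _, c_len = spec.cell[0], spec.cell[1], spec.cell[2]
        axis_point = np.array([(0.25 + ds.frac_offset_x) * a_len, 0.0, 0.25 * c_len])
    else:
        axis_point = np.zeros(3)

    mono = _build_monomer(spec, rng, sid=f"synth{spec.seed}_mono", chain_id="A")

    # place the subunit centroid centroid_offset A from the dyad axis
    u_perp, _ = _perp_basis(axis)
    centroid = mono.coords().mean(axis=0)
    target = axis_point + ds.centroid_offset * u_perp
    mono.set_coords(mono.coords() + (target - centroid))

    if ds.open_deg != 0.0:
        # swing the mobile domain away, about an axis parallel to the dyad
        # through the domain interface; the anchor domain stays put and the
        # C2 copy mirrors the swing on subunit B
        open_point = 0.5 * (
            _domain_ca_centroid(mono, spec.anchor_range)
            + _domain_ca_centroid(mono, spec.mobile_range)
        )
        mob_lo, mob_hi = spec.mobile_range
        idx = [i for i, at in enumerate(mono.atoms) if mob_lo <= at.res_seq <= mob_hi]
        xyz = mono.coords()
        xyz[idx] = _rotate_about_axis(xyz[idx], axis, open_point, ds.open_deg)
        mono.set_coords(xyz)

    sub_a = mono.copy(new_id=f"synth{spec.seed}_A")
    sub_b = mono.copy(new_id=f"synth{spec.seed}_B")
    r2 = axis_angle_to_matrix(axis, 180.0)
    sub_b.set_coords((sub_b.coords() - axis_point) @ r2.T + axis_point)
    for at in sub_b.atoms:
        at.chain_id = "B"

    _apply_gaps(sub_a, spec.gaps)
    _apply_gaps(sub_b, spec.gaps_moved if spec.gaps_moved is not None else spec.gaps)

    if spec.noise_sigma > 0:
        sub_a.set_coords(sub_a.coords()
                         + rng.normal(0.0, spec.noise_sigma, (len(sub_a.atoms), 3)))
        sub_b.set_coords(sub_b.coords()
                         + rng.normal(0.0, spec.noise_sigma, (len(sub_b.atoms), 3)))
    if ds.perturb_sigma > 0:
        sub_b.set_coords(sub_b.coords()
                         + rng.normal(0.0, ds.perturb_sigma, (len(sub_b.atoms), 3)))

    combined = Structure(
        id=f"synth{spec.seed}_dimer",
        atoms=[at.copy() for at in sub_a.atoms] + [at.copy() for at in sub_b.atoms],
        cell=spec.cell,
        space_group=spec.space_group,
    )
    dimer = Dimer(subunit_a=sub_a, subunit_b=sub_b, provenance="synthetic",
                  dyad=None)
    return DimerFixture(
        dimer=dimer,
        structure=combined,
        dyad_axis_unit=axis,
        dyad_axis_point=axis_point,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# toy nucleotide site

#: exact distances built into the default toy site (A)
TOY_SITE_DISTANCES = {
    "beta_P_to_Pi_P": 4.5,       # diphosphate beta-P to orthophosphate P
    "short_hbond_O3_O1B": 2.50,  # orthophosphate O3 to diphosphate O1B
    "mg_to_O4": 3.1,             # magnesium to orthophosphate O4 (weak)
    "his_ND1_to_O4": 2.8,        # imidazole donor nitrogen to O4
    "be_to_beta_P": 2.9,         # beryllium analog of the gamma-P (variant)
}

_C40, _S40 = math.cos(math.radians(40.0)), math.sin(math.radians(40.0))


def make_toy_site(*, with_bef3: bool = False, chain_id: str = "X") -> Structure:
    """A minimal nucleotide site with exactly placed distances.

    Contains a diphosphate (PA/PB with oxygens), an orthophosphate
    (P, O1-O4), a magnesium ion, and three donor nitrogens (an imidazole
    ND1 plus two amide-like N atoms).  All the distances in
    :data:`TOY_SITE_DISTANCES` hold by construction.  With ``with_bef3``,
    a beryllium trifluoride group replaces the orthophosphate, its Be atom
    2.9 A from the beta-phosphorus.
    """
    A = []  # (res_name, res_seq, atom_name, element, xyz, hetero)

    def add(res_name, res_seq, atom_name, element, xyz, hetero=True):
        A.append((res_name, res_seq, atom_name, element, np.array(xyz, float), hetero))

    # diphosphate (ADP-like): beta-phosphorus at the origin
    add("ADP", 501, "PA", "P", (-2.9, 0.0, 0.0))
    add("ADP", 501, "O1A", "O", (-3.6, 1.3, 0.0))
    add("ADP", 501, "O2A", "O", (-3.6, -1.3, 0.0))
    add("ADP", 501, "O3A", "O", (-1.45, 0.0, 0.0))  # bridging
    add("ADP", 501, "PB", "P", (0.0, 0.0, 0.0))
    # O1B solves |O1B - PB| = 1.5 and |O1B - O3| = 2.50 exactly
    _o1b_x = 5.0 / 6.0
    _o1b_y = math.sqrt(1.5**2 - _o1b_x**2)
    add("ADP", 501, "O1B", "O", (_o1b_x, _o1b_y, 0.0))
    add("ADP", 501, "O2B", "O", (-_o1b_x, -_o1b_y, 0.0))

    if with_bef3:
        add("BEF", 504, "BE", "BE", (0.0, 0.0, 2.9))
        add("BEF", 504, "F1", "F", (1.3, 0.0, 3.4))
        add("BEF", 504, "F2", "F", (-0.65, 1.126, 3.4))
        add("BEF", 504, "F3", "F", (-0.65, -1.126, 3.4))
    else:
        # orthophosphate: P at 4.5 A from the beta-phosphorus
        add("PO4", 502, "P", "P", (4.5, 0.0, 0.0))
        add("PO4", 502, "O1", "O", (4.5, 0.0, -1.5))
        add("PO4", 502, "O2", "O", (5.25, -1.299, 0.0))
        add("PO4", 502, "O3", "O", (3.0, 0.0, 0.0))   # 2.50 A from O1B
        add("PO4", 502, "O4", "O", (5.25, 1.299, 0.0))
        add("MG", 503, "MG", "MG", (5.25, 1.299, 3.1))  # 3.1 A above O4
        # donor nitrogens at stated distances from the phosphate oxygens
        add("HIS", 116, "ND1", "N",
            (5.25 + 2.8 * _C40, 1.299 + 2.8 * _S40, 0.0), False)  # 2.8 from O4
        add("ALA", 115, "N", "N", (8.15, -1.299, 0.0), False)  # 2.9 from O2
        add("GLY", 118, "N", "N", (3.0, 0.0, -3.0), False)  # 3.0 from O3

    atoms = [
        Atom(chain_id=chain_id, res_seq=seq, res_name=rn, atom_name=an,
             element=el, coord=xyz, is_hetero=het)
        for rn, seq, an, el, xyz, het in A
    ]
    return Structure(id="toy_site_bef3" if with_bef3 else "toy_site", atoms=atoms)


def make_octahedral_mg_site(distance: float = 2.1) -> Structure:
    """A magnesium ion with six water oxygens at exactly ``distance`` A."""
    atoms = [Atom(chain_id="X", res_seq=601, res_name="MG", atom_name="MG",
                  element="MG", coord=np.zeros(3), is_hetero=True)]
    for i, axis in enumerate(np.vstack([np.eye(3), -np.eye(3)])):
        atoms.append(
            Atom(chain_id="X", res_seq=602 + i, res_name="HOH", atom_name="O",
                 element="O", coord=distance * axis, is_hetero=True)
        )
    return Structure(id="mg_octahedral", atoms=atoms)
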