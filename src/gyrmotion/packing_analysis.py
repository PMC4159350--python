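"""Crystal-environment analysis: symmetry mates, solvent-accessible surface
area and buried crystal-contact interfaces, and the position of a local
(non-crystallographic) dyad in fractional coordinates.

SASA is computed with the Shrake-Rupley numeric scheme on a deterministic
spiral point set.  Interface area follows the common "half the total buried
surface" convention::

    buried(a, b) = (SASA(a) + SASA(b) - SASA(a u b)) / 2

so that a value quoted as "an interface of N A^2" matches what interface
servers report; the full (unhalved) delta-SASA is available via a switch.

The van-der-Waals radius table is a single element-keyed constant;
unlisted elements fall back to 1.80 A with a warning.  Interface areas are
convention-dependent at the ~10% level, which is why all area comparisons
in this package use generous tolerances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dimer_geometry import Dimer, molecular_dyad
from .errors import SymmetryUnavailableError
from .structure_io import Atom, Structure

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "SymmetryMate",
    "sphere_points",
    "sasa",
    "total_sasa",
    "buried_interface_area",
    "symmetry_mates",
    "locate_local_dyad_fractional",
    "FractionalDyad",
]

#: van-der-Waals radii in Angstrom (element symbol, upper case)
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "MG": 1.73,
    "BE": 1.53,
}
DEFAULT_RADIUS = 1.80

PROBE_RADIUS = 1.4  # A, water probe
N_SPHERE_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii(atoms: Sequence[Atom]) -> np.ndarray:
    out = np.empty(len(atoms))
    unknown = set()
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            unknown.add(a.element)
            r = DEFAULT_RADIUS
        out[i] = r
    if unknown:
        warnings.warn(
            f"no vdW radius for element(s) {sorted(unknown)}; using {DEFAULT_RADIUS} A",
            stacklevel=3,
        )
    return out


def sasa(
    atoms: Sequence[Atom] | Structure,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Shrake-Rupley).

    Each atom's extended sphere (vdW radius + probe) is sampled with
    ``n_points`` quasi-uniform points; a point is accessible when it lies
    outside every neighbour's extended sphere.  Area = accessible fraction
    times the extended-sphere area.
    """
    if isinstance(atoms, Structure):
        atoms = atoms.atoms
    if not atoms:
        return np.empty(0)
    xyz = np.array([a.coord for a in atoms])
    radii = _radii(atoms) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax) if j != i]
        pts = xyz[i] + radii[i] * unit
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_r = radii[neighbours]
            d2 = np.sum((pts[:, None, :] - nb_xyz[None, :, :]) ** 2, axis=2)
            accessible = np.all(d2 >= (nb_r**2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return areas


def total_sasa(atoms: Sequence[Atom] | Structure, **kw) -> float:
    return float(sasa(atoms, **kw).sum())


def buried_interface_area(
    a: Sequence[Atom],
    b: Sequence[Atom],
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    half: bool = True,
) -> float:
    """Surface area buried on forming the a/b contact.

    ``half=True`` (default) returns the per-side average — the usual
    "interface area"; ``half=False`` returns the full buried delta-SASA.
    """
    if not a or not b:
        raise ValueError("both selections must be non-empty")
    sa = total_sasa(a, probe=probe, n_points=n_points)
    sb = total_sasa(b, probe=probe, n_points=n_points)
    sab = total_sasa(list(a) + list(b), probe=probe, n_points=n_points)
    buried = sa + sb - sab
    return buried / 2.0 if half else buried


@dataclass
class SymmetryMate:
    operator_index: int
    lattice_translation: tuple[int, int, int]
    structure: Structure
    min_distance: float


def symmetry_mates(s: Structure, contact_cutoff: float = 5.0) -> list[SymmetryMate]:
    """All crystallographic copies with at least one atom within
    ``contact_cutoff`` of the source structure.

    The search covers every space-group operator combined with lattice
    translations of -1..+1 cell along each axis; the identity copy (the
    source itself) is excluded.
    """
    if s.symmetry_ops is None or s.cell is None:
        raise SymmetryUnavailableError(f"structure {s.id!r} lacks cell or symmetry operators")
    orth = np.array(s.unit_cell().orth.mat.tolist())
    frac_mat = np.linalg.inv(orth)
    xyz = s.coords()
    fr = xyz @ frac_mat.T
    tree = cKDTree(xyz)
    mates = []
    for k, (rot, tran) in enumerate(s.symmetry_ops):
        for shift in itertools.product((-1, 0, 1), repeat=3):
            if (
                np.allclose(rot, np.eye(3))
                and np.allclose(tran, 0)
                and shift == (0, 0, 0)
            ):
                continue
            mate_xyz = (fr @ rot.T + tran + np.array(shift, dtype=float)) @ orth.T
            dmin, _ = tree.query(mate_xyz, k=1)
            dmin = float(np.min(dmin))
            if dmin <= contact_cutoff:
                mate = s.copy(new_id=f"{s.id}_sym{k}_{shift[0]}{shift[1]}{shift[2]}")
                mate.set_coords(mate_xyz)
                mates.append(SymmetryMate(k, shift, mate, dmin))
    mates.sort(key=lambda m: m.min_distance)
    return mates


@dataclass
class FractionalDyad:
    x: float
    z: float
    axis_unit: np.ndarray
    axis_point_frac: np.ndarray
    offset_from_quarter: float  # x - 0.25, the symmetry-breaking shift


def locate_local_dyad_fractional(d: Dimer, cell: tuple[float, ...]) -> FractionalDyad:
    """Fractional (x, z) trace of the molecular dyad in the given cell.

    The dyad axis is expected to run (roughly) along b, so its trace in the
    a-c plane is a single fractional (x, z) point; x is reported against
    the special position at 1/4 where a crystallographic two-fold would
    lie.  Coordinates are folded into [0, 1).
    """
    import gemmi

    if d.dyad is not None:
        axis_unit, axis_point = d.dyad
    else:
        dyad = molecular_dyad(d)
        axis_unit, axis_point = dyad.axis_unit, dyad.axis_point
    orth = np.array(gemmi.UnitCell(*cell).orth.mat.tolist())
    frac = np.linalg.inv(orth)
    point_f = frac @ axis_point
    x = float(point_f[0] % 1.0)
    z = float(point_f[2] % 1.0)
    return FractionalDyad(
        x=x,
        z=z,
        axis_unit=np.asarray(axis_unit, dtype=float),
        axis_point_frac=point_f,
        offset_from_quarter=x - 0.25,
    )
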