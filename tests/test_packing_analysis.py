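"""SASA, buried interface areas, symmetry mates and local-dyad location.

Analytic sphere/cap geometry and biotite's independent Shrake-Rupley
implementation serve as oracles for the surface-area code."""

import math

import numpy as np
import pytest

from gyrmotion.dimer_geometry import molecular_dyad
from gyrmotion.errors import SymmetryUnavailableError
from gyrmotion.packing_analysis import (
    VDW_RADII,
    buried_interface_area,
    locate_local_dyad_fractional,
    sasa,
    sphere_points,
    symmetry_mates,
    total_sasa,
)
from gyrmotion.structure_io import Atom, Structure, space_group_operators
from gyrmotion.synthetic_data import DimerSpec, SyntheticSpec, make_dimer_fixture

from conftest import single_atom_structure


def _carbon(coord, res_seq=1):
    return Atom("A", res_seq, "UNK", "C", "C", np.array(coord, float), is_hetero=True)


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        areas = sasa(single_atom_structure("C"))
        analytic = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert areas[0] == pytest.approx(analytic, rel=1e-6)  # quadrature is exact here

    def test_distant_atoms_additive(self):
        s = Structure("two", [_carbon((0, 0, 0), 1), _carbon((100, 0, 0), 2)])
        single = total_sasa(single_atom_structure("C"))
        assert total_sasa(s) == pytest.approx(2 * single, rel=1e-9)

    def test_fully_buried_atom_has_zero_area(self):
        # enclose a carbon in a dense shell of carbons at 3 A radius
        shell = [_carbon(3.0 * p, i + 2) for i, p in enumerate(sphere_points(200))]
        s = Structure("shell", [_carbon((0, 0, 0), 1)] + shell)
        assert sasa(s)[0] == 0.0

    def test_two_sphere_occlusion_matches_cap_area(self):
        """Two equal spheres at separation d each lose a cap of area
        2*pi*R*(R - d/2) of their extended surface."""
        d = 4.0
        s = Structure("pair", [_carbon((0, 0, 0), 1), _carbon((d, 0, 0), 2)])
        areas = sasa(s, n_points=4000)
        r_ext = VDW_RADII["C"] + 1.4
        cap = 2 * math.pi * r_ext * (r_ext - d / 2)
        full = 4 * math.pi * r_ext**2
        assert areas[0] == pytest.approx(full - cap, rel=0.01)
        assert areas[1] == pytest.approx(full - cap, rel=0.01)

    def test_agrees_with_biotite_reference(self):
        """Independent cross-check against biotite's Shrake-Rupley on a
        random cluster, with matched radii and point counts."""
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        coords = rng.normal(size=(30, 3)) * 4.0
        atoms = [_carbon(c, i + 1) for i, c in enumerate(coords)]
        mine = sasa(Structure("cluster", atoms), n_points=1000)

        arr = struc.AtomArray(len(atoms))
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * len(atoms))
        arr.res_id = np.arange(1, len(atoms) + 1)
        arr.atom_name = np.array(["C"] * len(atoms))
        arr.res_name = np.array(["UNK"] * len(atoms))
        arr.chain_id = np.array(["A"] * len(atoms))
        ref = struc.sasa(
            arr, probe_radius=1.4, point_number=1000,
            vdw_radii=np.full(len(atoms), VDW_RADII["C"]),
        )
        assert np.abs(mine - ref).max() / mine.max() < 0.02

    def test_unknown_element_warns_and_defaults(self):
        s = Structure(
            "odd", [Atom("A", 1, "UNK", "XX", "XX", np.zeros(3), is_hetero=True)]
        )
        with pytest.warns(UserWarning, match="vdW radius"):
            areas = sasa(s)
        assert areas[0] == pytest.approx(4 * math.pi * (1.8 + 1.4) ** 2, rel=1e-6)


class TestBuriedInterface:
    def test_non_contacting_pair_zero(self):
        a = [_carbon((0, 0, 0), 1)]
        b = [_carbon((50, 0, 0), 2)]
        assert buried_interface_area(a, b) == pytest.approx(0.0, abs=1.0)

    def test_symmetric_in_selection_order(self):
        rng = np.random.default_rng(6)
        a = [_carbon(c, i + 1) for i, c in enumerate(rng.normal(size=(15, 3)) * 3)]
        b = [_carbon(c + np.array([5.0, 0, 0]), i + 20)
             for i, c in enumerate(rng.normal(size=(15, 3)) * 3)]
        assert buried_interface_area(a, b) == pytest.approx(
            buried_interface_area(b, a), abs=1e-9
        )

    def test_two_sphere_contact_matches_analytic_cap(self):
        d = 4.0
        a = [_carbon((0, 0, 0), 1)]
        b = [_carbon((d, 0, 0), 2)]
        r_ext = VDW_RADII["C"] + 1.4
        cap = 2 * math.pi * r_ext * (r_ext - d / 2)  # per-sphere buried cap
        assert buried_interface_area(a, b, n_points=4000) == pytest.approx(cap, rel=0.05)
        assert buried_interface_area(a, b, n_points=4000, half=False) == pytest.approx(
            2 * cap, rel=0.05
        )

    def test_total_sasa_decreases_monotonically_on_approach(self):
        rng = np.random.default_rng(7)
        blob = rng.normal(size=(10, 3)) * 2.5
        totals = []
        for gap in (12.0, 6.0, 4.0):
            atoms = [_carbon(c, i + 1) for i, c in enumerate(blob)]
            atoms += [
                _carbon(c + np.array([gap, 0, 0]), i + 30) for i, c in enumerate(blob)
            ]
            totals.append(total_sasa(Structure("approach", atoms)))
        assert totals[0] > totals[1] > totals[2]


class TestSymmetryMates:
    def test_lone_atom_in_huge_p1_cell_has_no_neighbours(self):
        s = Structure(
            "lone",
            [_carbon((10, 10, 10))],
            cell=(500.0, 500.0, 500.0, 90.0, 90.0, 90.0),
            space_group="P 1",
            symmetry_ops=space_group_operators("P 1"),
        )
        assert symmetry_mates(s) == []

    def test_missing_symmetry_raises(self):
        with pytest.raises(SymmetryUnavailableError):
            symmetry_mates(single_atom_structure())

    def test_dimer_mate_found_with_correct_operator(self):
        """A subunit straddling the b dyad of a C222(1) cell must see its
        dimer partner among the contact mates, generated by the operator
        -x, y, -z+1/2."""
        cell = (80.0, 130.0, 90.0, 90.0, 90.0, 90.0)
        spec = SyntheticSpec(
            seed=21, cell=cell, space_group="C 2 2 2 1",
            dimer=DimerSpec(axis_point=(0.0, 0.0, 0.25 * cell[2])),
        )
        fx = make_dimer_fixture(spec)
        mono = fx.dimer.subunit_a.copy()
        mono.cell = cell
        mono.space_group = "C 2 2 2 1"
        mono.symmetry_ops = space_group_operators("C 2 2 2 1")
        mates = symmetry_mates(mono, contact_cutoff=5.0)
        assert mates, "expected at least the dimer mate in contact"
        k_dyad = next(
            i for i, (rot, tran) in enumerate(mono.symmetry_ops)
            if np.allclose(rot, np.diag([-1.0, 1.0, -1.0]))
            and np.allclose(tran, [0.0, 0.0, 0.5])
        )
        found = [
            m for m in mates
            if m.operator_index == k_dyad and m.lattice_translation == (0, 0, 0)
        ]
        assert found, "the dimer partner mate must be detected"
        # oracle: the closest approach of the generator's exact partner
        partner = fx.dimer.subunit_b.coords()
        source = mono.coords()
        dmin_oracle = min(
            np.linalg.norm(source - p, axis=1).min() for p in partner
        )
        assert found[0].min_distance == pytest.approx(dmin_oracle, abs=1e-6)

    def test_mate_operator_inverse_recovers_source(self):
        cell = (40.0, 50.0, 60.0, 90.0, 90.0, 90.0)
        s = Structure(
            "p21",
            [_carbon((1.0, 2.0, 29.0), 1), _carbon((3.0, 4.0, 31.0), 2)],
            cell=cell,
            space_group="P 21 21 2",
            symmetry_ops=space_group_operators("P 21 21 2"),
        )
        for mate in symmetry_mates(s, contact_cutoff=10.0):
            rot, tran = s.symmetry_ops[mate.operator_index]
            orth = np.array(s.unit_cell().orth.mat.tolist())
            frac = np.linalg.inv(orth)
            mate_f = mate.structure.coords() @ frac.T
            back = (mate_f - tran - np.array(mate.lattice_translation)) @ np.linalg.inv(rot).T
            assert np.abs(back @ orth.T - s.coords()).max() < 1e-6


class TestLocalDyad:
    def test_dimer_on_special_position_reports_quarter(self):
        spec = SyntheticSpec(
            seed=11, cell=(80.0, 130.0, 90.0, 90.0, 90.0, 90.0),
            space_group="P 21 21 2", dimer=DimerSpec(frac_offset_x=0.0),
        )
        fx = make_dimer_fixture(spec)
        fd = locate_local_dyad_fractional(fx.dimer, spec.cell)
        assert fd.x == pytest.approx(0.25, abs=1e-6)
        assert fd.offset_from_quarter == pytest.approx(0.0, abs=1e-6)

    def test_offset_dimer_reports_broken_symmetry(self, cell_dimer_offset):
        fx = cell_dimer_offset
        fd = locate_local_dyad_fractional(fx.dimer, fx.spec.cell)
        assert fd.x == pytest.approx(0.29, abs=1e-6)
        assert fd.offset_from_quarter == pytest.approx(0.04, abs=1e-6)

    def test_axis_direction_along_b(self, cell_dimer_offset):
        fx = cell_dimer_offset
        dyad = molecular_dyad(fx.dimer)
        assert abs(dyad.axis_unit @ np.array([0.0, 1.0, 0.0])) == pytest.approx(
            1.0, abs=1e-9
        )
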