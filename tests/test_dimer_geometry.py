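"""Dimer construction, dyad determination and inter-subunit distances."""

import numpy as np
import pytest

from gyrmotion.dimer_geometry import (
    Dimer,
    build_dimer,
    intersubunit_distance_table,
    molecular_dyad,
    parse_residue_label,
)
from gyrmotion.errors import MissingChainError, NotADyadError
from gyrmotion.rotation_analysis import angle_between_axes, axis_angle_to_matrix
from gyrmotion.structure_io import select
from gyrmotion.synthetic_data import (
    DimerSpec,
    Motion,
    SyntheticSpec,
    make_dimer_fixture,
    make_two_domain_structure,
)


def test_chain_mode_subunits_superpose_exactly(exact_dimer):
    dimer = build_dimer(exact_dimer.structure, chains=("A", "B"))
    assert dimer.provenance == "second-chain"
    # the C2 image has identical internal geometry: centroid distances match
    ca_a = np.array([a.coord for a in dimer.subunit_a.atoms if a.atom_name == "CA"])
    ca_b = np.array([a.coord for a in dimer.subunit_b.atoms if a.atom_name == "CA"])
    da = np.linalg.norm(ca_a - ca_a.mean(axis=0), axis=1)
    db = np.linalg.norm(ca_b - ca_b.mean(axis=0), axis=1)
    assert np.allclose(da, db, atol=1e-9)


def test_chain_mode_missing_chain_raises(exact_dimer):
    with pytest.raises(MissingChainError):
        build_dimer(exact_dimer.dimer.subunit_a, chains=("A", "B"))


def test_crystallographic_mode_reproduces_generator_partner():
    """A monomer placed beside the b dyad of a C222(1) cell (the axis of the
    operator -x, y, -z+1/2 runs along b through x = 0, z = 1/4): applying
    that crystallographic 2-fold reproduces the generator's exact C2
    partner coordinates."""
    cell = (80.0, 130.0, 90.0, 90.0, 90.0, 90.0)
    spec = SyntheticSpec(
        seed=21, cell=cell, space_group="C 2 2 2 1",
        dimer=DimerSpec(axis_point=(0.0, 0.0, 0.25 * cell[2])),
    )
    fx = make_dimer_fixture(spec)
    mono = fx.dimer.subunit_a.copy()
    mono.cell = cell
    from gyrmotion.structure_io import space_group_operators

    mono.space_group = "C 2 2 2 1"
    mono.symmetry_ops = space_group_operators("C 2 2 2 1")
    k = next(
        i for i, (rot, tran) in enumerate(mono.symmetry_ops)
        if np.allclose(rot, np.diag([-1.0, 1.0, -1.0]))
        and np.allclose(tran, [0.0, 0.0, 0.5])
    )
    dimer = build_dimer(mono, operator_index=k)
    assert dimer.provenance == "crystallographic-op"
    assert np.allclose(
        dimer.subunit_b.coords(), fx.dimer.subunit_b.coords(), atol=1e-9
    )


def test_non_twofold_operator_rejected():
    spec = SyntheticSpec(seed=22, cell=(80.0, 130.0, 90.0, 90.0, 90.0, 90.0),
                         space_group="C 2 2 2 1", dimer=DimerSpec())
    fx = make_dimer_fixture(spec)
    s = fx.dimer.subunit_a.copy()
    s.cell = spec.cell
    from gyrmotion.structure_io import space_group_operators

    s.symmetry_ops = space_group_operators("C 2 2 2 1")
    # forge a 4-fold-like operator (not its own inverse in fractional space)
    s.symmetry_ops[1] = (
        np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        np.zeros(3),
    )
    with pytest.raises(NotADyadError):
        build_dimer(s, operator_index=1)


def test_exact_dimer_dyad_is_180_with_generator_axis(exact_dimer):
    dyad = molecular_dyad(exact_dimer.dimer)
    assert dyad.residual_deg == pytest.approx(0.0, abs=1e-9)
    assert angle_between_axes(dyad.axis_unit, exact_dimer.dyad_axis_unit) < 1e-6
    # recovered axis point lies on the generator's dyad line
    d = dyad.axis_point - exact_dimer.dyad_axis_point
    perp = d - (d @ exact_dimer.dyad_axis_unit) * exact_dimer.dyad_axis_unit
    assert np.linalg.norm(perp) < 1e-6


def test_noisy_dimer_dyad_recovered_within_half_degree():
    errors = []
    for seed in range(50):
        spec = SyntheticSpec(seed=seed, noise_sigma=0.2, dimer=DimerSpec())
        fx = make_dimer_fixture(spec)
        dyad = molecular_dyad(fx.dimer)
        errors.append(angle_between_axes(dyad.axis_unit, fx.dyad_axis_unit))
    assert np.median(errors) < 0.5


def test_monomer_pair_is_not_a_dyad(two_domain_clean):
    ref, moved, _ = two_domain_clean
    fake = Dimer(subunit_a=ref, subunit_b=moved, provenance="synthetic")
    with pytest.raises(NotADyadError):
        molecular_dyad(fake)


def test_residue_label_parsing():
    assert parse_residue_label("D377") == 377
    assert parse_residue_label("335") == 335
    assert parse_residue_label(336) == 336
    with pytest.raises(ValueError):
        parse_residue_label("not-a-residue")


def test_distance_table_self_comparison_is_zero(exact_dimer):
    table = intersubunit_distance_table(
        exact_dimer.dimer, exact_dimer.dimer, ["250", "300", "377"]
    )
    assert np.allclose(table["delta"], 0.0)
    assert table["present"].all()


def test_distance_table_symmetric_under_subunit_exchange(exact_dimer):
    swapped = Dimer(
        subunit_a=exact_dimer.dimer.subunit_b,
        subunit_b=exact_dimer.dimer.subunit_a,
        provenance="synthetic",
    )
    panel = ["230", "290", "350", "392"]
    t1 = intersubunit_distance_table(exact_dimer.dimer, exact_dimer.dimer, panel)
    t2 = intersubunit_distance_table(swapped, swapped, panel)
    assert np.allclose(t1["d_ref"], t2["d_ref"], atol=1e-9)


def test_missing_residues_reported_absent_not_error(exact_dimer):
    spec = SyntheticSpec(seed=7, dimer=DimerSpec(), gaps=((300, 310),))
    gapped = make_dimer_fixture(spec)
    table = intersubunit_distance_table(exact_dimer.dimer, gapped.dimer, ["305", "350"])
    row305 = table[table["residue"] == "305"].iloc[0]
    assert not row305["present"] and np.isnan(row305["d_alt"])
    assert table[table["residue"] == "350"].iloc[0]["present"]


def test_empty_residue_panel_rejected(exact_dimer):
    with pytest.raises(ValueError):
        intersubunit_distance_table(exact_dimer.dimer, exact_dimer.dimer, [])


def test_opened_dimer_deltas_match_chord_oracle():
    """Swinging each subunit's mobile domain 6 degrees about the dyad-parallel
    interface axis changes inter-subunit distances by exactly the amount
    computed from the explicit rotation of the closed coordinates."""
    closed_spec = SyntheticSpec(seed=33, dimer=DimerSpec(open_deg=0.0))
    open_spec = SyntheticSpec(seed=33, dimer=DimerSpec(open_deg=6.0))
    closed = make_dimer_fixture(closed_spec)
    opened = make_dimer_fixture(open_spec)
    panel = ["260", "300", "377", "392"]
    table = intersubunit_distance_table(closed.dimer, opened.dimer, panel)

    # oracle: rotate the closed subunit-A mobile CA directly, mirror through
    # the dyad for subunit B, and take the distance atom-wise
    axis = closed.dyad_axis_unit
    axis_pt = closed.dyad_axis_point
    sub_a = closed.dimer.subunit_a
    mob_lo, mob_hi = closed_spec.mobile_range
    interface = None
    ca_anchor = [a.coord for a in sub_a.atoms
                 if a.atom_name == "CA" and a.res_seq <= closed_spec.anchor_range[1]]
    ca_mobile = [a.coord for a in sub_a.atoms
                 if a.atom_name == "CA" and mob_lo <= a.res_seq <= mob_hi]
    interface = 0.5 * (np.mean(ca_anchor, axis=0) + np.mean(ca_mobile, axis=0))
    r_open = axis_angle_to_matrix(axis, 6.0)
    r_dyad = axis_angle_to_matrix(axis, 180.0)
    for _, row in table.iterrows():
        res = int(row["residue"])
        ca = next(a.coord for a in sub_a.atoms
                  if a.atom_name == "CA" and a.res_seq == res)
        opened_a = (ca - interface) @ r_open.T + interface
        opened_b = (opened_a - axis_pt) @ r_dyad.T + axis_pt
        expected = np.linalg.norm(opened_a - opened_b)
        assert row["d_alt"] == pytest.approx(expected, abs=1e-6)


def test_opening_signature_distal_residues_separate():
    """A 6-degree outward swing of both transducer arms moves their distal
    ends apart while the dimer core stays put (positive deltas grow with
    distance from the interface along the mobile domain)."""
    closed = make_dimer_fixture(SyntheticSpec(seed=2, dimer=DimerSpec(open_deg=0.0)))
    opened = make_dimer_fixture(SyntheticSpec(seed=2, dimer=DimerSpec(open_deg=6.0)))
    table = intersubunit_distance_table(
        closed.dimer, opened.dimer, ["225", "392"]
    )
    near = table[table["residue"] == "225"].iloc[0]["delta"]
    far = table[table["residue"] == "392"].iloc[0]["delta"]
    assert abs(far) > abs(near)
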