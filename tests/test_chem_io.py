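"""chem_io: CIF/XYZ round trips, hydrogen handling, features, filters."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from xtalkit import elements
from xtalkit.chem_io import (
    CrystalEntry,
    MoleculeRecord,
    apply_filters,
    crystal_density,
    featurize,
    molecular_volume,
    packing_coefficient,
    read_crystal_cif,
    read_xyz,
    strip_hydrogens,
    write_crystal_cif,
    write_xyz,
)
from xtalkit.fixtures import FixtureSpec, benzene_like, make_crystal, make_molecule, urea_like
from xtalkit.spacegroups import get_space_group

from conftest import rigid_rotation


# ----------------------------------------------------------------------
# CIF round trips
# ----------------------------------------------------------------------

def _coord_set(entry):
    return np.sort(entry.unit_cell_coords.reshape(-1, 3), axis=0)


def test_cif_round_trip_identity(crystal_p21c, tmp_path):
    _, entry = crystal_p21c
    path = tmp_path / "rt.cif"
    write_crystal_cif(entry, path)
    back = read_crystal_cif(path)
    assert back.Z == entry.Z
    for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
        assert abs(getattr(back, attr) - getattr(entry, attr)) < 1e-6
    np.testing.assert_allclose(_coord_set(back), _coord_set(entry), atol=1e-6)


def test_cif_p1_cubic(tmp_path):
    text = """data_cube
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P1'
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.10 0.10 0.10
N1 N 0.25 0.10 0.10
O1 O 0.10 0.25 0.10
"""
    path = tmp_path / "cube.cif"
    path.write_text(text)
    entry = read_crystal_cif(path)
    assert entry.Z == 1
    assert entry.a == entry.b == entry.c == 10.0
    assert entry.alpha == entry.beta == entry.gamma == 90.0
    np.testing.assert_allclose(
        entry.unit_cell_coords[0][0], [1.0, 1.0, 1.0], atol=1e-9
    )


def test_cif_pminus1_expands_inversion_image(tmp_path):
    # hand-applied (-x,-y,-z): fractional site (0.1,0.2,0.3) -> (0.9,0.8,0.7)
    text = """data_inv
_cell_length_a 8.0
_cell_length_b 8.0
_cell_length_c 8.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P-1'
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
'-x,-y,-z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.10 0.20 0.30
C2 C 0.10 0.20 0.48
C3 C 0.28 0.20 0.30
"""
    path = tmp_path / "inv.cif"
    path.write_text(text)
    entry = read_crystal_cif(path)
    assert entry.Z == 2
    frac_img = entry.unit_cell_coords[1] @ np.linalg.inv(entry.cell_matrix())
    # image of the whole molecule, wrapped so its centroid is in [0,1)
    expected = 1.0 - np.array([[0.10, 0.20, 0.30], [0.10, 0.20, 0.48], [0.28, 0.20, 0.30]])
    np.testing.assert_allclose(frac_img, expected, atol=1e-9)


def test_cif_full_and_asymmetric_serializations_agree(crystal_p21c, tmp_path):
    _, entry = crystal_p21c
    assert entry.Z == 4
    pa, pf = tmp_path / "a.cif", tmp_path / "f.cif"
    write_crystal_cif(entry, pa, mode="asymmetric")
    write_crystal_cif(entry, pf, mode="full")
    ea, ef = read_crystal_cif(pa), read_crystal_cif(pf)
    assert ea.Z == ef.Z == 4
    np.testing.assert_allclose(_coord_set(ea), _coord_set(ef), atol=1e-6)


def test_cif_missing_sites_is_incomplete(tmp_path):
    path = tmp_path / "empty.cif"
    path.write_text("data_x\n_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n"
                    "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n")
    with pytest.raises(ValueError, match="missing atom sites"):
        read_crystal_cif(path)


def test_cif_parse_garbage_fails(tmp_path):
    path = tmp_path / "bad.cif"
    path.write_text("data_x\n_cell_length_a\n")  # dangling tag
    with pytest.raises(ValueError):
        read_crystal_cif(path)


def test_degenerate_cell_rejected_before_write(crystal_p1):
    _, entry = crystal_p1
    with pytest.raises(ValueError):
        CrystalEntry(
            identifier="degenerate",
            molecule=entry.molecule,
            a=entry.a, b=entry.b, c=entry.c,
            alpha=179.99, beta=179.99, gamma=179.99,  # essentially flat
            space_group=entry.space_group,
            Z=entry.Z,
            unit_cell_coords=entry.unit_cell_coords,
        )


def test_xyz_round_trip(small_molecule, tmp_path):
    path = tmp_path / "m.xyz"
    write_xyz(small_molecule, path)
    back = read_xyz(path)
    np.testing.assert_array_equal(back.atomic_numbers, small_molecule.atomic_numbers)
    np.testing.assert_allclose(back.coords, small_molecule.coords, atol=1e-9)


# ----------------------------------------------------------------------
# hydrogens
# ----------------------------------------------------------------------

def test_strip_hydrogens_methane_like():
    t = 1.09 / np.sqrt(3)
    mol = MoleculeRecord(
        "ch4",
        [6, 1, 1, 1, 1],
        [[0, 0, 0], [t, t, t], [-t, -t, t], [-t, t, -t], [t, -t, -t]],
    )
    out = strip_hydrogens(mol)
    assert out.n_atoms == 1
    assert out.atomic_numbers[0] == 6


def test_strip_hydrogens_identity_on_hydrogen_free(small_molecule):
    out = strip_hydrogens(small_molecule)
    np.testing.assert_array_equal(out.atomic_numbers, small_molecule.atomic_numbers)
    np.testing.assert_allclose(out.coords, small_molecule.coords)


def test_strip_hydrogens_all_hydrogen_rejected():
    mol = MoleculeRecord("h2", [1, 1], [[0, 0, 0], [0, 0, 0.74]])
    with pytest.raises(ValueError, match="all-hydrogen"):
        strip_hydrogens(mol)


def test_benzene_like_annotations_preserved():
    # 6 heavy atoms survive; annotated counts carried through featurization
    stripped = strip_hydrogens(benzene_like())
    assert stripped.n_atoms == 6
    annotated = replace(
        stripped,
        acceptor_flags=np.array([1.0, 1.0, 0, 0, 0, 0]),
        n_acceptors=2,
    )
    feat = featurize(annotated)
    assert feat.n_donors == 0
    assert feat.mol_features[10] == 2  # acceptor count slot


def test_urea_like_donors_detected():
    stripped = strip_hydrogens(urea_like())
    assert stripped.n_atoms == 4
    assert stripped.n_donors == 2  # both NH2 nitrogens
    assert stripped.n_acceptors == 3  # O + 2 N


# ----------------------------------------------------------------------
# featurization
# ----------------------------------------------------------------------

def test_featurize_single_carbon():
    mol = featurize(MoleculeRecord("c", [6], [[0.0, 0.0, 0.0]]))
    assert mol.atom_features.shape == (1, 8)
    assert mol.atom_features[0, 0] == 6.0
    assert mol.mol_features.shape == (16,)
    assert mol.mol_features[0] == 1.0


def test_featurize_rotation_translation_invariant(small_molecule):
    R = rigid_rotation(7)
    moved = replace(
        small_molecule,
        coords=small_molecule.coords @ R.T + np.array([3.0, -2.0, 11.0]),
        atom_features=None, mol_features=None, mol_volume=None,
    )
    a = featurize(replace(small_molecule, atom_features=None,
                          mol_features=None, mol_volume=None))
    b = featurize(moved)
    np.testing.assert_allclose(a.mol_features, b.mol_features, rtol=1e-6, atol=1e-7)


def test_featurize_permutation_invariant(small_molecule):
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_molecule.n_atoms)
    permuted = MoleculeRecord(
        "perm",
        small_molecule.atomic_numbers[perm],
        small_molecule.coords[perm],
    )
    a = featurize(replace(small_molecule, atom_features=None,
                          mol_features=None, mol_volume=None))
    b = featurize(permuted)
    np.testing.assert_allclose(a.mol_features, b.mol_features, rtol=1e-6, atol=1e-7)
    np.testing.assert_allclose(
        np.sort(a.atom_features, axis=0), np.sort(b.atom_features, axis=0)
    )


def test_featurize_atom_count_slot(spec):
    mol = make_molecule(FixtureSpec(seed=9, n_atoms_range=(10, 10)), 0)
    assert mol.n_atoms == 10
    assert mol.mol_features[0] == 10.0


def test_featurize_rejects_hydrogens():
    with pytest.raises(ValueError, match="strip hydrogens"):
        featurize(benzene_like())


# ----------------------------------------------------------------------
# packing coefficient
# ----------------------------------------------------------------------

def _toy_entry(v_mol, v_cell, Z=1):
    n = Z
    mol = MoleculeRecord("toy", [6], [[0.0, 0.0, 0.0]], mol_volume=v_mol)
    group = get_space_group("P1") if Z == 1 else get_space_group("P-1")
    a = v_cell ** (1 / 3)
    return CrystalEntry(
        identifier="toy", molecule=mol, a=a, b=a, c=a,
        alpha=90, beta=90, gamma=90, space_group=group, Z=Z,
        unit_cell_coords=np.zeros((Z, 1, 3)) + np.arange(Z)[:, None, None],
    )


def test_packing_coefficient_unity():
    assert packing_coefficient(_toy_entry(100.0, 100.0)) == pytest.approx(1.0)


def test_packing_coefficient_half():
    assert packing_coefficient(_toy_entry(100.0, 400.0, Z=2)) == pytest.approx(0.5)


def test_packing_coefficient_scaling_law(crystal_pminus1):
    _, entry = crystal_pminus1
    base = packing_coefficient(entry)
    doubled = CrystalEntry(
        identifier="x2", molecule=entry.molecule,
        a=2 * entry.a, b=2 * entry.b, c=2 * entry.c,
        alpha=entry.alpha, beta=entry.beta, gamma=entry.gamma,
        space_group=entry.space_group, Z=entry.Z,
        unit_cell_coords=entry.unit_cell_coords,
    )
    assert packing_coefficient(doubled) == pytest.approx(base / 8.0)


def test_density_is_mass_weighted_transform(crystal_pminus1):
    _, entry = crystal_pminus1
    cp = packing_coefficient(entry)
    rho = crystal_density(entry)
    mass = sum(elements.mass(int(z)) for z in entry.molecule.atomic_numbers)
    expected = cp * mass / (molecular_volume(entry.molecule) * 0.602214076)
    assert rho == pytest.approx(expected, rel=1e-6)


def test_molecular_volume_rigid_motion_invariant(small_molecule):
    R = rigid_rotation(11)
    moved = replace(small_molecule, coords=small_molecule.coords @ R.T + 4.0)
    v1 = molecular_volume(small_molecule)
    v2 = molecular_volume(moved)
    assert v2 == pytest.approx(v1, rel=1e-5)


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------

def test_filter_max_atoms(spec):
    big = featurize(
        MoleculeRecord(
            "big",
            [6] * 101,
            np.arange(303, dtype=float).reshape(101, 3) * 1.6,
            mol_volume=500.0,
        )
    )
    group = get_space_group("P1")
    entry = CrystalEntry(
        identifier="big", molecule=big, a=50, b=50, c=50,
        alpha=90, beta=90, gamma=90, space_group=group, Z=1,
        unit_cell_coords=big.coords[None],
    )
    report = apply_filters([entry], stage="runtime")
    assert not report.flags["big"]["max_atoms"]
    assert not report.passed("big")


def test_filter_all_pass(spec):
    for i in range(20):
        _, entry = make_crystal(spec, i)
        report = apply_filters([entry], stage="runtime")
        flags = report.flags[entry.identifier]
        assert flags["z_prime_one"] and flags["max_atoms"]
        assert flags["z_wyckoff"] and flags["z_range"]
        assert flags["packing_coefficient_range"], entry.identifier
        assert report.passed(entry.identifier)


def test_filter_overlapping_atoms(crystal_p1):
    _, entry = crystal_p1
    coords = entry.unit_cell_coords.copy()
    coords[0, 1] = coords[0, 0]  # exact duplicate position
    dup = CrystalEntry(
        identifier="dup", molecule=replace(entry.molecule, coords=coords[0]),
        a=entry.a, b=entry.b, c=entry.c,
        alpha=entry.alpha, beta=entry.beta, gamma=entry.gamma,
        space_group=entry.space_group, Z=entry.Z, unit_cell_coords=coords,
    )
    report = apply_filters([dup], stage="runtime")
    assert not report.flags["dup"]["overlapping_atoms"]


def test_filter_packing_range_boundaries(crystal_p1):
    _, entry = crystal_p1
    cp = packing_coefficient(entry)
    # rescale cell so c_pack lands below/above the window
    for target, ok in ((0.50, False), (0.70, True), (0.90, False)):
        s = (cp / target) ** (1 / 3)
        scaled = CrystalEntry(
            identifier=f"cp{target}", molecule=entry.molecule,
            a=s * entry.a, b=s * entry.b, c=s * entry.c,
            alpha=entry.alpha, beta=entry.beta, gamma=entry.gamma,
            space_group=entry.space_group, Z=entry.Z,
            unit_cell_coords=entry.unit_cell_coords,
        )
        report = apply_filters([scaled], stage="runtime")
        assert report.flags[f"cp{target}"]["packing_coefficient_range"] is ok


def test_filters_never_raise_and_mark_empty():
    report = apply_filters([None], stage="processing")
    ident = next(iter(report.flags))
    assert not report.passed(ident)


def test_filter_order_independence(spec):
    entries = [make_crystal(spec, i)[1] for i in range(5)]
    report = apply_filters(entries, stage="runtime")
    survivors = set(report.survivors)
    # survivors = entries passing every filter; any application order of the
    # per-filter predicates yields the same conjunction
    for perm in itertools.permutations(report.filters, 3):
        alt = {
            ident
            for ident, row in report.flags.items()
            if all(row[f] for f in perm) and all(row[f] for f in report.filters)
        }
        assert alt == survivors


def test_report_to_text(spec):
    entries = [make_crystal(spec, i)[1] for i in range(2)]
    text = apply_filters(entries, stage="runtime").to_text()
    assert text.splitlines()[0].startswith("identifier\t")
    assert len(text.splitlines()) == 3


def test_sdf_reader_v2000(tmp_path):
    from xtalkit.chem_io import read_sdf

    sdf = (
        "urea\n  generated\n\n"
        "  4  3  0  0  0  0  0  0  0  0999 V2000\n"
        "    0.0000    0.0000    0.0000 C   0  0\n"
        "    0.0000    1.2300    0.0000 O   0  0\n"
        "    1.1600   -0.6600    0.0000 N   0  0\n"
        "   -1.1600   -0.6600    0.0000 N   0  0\n"
        "  1  2  2  0\n  1  3  1  0\n  1  4  1  0\nM  END\n$$$$\n"
    )
    path = tmp_path / "m.sdf"
    path.write_text(sdf)
    mol = read_sdf(path)
    assert mol.identifier == "urea"
    np.testing.assert_array_equal(mol.atomic_numbers, [6, 8, 7, 7])
    assert mol.coords[1, 1] == 1.23
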