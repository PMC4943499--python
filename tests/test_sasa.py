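import numpy as np
import pytest

from ppisite import sasa, synthetic
from ppisite.structure import Atom, ChainStructure, ComplexStructure, ResidueRecord

from conftest import FAST_N_POINTS


def _carbon(coord, name="C"):
    return Atom(name, "C", np.asarray(coord, dtype=float), 1.70)


def test_isolated_atom_analytic():
    area = sasa.shrake_rupley([_carbon([0, 0, 0])], probe_radius=1.4, n_points=960)
    expected = 4 * np.pi * (1.70 + 1.40) ** 2
    assert area[0] == pytest.approx(expected, rel=1e-9)  # no occlusion at all


def test_two_distant_atoms_full_sphere():
    atoms = [_carbon([0, 0, 0]), _carbon([100, 0, 0])]
    areas = sasa.shrake_rupley(atoms)
    expected = 4 * np.pi * 3.1**2
    np.testing.assert_allclose(areas, expected, rtol=1e-9)


def test_caged_atom_nearly_buried(rng):
    # Center atom surrounded by a dense closed cage of atoms at 3 A.
    cage_dirs = sasa._sphere_points(200)
    atoms = [_carbon([0, 0, 0])] + [_carbon(3.0 * d) for d in cage_dirs]
    area = sasa.shrake_rupley(atoms, n_points=960)[0]
    assert area < 1.0
    # Independent oracle: Monte-Carlo points on the expanded sphere checked
    # against every cage sphere by brute force.
    pts = rng.normal(size=(20000, 3))
    pts *= 3.1 / np.linalg.norm(pts, axis=1, keepdims=True)
    free = np.ones(len(pts), dtype=bool)
    for d in cage_dirs:
        free &= np.linalg.norm(pts - 3.0 * d, axis=1) > 3.1
    mc_area = free.mean() * 4 * np.pi * 3.1**2
    assert mc_area < 1.0


def test_quadrature_convergence(rng):
    atoms = [_carbon(c) for c in rng.normal(scale=2.0, size=(5, 3))]
    coarse = sasa.shrake_rupley(atoms, n_points=960)
    fine = sasa.shrake_rupley(atoms, n_points=4000)
    np.testing.assert_allclose(coarse, fine, rtol=0.03)


def test_identical_coordinates_not_an_error():
    # Coincident spheres are computed normally, not rejected; every test
    # point sits exactly on the twin's surface, so the result is finite and
    # bounded, with the sign of the boundary decided by rounding.
    atoms = [_carbon([0, 0, 0]), _carbon([0, 0, 0])]
    areas = sasa.shrake_rupley(atoms)
    full = 4 * np.pi * 3.1**2
    assert np.all(areas >= 0.0) and np.all(areas <= full)


def _residue(chain_id, idx, aa, atoms):
    return ResidueRecord(chain_id, idx, idx + 1, aa, atoms)


def test_component_conservation(rng):
    atoms = []
    for i, c in enumerate(rng.normal(scale=3.0, size=(8, 3))):
        name = ["N", "CA", "C", "O", "CB", "CG", "OD1", "SD"][i]
        element = name[0] if name[0] in "NOCS" else "C"
        atoms.append(Atom(name, element, c, sasa.VDW_RADII.get(element, 1.7)))
    chain = ChainStructure("A", [_residue("A", 0, "A", atoms[:4]),
                                 _residue("A", 1, "A", atoms[4:])])
    table = sasa.residue_asa(ComplexStructure("t", [chain]), "bound",
                             n_points=FAST_N_POINTS)
    np.testing.assert_allclose(
        table.backbone_asa + table.sidechain_asa, table.total_asa, rtol=1e-6
    )
    np.testing.assert_allclose(
        table.polar_asa + table.nonpolar_asa, table.total_asa, rtol=1e-6
    )


def test_single_chain_bound_equals_unbound(toy_complex):
    structure, _ = toy_complex
    mono = ComplexStructure("m", [structure.chains[0]])
    bound = sasa.residue_asa(mono, "bound", n_points=FAST_N_POINTS)
    unbound = sasa.residue_asa(mono, "unbound", n_points=FAST_N_POINTS)
    np.testing.assert_allclose(bound.total_asa, unbound.total_asa)


def test_casa_le_masa(toy_complex):
    structure, _ = toy_complex
    casa = sasa.residue_asa(structure, "bound", n_points=FAST_N_POINTS)
    masa = sasa.residue_asa(structure, "unbound", n_points=FAST_N_POINTS)
    assert casa.keys() == masa.keys()
    assert np.all(casa.total_asa <= masa.total_asa + 1e-9)


def test_glycine_sidechain_zero(toy_complex):
    structure, _ = toy_complex
    table = sasa.residue_asa(structure, "bound", n_points=FAST_N_POINTS)
    gly = [i for i, aa in enumerate(table.aas) if aa == "G"]
    assert gly, "fixture should contain at least one glycine"
    assert np.all(table.sidechain_asa[gly] == 0.0)


def test_translation_invariance_exact(rng):
    atoms = [_carbon(c) for c in rng.normal(scale=3.0, size=(6, 3))]
    base = sasa.shrake_rupley(atoms, n_points=FAST_N_POINTS)
    shift = rng.normal(scale=50.0, size=3)
    moved = [_carbon(a.coord + shift) for a in atoms]
    np.testing.assert_allclose(
        sasa.shrake_rupley(moved, n_points=FAST_N_POINTS), base, rtol=1e-6
    )


def test_rotation_invariance_within_quadrature_error(rng):
    # The spiral point set is fixed in the lab frame, so rotations change
    # areas only within the quadrature error, which shrinks with n_points.
    atoms = [_carbon(c) for c in rng.normal(scale=3.0, size=(6, 3))]
    base = sasa.shrake_rupley(atoms, n_points=2000)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = [_carbon(q @ a.coord) for a in atoms]
    np.testing.assert_allclose(
        sasa.shrake_rupley(moved, n_points=2000), base, rtol=0.02, atol=0.5
    )


def test_relative_asa_zero_is_zero():
    table = sasa.SasaTable(
        chain_ids=["A"], seq_indices=[0], author_numbers=[1], aas=["A"],
        context="unbound",
        total_asa=np.zeros(1), backbone_asa=np.zeros(1),
        sidechain_asa=np.zeros(1), polar_asa=np.zeros(1),
        nonpolar_asa=np.zeros(1),
    )
    sasa.relative_asa(table)
    for comp in sasa.ASA_COMPONENTS:
        assert getattr(table, f"{comp}_rasa")[0] == 0.0
    assert table.total_rasa[0] < 0.16  # buried by construction


def test_extended_ala_total_rasa_band():
    # Central residue of an isolated extended G-A-G construction should be
    # close to its reference maximum.
    ref = sasa._component_reference("A")
    assert 0.8 <= ref["total"] / sasa.MAX_ASA_TOTAL["A"] <= 1.2


def test_relative_asa_unknown_residue_flagged():
    table = sasa.SasaTable(
        chain_ids=["A"], seq_indices=[0], author_numbers=[1], aas=["X"],
        context="unbound",
        total_asa=np.array([100.0]), backbone_asa=np.array([60.0]),
        sidechain_asa=np.array([40.0]), polar_asa=np.array([30.0]),
        nonpolar_asa=np.array([70.0]),
    )
    sasa.relative_asa(table)
    mean_ref = np.mean(list(sasa.MAX_ASA_TOTAL.values()))
    assert table.total_rasa[0] == pytest.approx(100.0 / mean_ref)
    assert table.rasa_flagged[0]


def test_sasa_csv_writer(tmp_path, toy_complex):
    structure, _ = toy_complex
    table = sasa.relative_asa(
        sasa.residue_asa(structure, "unbound", n_points=FAST_N_POINTS)
    )
    out = tmp_path / "sasa.csv"
    table.write_csv(out)
    lines = out.read_text().splitlines()
    assert len(lines) == len(table) + 1
    assert lines[0].startswith("chain_id,author_number,aa,context,total_asa")


# --- DSSP bypass -----------------------------------------------------------

def _dssp_line(idx, num, chain, aa, acc):
    s = f"{idx:5d}{num:5d} {chain} {aa}"
    return s + " " * (34 - len(s)) + f"{acc:4d}" + "\n"


DSSP_HEADER = (
    "==== DSSP stub ====\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
)


def test_read_dssp_stub(tmp_path):
    path = tmp_path / "x.dssp"
    path.write_text(DSSP_HEADER + _dssp_line(1, 1, "A", "A", 100)
                    + _dssp_line(2, 2, "A", "G", 0))
    rows = sasa.read_dssp_asa(path)
    assert [r.acc for r in rows] == [100.0, 0.0]
    assert [r.chain_id for r in rows] == ["A", "A"]


def test_dssp_chain_break_skipped(tmp_path):
    path = tmp_path / "x.dssp"
    break_line = "    3        !              \n"
    path.write_text(DSSP_HEADER + _dssp_line(1, 1, "A", "A", 50)
                    + break_line + _dssp_line(4, 1, "B", "V", 75))
    rows = sasa.read_dssp_asa(path)
    assert len(rows) == 2
    assert rows[1].chain_id == "B" and rows[1].acc == 75.0


def test_dssp_non_numeric_acc(tmp_path):
    path = tmp_path / "x.dssp"
    bad = _dssp_line(1, 1, "A", "A", 50).replace("  50", " abc")
    path.write_text(DSSP_HEADER + bad)
    with pytest.raises(ValueError, match="non-numeric"):
        sasa.read_dssp_asa(path)


def test_dssp_alignment(tmp_path, toy_complex):
    structure, _ = toy_complex
    chain = structure.chains[0]
    path = tmp_path / "toy.dssp"
    body = "".join(
        _dssp_line(i + 1, res.author_number, "A", res.aa, i)
        for i, res in enumerate(chain.residues)
    )
    path.write_text(DSSP_HEADER + body)
    values = sasa.align_dssp(sasa.read_dssp_asa(path), chain)
    np.testing.assert_allclose(values, np.arange(chain.length))


def test_dssp_alignment_failure(tmp_path, toy_complex):
    structure, _ = toy_complex
    chain = structure.chains[0]
    path = tmp_path / "bad.dssp"
    path.write_text(DSSP_HEADER + _dssp_line(1, 999, "A", "A", 10))
    with pytest.raises(ValueError, match="unmatched"):
        sasa.align_dssp(sasa.read_dssp_asa(path), chain)
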