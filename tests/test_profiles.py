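import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppisite import profiles
from ppisite._aadata import AA_FACTORS, HQI8


def _uniform_row(**kwargs):
    defaults = dict(
        p=np.full(20, 0.05), entropy=math.log(20),
        relative_entropy=100.0, conservation_weight=1.0,
        sequence_variability=50.0, nocc=10,
    )
    defaults.update(kwargs)
    return profiles.ProfileRow(**defaults)


class TestProfileRow:
    def test_vector25_order(self):
        row = _uniform_row()
        v = row.vector25
        assert v.shape == (25,)
        np.testing.assert_allclose(v[:20], 0.05)
        assert v[24] == 10.0

    def test_negative_probability_rejected(self):
        p = np.full(20, 0.05)
        p[0] = -0.01
        with pytest.raises(ValueError, match="negative"):
            _uniform_row(p=p)

    def test_rounding_tolerance(self):
        p = np.full(20, 0.049)  # sums to 0.98, integer-percent rounding
        _uniform_row(p=p)  # accepted

    def test_sum_out_of_tolerance(self):
        with pytest.raises(ValueError, match="sum"):
            _uniform_row(p=np.full(20, 0.06))


class TestEntropy:
    def test_one_hot(self):
        p = np.zeros(20)
        p[3] = 1.0
        assert profiles.profile_entropy(p) == (0.0, 0.0)

    def test_uniform_is_maximal(self):
        entropy, relent = profiles.profile_entropy(np.full(20, 0.05))
        assert entropy == pytest.approx(math.log(20))
        assert relent == pytest.approx(100.0)

    def test_two_state(self):
        p = np.zeros(20)
        p[0] = p[1] = 0.5
        entropy, relent = profiles.profile_entropy(p)
        assert entropy == pytest.approx(math.log(2))
        assert relent == pytest.approx(100 * math.log(2) / math.log(20))

    @given(st.lists(st.floats(0.0, 1.0), min_size=20, max_size=20))
    def test_bounds(self, raw):
        p = np.array(raw)
        total = p.sum()
        if total == 0:
            return
        p = p / total
        entropy, relent = profiles.profile_entropy(p)
        assert -1e-12 <= entropy <= math.log(20) + 1e-12
        assert -1e-9 <= relent <= 100 + 1e-9


# --- HSSP parsing ----------------------------------------------------------

HSSP_AA_COLS = " ".join(f"{aa:>4}" for aa in profiles.AA_ORDER)


def _hssp_text(rows):
    lines = [
        "HSSP stub",
        "## SEQUENCE PROFILE AND ENTROPY",
        f" SeqNo PDBNo {HSSP_AA_COLS} NOCC NDEL NCON ENTROPY RELENT WEIGHT VAR",
    ]
    for i, (percents, nocc, entropy, relent, weight, var) in enumerate(rows, 1):
        cells = " ".join(f"{v:4d}" for v in percents)
        lines.append(
            f"{i:6d} {i:5d} {cells} {nocc:4d}    0    0 {entropy:7.3f} "
            f"{relent:6.1f} {weight:6.2f} {var:3.0f}"
        )
    return "\n".join(lines) + "\n"


def test_parse_hssp_one_hot(tmp_path):
    percents = [0] * 20
    percents[profiles.AA_ORDER.index("A")] = 100
    path = tmp_path / "x.hssp"
    path.write_text(_hssp_text([(percents, 12, 0.0, 0.0, 1.5, 10)]))
    rows = profiles.parse_hssp(path)
    assert len(rows) == 1
    assert rows[0].p[profiles.AA_ORDER.index("A")] == 1.0
    assert rows[0].p.sum() == 1.0
    assert rows[0].nocc == 12
    assert rows[0].conservation_weight == 1.5
    assert rows[0].sequence_variability == 10


def test_parse_hssp_uniform(tmp_path):
    path = tmp_path / "x.hssp"
    path.write_text(_hssp_text([([5] * 20, 40, 2.996, 100.0, 1.0, 80)]))
    rows = profiles.parse_hssp(path)
    np.testing.assert_allclose(rows[0].p, 0.05)


def test_parse_hssp_rounding_accepted(tmp_path):
    percents = [5] * 20
    percents[0] = 3  # sums to 98
    path = tmp_path / "x.hssp"
    path.write_text(_hssp_text([(percents, 10, 2.9, 97.0, 1.0, 70)]))
    assert profiles.parse_hssp(path)[0].p.sum() == pytest.approx(0.98)


def test_parse_hssp_missing_section(tmp_path):
    path = tmp_path / "x.hssp"
    path.write_text("HSSP stub\n## ALIGNMENTS\n")
    with pytest.raises(profiles.ProfileFormatError, match="SEQUENCE PROFILE"):
        profiles.parse_hssp(path)


# --- simplified TSV dialect ------------------------------------------------

def test_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    rows = []
    for _ in range(6):
        p = rng.dirichlet(np.ones(20))
        e, r = profiles.profile_entropy(p)
        rows.append(profiles.ProfileRow(
            p=p, entropy=e, relative_entropy=r, conservation_weight=1.2,
            sequence_variability=33.0, nocc=17, aa="K",
        ))
    path = tmp_path / "p.tsv"
    profiles.write_profile_tsv(path, rows)
    back = profiles.parse_profile_tsv(path)
    assert len(back) == len(rows)
    for a, b in zip(rows, back):
        np.testing.assert_allclose(a.p, b.p, atol=1e-5)
        assert b.nocc == 17 and b.aa == "K"


def test_tsv_negative_probability(tmp_path):
    rows = [_uniform_row()]
    path = tmp_path / "p.tsv"
    profiles.write_profile_tsv(path, rows, with_aa=False)
    text = path.read_text().replace("0.05", "-0.05", 1)
    path.write_text(text)
    with pytest.raises(profiles.ProfileFormatError, match="negative"):
        profiles.parse_profile_tsv(path)


def test_tsv_missing_nocc_defaults(tmp_path):
    path = tmp_path / "p.tsv"
    profiles.write_profile_tsv(path, [_uniform_row()], with_aa=False)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")[:-1]
    body = lines[1].split("\t")[:-1]
    path.write_text("\t".join(header) + "\n" + "\t".join(body) + "\n")
    rows = profiles.parse_profile_tsv(path)
    assert rows[0].nocc == 1 and rows[0].flagged


def test_tsv_wrong_columns(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("a\tb\tc\n1\t2\t3\n")
    with pytest.raises(profiles.ProfileFormatError, match="header"):
        profiles.parse_profile_tsv(path)


def test_tsv_wrong_field_count(tmp_path):
    path = tmp_path / "p.tsv"
    profiles.write_profile_tsv(path, [_uniform_row()], with_aa=False)
    path.write_text(path.read_text() + "0.05\t0.05\n")
    with pytest.raises(profiles.ProfileFormatError, match="fields"):
        profiles.parse_profile_tsv(path)


# --- physicochemical lookup ------------------------------------------------

def test_physchem_shape():
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        assert profiles.physchem_lookup(aa).shape == (13,)


def test_physchem_unknown_is_mean():
    fallback = profiles.physchem_lookup("X")
    expected = np.concatenate([
        np.mean([HQI8[a] for a in HQI8], axis=0),
        np.mean([AA_FACTORS[a] for a in AA_FACTORS], axis=0),
    ])
    np.testing.assert_allclose(fallback, expected)


def test_physchem_tables_injective():
    vectors = {aa: tuple(profiles.physchem_lookup(aa)) for aa in HQI8}
    assert len(set(vectors.values())) == 20


def test_tables_complete():
    assert set(HQI8) == set(AA_FACTORS) == set("ACDEFGHIKLMNPQRSTVWY")
    assert all(len(v) == 8 for v in HQI8.values())
    assert all(len(v) == 5 for v in AA_FACTORS.values())


# --- assembly --------------------------------------------------------------

def test_assemble_zeros():
    row = profiles.ProfileRow(
        p=np.zeros(20), entropy=0.0, relative_entropy=0.0,
        conservation_weight=0.0, sequence_variability=0.0, nocc=0,
    )
    vec = profiles.assemble_residue_vector(row, np.zeros(12), np.zeros(13))
    assert vec.shape == (50,)
    np.testing.assert_allclose(vec, 0.0)


def test_assemble_length_50():
    vec = profiles.assemble_residue_vector(
        _uniform_row(), np.arange(12, dtype=float), profiles.physchem_lookup("W")
    )
    assert vec.shape == (50,)
    assert len(profiles.FEATURE_NAMES) == 50


def test_assemble_missing_parts():
    with pytest.raises(ValueError, match="profile"):
        profiles.assemble_residue_vector(None, np.zeros(12), np.zeros(13))
    with pytest.raises(ValueError, match="structure"):
        profiles.assemble_residue_vector(_uniform_row(), np.zeros(5), np.zeros(13))
    with pytest.raises(ValueError, match="physicochemical"):
        profiles.assemble_residue_vector(_uniform_row(), np.zeros(12), np.zeros(4))


def test_assemble_alignment_permutes():
    rng = np.random.default_rng(7)
    rows = []
    for _ in range(4):
        p = rng.dirichlet(np.ones(20))
        e, r = profiles.profile_entropy(p)
        rows.append(profiles.ProfileRow(
            p=p, entropy=e, relative_entropy=r, conservation_weight=1.0,
            sequence_variability=10.0, nocc=5,
        ))
    struct = rng.normal(size=(4, 12))
    phys = [profiles.physchem_lookup(aa) for aa in "ACDE"]
    vectors = [
        profiles.assemble_residue_vector(rows[i], struct[i], phys[i])
        for i in range(4)
    ]
    perm = [2, 0, 3, 1]
    permuted = [
        profiles.assemble_residue_vector(rows[i], struct[i], phys[i])
        for i in perm
    ]
    for k, i in enumerate(perm):
        np.testing.assert_array_equal(permuted[k], vectors[i])
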