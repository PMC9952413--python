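import numpy as np
import pytest

from prosfold import structio
from prosfold.errors import EmptyStructureError, MappingError, RangeError
from prosfold.structio import Structure, write_pdb, read_structure, map_segment

from conftest import make_record, make_structure

FIVE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 20.00           C
ATOM      4  CA  GLY A   2       4.200   1.500   0.500  1.00 30.00           C
ATOM      5  CA  SER A   3       7.900   1.600   1.000  1.00 40.00           C
ATOM      6  CA  MSE A   4      11.600   1.700   1.500  1.00 50.00           C
ATOM      7  CA  LEU A   5      15.300   1.800   2.000  1.00 60.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 20.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00 20.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40 20.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60 20.00           C
ATOM      4  CA  GLY A   2       5.000   0.000   0.000  1.00 20.00           C
ATOM      5  CA AGLY A   3       8.000   0.000   0.000  0.50 20.00           C
ATOM      6  CA BGLY A   3       9.000   0.000   0.000  0.50 20.00           C
END
"""


def test_read_single_chain_pdb(tmp_path):
    """A small PDB with five residues parses into one chain of five, with
    the selenomethionine mapped to its parent amino acid."""
    path = tmp_path / "five.pdb"
    path.write_text(FIVE_RES_PDB)
    st = read_structure(path)
    assert len(st.chains) == 1
    chain = st.chains[0]
    assert len(chain.residues) == 5
    assert chain.sequence == "AGSML"
    assert chain.residues[0].ca.b_factor == pytest.approx(20.0)


def test_water_only_file_is_empty_structure(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_ONLY_PDB)
    with pytest.raises(EmptyStructureError):
        read_structure(path)


def test_unreadable_file_raises_parse_error(tmp_path):
    missing = tmp_path / "nope.pdb"
    with pytest.raises(Exception):
        read_structure(missing)


def test_altloc_resolved_to_highest_occupancy_ties_first(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    st = read_structure(path)
    chain = st.chains[0]
    # residue 1: B has higher occupancy
    assert chain.residues[0].ca.coord[0] == pytest.approx(2.0)
    # residue 3: tie -> first altloc (A)
    assert chain.residues[2].ca.coord[0] == pytest.approx(8.0)


def test_pdb_round_trip(helix_pair):
    """Writing to PDB text and re-reading preserves residue count,
    sequence, Calpha coordinates (format precision) and B-factors."""
    _, model, _ = helix_pair
    text = write_pdb(model)
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "m.pdb"
        p.write_text(text)
        back = read_structure(p)
    a, b = model.chains[0], back.chains[0]
    assert len(a.residues) == len(b.residues)
    assert a.sequence == b.sequence
    np.testing.assert_allclose(a.ca_coords(), b.ca_coords(), atol=1e-3)
    for ra, rb in zip(a.residues, b.residues):
        assert ra.ca.b_factor == pytest.approx(rb.ca.b_factor, abs=0.01)


def test_model_plddt_constant_and_mean():
    st = make_structure(np.random.default_rng(0).normal(size=(5, 3)),
                        b_factors=[70.0] * 5)
    assert structio.model_plddt(st, (1, 5)) == pytest.approx(70.0)
    st2 = make_structure([[0, 0, 0], [3.8, 0, 0]], b_factors=[60.0, 80.0])
    assert structio.model_plddt(st2, (1, 2)) == pytest.approx(70.0)


def test_model_plddt_region_outside_model():
    st = make_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    with pytest.raises(RangeError):
        structio.model_plddt(st, (2, 7))


def test_map_segment_identical_sequences(helix_pair):
    exp, model, record = helix_pair
    mapping = map_segment(record, exp, model)
    assert mapping.coverage == pytest.approx(1.0)
    assert len(mapping.pairs) == record.length
    m_idx = [p[0] for p in mapping.pairs]
    e_idx = [p[1] for p in mapping.pairs]
    assert m_idx == sorted(m_idx) and e_idx == sorted(e_idx)


def test_map_segment_missing_residues_coverage():
    """Experimental chain missing 3 of 20 region residues -> coverage 0.85."""
    rng = np.random.default_rng(1)
    coords = np.cumsum(rng.normal(scale=2.0, size=(20, 3)), axis=0) \
        + np.arange(20)[:, None] * [3.8, 0, 0]
    seq = "ACDEFGHIKLMNPQRSTVWY"
    model = make_structure(coords, seq=seq)
    keep = [i for i in range(20) if i not in (4, 9, 14)]
    exp = make_structure(coords[keep], seq="".join(seq[i] for i in keep))
    record = make_record(20)
    mapping = map_segment(record, exp, model)
    assert mapping.coverage == pytest.approx(0.85)
    assert len(mapping.pairs) == 17


def test_map_segment_wrong_chain_raises():
    rng = np.random.default_rng(2)
    seq_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
    seq_b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
    assert seq_a != seq_b
    coords = np.arange(90, dtype=float).reshape(30, 3)
    model = make_structure(coords, seq=seq_a)
    exp = make_structure(coords, seq=seq_b)
    with pytest.raises(MappingError):
        map_segment(make_record(30), exp, model)


def test_map_segment_swap_transposes_pairs(helix_pair):
    """Swapping which structure plays 'model' transposes the pair list."""
    exp, model, record = helix_pair
    exp_mono = Structure(chains=[exp.chains[0]], source_id="exp_mono")
    fwd = map_segment(record, exp_mono, model)
    rev = map_segment(record, model, exp_mono)
    assert [(b, a) for a, b in fwd.pairs] == rev.pairs


def test_segment_table_round_trip(tmp_path):
    records = [make_record(20), make_record(15, partners=("B", "C"),
                                            uniprot_ac="P00002", start=5)]
    path = tmp_path / "segments.tsv"
    structio.write_segment_table(records, path)
    back = structio.read_segment_table(path)
    assert [r.pros_id for r in back] == [r.pros_id for r in records]
    assert back[1].partner_chain_ids == ["B", "C"]
    assert back[1].region == (5, 19)
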