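"""Domain-type validation and file round-trips."""

import pytest

from mimicryscan.io import (
    read_binding_table,
    read_elisa_table,
    read_epitope_table,
    read_fasta,
    read_hits_report,
    write_hits_report,
)
from mimicryscan.types import (
    BindingRecord,
    ELISAMeasurement,
    Epitope,
    FormatError,
    ProteinSequence,
    ScreenConfig,
)


class TestProteinSequence:
    def test_uppercases_and_validates(self):
        p = ProteinSequence(id="P81453", residues="dsdd")
        assert p.residues == "DSDD"
        assert len(p) == 4

    @pytest.mark.parametrize("bad", ["DS1D", "ACDZ", "AC DE", ""])
    def test_illegal_residues_raise_naming_record(self, bad):
        with pytest.raises(FormatError, match="P81453|empty"):
            ProteinSequence(id="P81453", residues=bad)

    def test_x_is_accepted_but_flagged(self):
        p = ProteinSequence(id="q", residues="ACXD")
        assert p.has_ambiguous


class TestConfigInvariants:
    def test_min_length_must_cover_min_identity(self):
        with pytest.raises(ValueError):
            ScreenConfig(min_identity=10, min_length=5)

    def test_gap_penalty_ordering(self):
        with pytest.raises(ValueError):
            ScreenConfig(gap_open=2, gap_extend=4)


def test_read_fasta_roundtrip(tmp_path):
    path = tmp_path / "t.fasta"
    path.write_text(">P81453 target\nDSDDRVT\n>Q2 other\nACDEF\n")
    seqs = read_fasta(path)
    assert [s.id for s in seqs] == ["P81453", "Q2"]
    assert seqs[0].residues == "DSDDRVT"


def test_read_fasta_rejects_bad_residues(tmp_path):
    path = tmp_path / "t.fasta"
    path.write_text(">rec1\nAC1DE\n")
    with pytest.raises(FormatError, match="rec1"):
        read_fasta(path)


def test_read_fasta_empty_file(tmp_path):
    path = tmp_path / "t.fasta"
    path.write_text("")
    with pytest.raises(FormatError, match="no FASTA"):
        read_fasta(path)


EPITOPE_HEADER = "epitope_id\tsequence\tparent_antigen\tdiseases\toutcome\n"


def test_epitope_table_drops_negative_outcomes(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text(
        EPITOPE_HEADER
        + "E1\tACDEF\tAg1\tRA\tPositive\n"
        + "E2\tGHIKL\tAg2\tSS\tNegative\n"
        + "E3\tMNPQR\tAg3\t\tPositive\n"
    )
    eps = read_epitope_table(path)
    assert {e.epitope_id for e in eps} == {"E1", "E3"}
    assert all(e.positive for e in eps)


def test_epitope_table_merges_duplicates_with_disease_union(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text(
        EPITOPE_HEADER
        + "E1\tACDEF\tAg1\tRA\tPositive\n"
        + "E2\tACDEF\tAg1\tSS;T1DM\tPositive\n"
    )
    eps = read_epitope_table(path)
    assert len(eps) == 1
    assert eps[0].diseases == {"RA", "SS", "T1DM"}


def test_epitope_table_unmapped_column_is_config_error(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("id\tpeptide\toutcome\nE1\tACDEF\tPositive\n")
    with pytest.raises(FormatError, match="sequence"):
        read_epitope_table(path)


def test_epitope_table_custom_column_map(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text(
        "Epitope ID\tDescription\tAntigen\tDisease\tQualitative Measure\n"
        "1\tACDEF\tAg1\tRA\tPositive\n"
    )
    eps = read_epitope_table(
        path,
        column_map={
            "epitope_id": "Epitope ID",
            "sequence": "Description",
            "parent_antigen": "Antigen",
            "diseases": "Disease",
            "outcome": "Qualitative Measure",
        },
    )
    assert eps[0].sequence == "ACDEF"


def test_binding_table_malformed_numeric_reports_line(tmp_path):
    path = tmp_path / "b.tsv"
    path.write_text(
        "peptide\tallele\thla_class\tic50_nM\n"
        "ACDEF\tHLA-A*02:01\tI\t12.5\n"
        "GHIKL\tHLA-A*02:01\tI\tabc\n"
    )
    with pytest.raises(FormatError, match="line 3"):
        read_binding_table(path)


def test_elisa_table_roundtrip_and_bad_od(tmp_path):
    good = tmp_path / "good.tsv"
    good.write_text(
        "antigen\tantibody\tod1\tod2\nTG6\tpolyclonal\t0.29\t0.30\n"
    )
    (m,) = read_elisa_table(good)
    assert m.ods == (0.29, 0.30)
    bad = tmp_path / "bad.tsv"
    bad.write_text("antigen\tantibody\tod1\tod2\nTG6\tpolyclonal\tabc\t0.3\n")
    with pytest.raises(FormatError, match="line 2"):
        read_elisa_table(bad)


def test_binding_record_rejects_nonpositive_ic50():
    with pytest.raises(FormatError):
        BindingRecord(peptide="ACD", allele="HLA-A*02:01", hla_class="I", ic50_nM=0)


def test_elisa_measurement_rejects_negative_od():
    with pytest.raises(FormatError):
        ELISAMeasurement(antigen="x", antibody="polyclonal", ods=(0.1, -0.2))


def _dummy_hits(blosum62):
    from mimicryscan.fixtures import aligned_pair_hits

    return aligned_pair_hits(blosum62)[:2]


def test_hits_report_roundtrip(tmp_path, blosum62):
    hits = _dummy_hits(blosum62)
    path = tmp_path / "hits.tsv"
    write_hits_report(hits, path)
    df = read_hits_report(path)
    assert len(df) == 2
    for hit, (_, row) in zip(hits, df.iterrows()):
        assert row["human"] == hit.alignment.aligned_query
        assert row["mtg"] == hit.alignment.aligned_target
        assert row["ln"] == hit.alignment.length
        assert row["identity"] == hit.alignment.n_identity
        assert row["similarity"] == hit.alignment.n_similarity
        assert row["diseases"] == ";".join(sorted(hit.epitope.diseases))


def test_hits_report_empty_is_header_only(tmp_path):
    path = tmp_path / "hits.tsv"
    write_hits_report([], path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1
    assert read_hits_report(path).empty


def test_epitope_rejects_empty_sequence():
    with pytest.raises(FormatError):
        Epitope(epitope_id="E1", sequence="", parent_antigen="Ag")
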