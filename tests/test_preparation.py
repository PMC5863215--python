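import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam.preparation import (
    FeatureStore,
    PreparationError,
    SequenceRecord,
    demangle_id,
    mangle_headers,
    read_fasta,
    read_gff3,
    sanitize_species,
    select_longest_cds,
)

from conftest import nt_record


class TestReadFasta:
    def test_normalizes_case_and_takes_first_header_token(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">t1 descr text\nacgt\n")
        (rec,) = read_fasta(p, "nt")
        assert rec.id == "t1"
        assert rec.seq == "ACGT"

    def test_duplicate_id_rejected_with_offender(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">t1\nACG\n>t1\nTTT\n")
        with pytest.raises(PreparationError, match="t1"):
            read_fasta(p, "nt")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text("")
        with pytest.raises(PreparationError):
            read_fasta(p, "nt")

    def test_illegal_characters_name_the_record(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">bad\nAC-GT\n")
        with pytest.raises(PreparationError, match="bad"):
            read_fasta(p, "nt")


GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1
chr1\tsrc\tCDS\t100\t199\t.\t+\t.\tID=t1.c;Parent=t1
chr1\tsrc\tCDS\t300\t350\t.\t+\t.\tID=t1.c;Parent=t1
chr1\tsrc\tgene\t900\t1400\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t900\t1400\t.\t-\t.\tID=t2;Parent=g2
chr1\tsrc\tCDS\t900\t999\t.\t-\t.\tID=t2.c;Parent=t2
chr1\tsrc\tCDS\t1200\t1400\t.\t-\t.\tID=t2.c;Parent=t2
"""


class TestReadGff3:
    def test_gene_fields_mapped_directly(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        feats = read_gff3(p, "spx")
        g1 = next(f for f in feats if f.feature_id == "g1")
        assert (g1.ftype, g1.start, g1.end, g1.strand) == ("gene", 100, 500, "+")

    def test_cds_ranks_follow_transcript_orientation(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        store = FeatureStore(read_gff3(p, "spx"))
        plus = store.cds_segments_of("t1")
        assert [(s.rank, s.start) for s in plus] == [(1, 100), (2, 300)]
        minus = store.cds_segments_of("t2")
        # 5'->3' on the minus strand runs from the highest start downwards
        assert [(s.rank, s.start) for s in minus] == [(1, 1200), (2, 900)]

    def test_unresolvable_parent_names_the_parent(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\ts\tCDS\t1\t9\t.\t+\t.\tID=c;Parent=tX\n")
        with pytest.raises(PreparationError, match="tX"):
            read_gff3(p, "spx")

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\ts\tgene\t500\t100\t.\t+\t.\tID=g\n")
        with pytest.raises(PreparationError):
            read_gff3(p, "spx")

    def test_regrouping_by_parent_reconstructs_hierarchy(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        feats = read_gff3(p, "spx")
        store = FeatureStore(feats)
        store.validate()
        regrouped = {
            f.feature_id
            for g in store.genes()
            for t in store.transcripts_of(g.feature_id)
            for f in [g, t, *store.cds_segments_of(t.feature_id)]
        }
        assert regrouped == {f.feature_id for f in feats if f.ftype != "exon"}


class TestMangling:
    def test_species_label_appended(self):
        (out,) = mangle_headers([nt_record("ENST0001", "ATG")], "Homo sapiens")
        assert out.id == "ENST0001_homo_sapiens"
        assert out.species == "homo_sapiens"

    def test_empty_species_rejected(self):
        with pytest.raises(PreparationError):
            mangle_headers([nt_record("t1", "ATG")], "??")

    def test_collision_detected(self):
        # duplicate input ids necessarily mangle to the same output id
        records = [nt_record("t1", "ATG"), nt_record("t1", "CCC")]
        with pytest.raises(PreparationError, match="collision"):
            mangle_headers(records, "sp")

    def test_longest_suffix_wins_on_underscored_labels(self):
        orig, label = demangle_id("t1_canis_lupus_familiaris", ["familiaris", "canis_lupus_familiaris"])
        assert (orig, label) == ("t1", "canis_lupus_familiaris")

    @settings(max_examples=60, deadline=None)
    @given(
        sid=st.from_regex(r"[A-Za-z][A-Za-z0-9]{0,12}", fullmatch=True),
        species=st.from_regex(r"[a-z][a-z0-9 ]{0,15}[a-z0-9]", fullmatch=True),
    )
    def test_mangle_demangle_roundtrip(self, sid, species):
        label = sanitize_species(species)
        (out,) = mangle_headers([nt_record(sid, "ATG")], species)
        assert demangle_id(out.id, [label]) == (sid, label)


class TestSelectLongestCds:
    def test_longest_kept_per_gene(self, tiny_store):
        records = [nt_record("t1a", "A" * 300), nt_record("t1b", "A" * 450), nt_record("t2", "ATG")]
        kept = select_longest_cds(records, tiny_store)
        assert {r.id for r in kept} == {"t1b", "t2"}

    def test_tie_breaks_to_smallest_transcript_id(self, tiny_store):
        records = [nt_record("t1b", "A" * 300), nt_record("t1a", "A" * 300)]
        kept = select_longest_cds(records, tiny_store)
        assert [r.id for r in kept] == ["t1a"]

    def test_single_transcript_gene_passes_through(self, tiny_store):
        records = [nt_record("t2", "ATGCCC")]
        assert select_longest_cds(records, tiny_store) == records

    def test_one_record_per_gene_and_subset_of_input(self, tiny_store):
        records = [nt_record("t1a", "A" * 9), nt_record("t1b", "A" * 6), nt_record("t2", "ATG")]
        kept = select_longest_cds(records, tiny_store)
        assert len(kept) == 2
        assert set(kept) <= set(records)

    def test_unknown_transcript_rejected(self, tiny_store):
        with pytest.raises(PreparationError, match="tZ"):
            select_longest_cds([nt_record("tZ", "ATG")], tiny_store)

    def test_mangled_ids_resolved_via_species_labels(self, tiny_store):
        records = mangle_headers([nt_record("t1a", "A" * 9), nt_record("t1b", "A" * 6)], "spx")
        kept = select_longest_cds(records, tiny_store, ["spx"])
        assert [r.id for r in kept] == ["t1a_spx"]
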