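import numpy as np
import pytest
from hypothesis import given, strategies as st

from v6pipe.fileio import (
    DistanceMatrix,
    FastaParseError,
    ManifestEntry,
    SampleManifest,
    TagRecord,
    TaxonomyPath,
    ValidationError,
    qc_filter_tags,
    read_distance_matrix,
    read_fasta,
    read_manifest,
    read_reference_db,
    read_table,
    write_distance_matrix,
    write_fasta,
    write_manifest,
    write_reference_db,
    write_table,
)


def write_text(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_three_records_in_file_order(self, tmp_path):
        p = write_text(
            tmp_path, "x.fa", ">t1\nACGT\n>t2\nGGGG\nCCCC\n>t3\nTTTT\n"
        )
        recs = read_fasta(p, sample_id="s1")
        assert [r.tag_id for r in recs] == ["t1", "t2", "t3"]
        assert recs[1].sequence == "GGGGCCCC"

    def test_lowercase_and_u_normalized(self, tmp_path):
        p = write_text(tmp_path, "x.fa", ">t1\nacgu\n")
        assert read_fasta(p, sample_id="s")[0].sequence == "ACGT"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = write_text(tmp_path, "x.fa", "")
        assert read_fasta(p) == []

    def test_sample_field_in_header(self, tmp_path):
        p = write_text(tmp_path, "x.fa", ">t1 sample=w3\nACGT\n")
        assert read_fasta(p)[0].sample_id == "w3"

    def test_duplicate_tag_id_raises(self, tmp_path):
        p = write_text(tmp_path, "x.fa", ">t1\nACGT\n>t1\nGGGG\n")
        with pytest.raises(FastaParseError, match="t1"):
            read_fasta(p)

    def test_sequence_before_header_names_line(self, tmp_path):
        p = write_text(tmp_path, "x.fa", "ACGT\n>t1\nACGT\n")
        with pytest.raises(FastaParseError, match=":1"):
            read_fasta(p)

    def test_header_without_sequence_raises(self, tmp_path):
        p = write_text(tmp_path, "x.fa", ">t1\n>t2\nACGT\n")
        with pytest.raises(FastaParseError, match="t1"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "y.fa"
        write_fasta(p, [("a", "ACGT" * 30), ("b", "TTGA")])
        recs = read_fasta(p, sample_id="s")
        assert [(r.tag_id, r.sequence) for r in recs] == [
            ("a", "ACGT" * 30),
            ("b", "TTGA"),
        ]


class TestQcFilter:
    def test_50nt_rule(self, tag_factory):
        tags = [tag_factory("A" * n) for n in (49, 50, 60)]
        kept, removed = qc_filter_tags(tags)
        assert [t.length for t in kept] == [50, 60]
        assert [t.length for t in removed] == [49]

    def test_min_len_zero_keeps_all(self, tag_factory):
        tags = [tag_factory("A" * n) for n in (1, 5, 49)]
        kept, removed = qc_filter_tags(tags, min_len=0)
        assert len(kept) == 3 and not removed

    def test_single_n_removed_by_default(self, tag_factory):
        tag = tag_factory("A" * 30 + "N" + "A" * 29)
        assert tag.length == 60
        kept, removed = qc_filter_tags([tag])
        assert not kept and removed == [tag]

    def test_max_n_relaxed(self, tag_factory):
        tag = tag_factory("A" * 59 + "N")
        kept, _ = qc_filter_tags([tag], max_n=1)
        assert kept == [tag]

    @given(
        lengths=st.lists(st.integers(min_value=1, max_value=80), max_size=30),
        min_len=st.integers(min_value=0, max_value=80),
    )
    def test_partition_property(self, lengths, min_len):
        tags = [
            TagRecord(f"t{i}", "s", "A" * n) for i, n in enumerate(lengths)
        ]
        kept, removed = qc_filter_tags(tags, min_len=min_len)
        assert len(kept) + len(removed) == len(tags)
        assert set(t.tag_id for t in kept).isdisjoint(t.tag_id for t in removed)


class TestTaxonomyPath:
    def test_prefix_complete_suffix_ok(self):
        path = TaxonomyPath.from_string("Chloroflexi;Anaerolineae;;;")
        assert path.labels == ("Chloroflexi", "Anaerolineae", "", "", "")
        assert path.depth == 2

    def test_gap_in_middle_rejected(self):
        with pytest.raises(ValidationError):
            TaxonomyPath.from_string("PhyA;;OrdA;;")

    def test_roundtrip_string(self):
        s = "P;C;O;F;G"
        assert TaxonomyPath.from_string(s).to_string() == s


class TestReferenceDB:
    def test_read_write_roundtrip(self, tmp_path, tiny_db):
        p = tmp_path / "db.tsv"
        write_reference_db(tiny_db, p)
        db2 = read_reference_db(p)
        assert len(db2) == len(tiny_db)
        assert db2["R1"].cluster_label == "SC01"
        assert db2["R3"].cluster_label is None
        assert db2["R4"].taxonomy.to_string() == "PhyB;ClsB;OrdC;FamC;GenC"

    def test_cluster_label_carried(self, tmp_path):
        p = write_text(
            tmp_path,
            "db.tsv",
            "ref_id\ttaxonomy\tcluster_label\tsequence\n"
            "R1\tPhyA;;;;\tSC70\tACGTACGT\n",
        )
        assert read_reference_db(p)["R1"].cluster_label == "SC70"

    def test_taxonomy_gap_names_ref(self, tmp_path):
        p = write_text(
            tmp_path,
            "db.tsv",
            "ref_id\ttaxonomy\tcluster_label\tsequence\n"
            "Rbad\tPhyA;;OrdA;;\t\tACGT\n",
        )
        with pytest.raises(ValidationError, match="Rbad"):
            read_reference_db(p)

    def test_duplicate_ref_id(self, tmp_path):
        p = write_text(
            tmp_path,
            "db.tsv",
            "ref_id\ttaxonomy\tcluster_label\tsequence\n"
            "R1\tPhyA;;;;\t\tACGT\nR1\tPhyB;;;;\t\tGGGG\n",
        )
        with pytest.raises(ValidationError, match="R1"):
            read_reference_db(p)

    def test_phylum_required(self, tmp_path):
        p = write_text(
            tmp_path,
            "db.tsv",
            "ref_id\ttaxonomy\tcluster_label\tsequence\nR1\t;;;;\t\tACGT\n",
        )
        with pytest.raises(ValidationError, match="phylum"):
            read_reference_db(p)


class TestDistanceMatrix:
    def test_lower_triangle_2x2(self, tmp_path):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.05], [0.05, 0]]))
        p = tmp_path / "m.phy"
        write_distance_matrix(m, p, "phylip-lower")
        lines = p.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[2].split() == ["b", "0.050000"]

    @pytest.mark.parametrize("dialect", ["phylip-square", "phylip-lower"])
    def test_roundtrip(self, tmp_path, rng, dialect):
        n = 7
        vals = rng.random((n, n))
        vals = np.round((vals + vals.T) / 2, 6)
        np.fill_diagonal(vals, 0)
        m = DistanceMatrix([f"u{i}" for i in range(n)], vals)
        p = tmp_path / "m.phy"
        write_distance_matrix(m, p, dialect)
        m2 = read_distance_matrix(p, dialect)
        assert m2.labels == m.labels
        np.testing.assert_allclose(m2.values, m.values, atol=1e-6)

    def test_zero_label_matrix_rejected(self, tmp_path):
        m = DistanceMatrix([], np.zeros((0, 0)))
        with pytest.raises(ValidationError):
            write_distance_matrix(m, tmp_path / "m.phy")

    def test_unknown_dialect(self, tmp_path):
        m = DistanceMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="dialect"):
            write_distance_matrix(m, tmp_path / "m.phy", "nexus")

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))


class TestManifest:
    def test_roundtrip(self, tmp_path, tiny_manifest):
        p = tmp_path / "m.tsv"
        write_manifest(tiny_manifest, p)
        m2 = read_manifest(p)
        assert m2.sample_ids == tiny_manifest.sample_ids
        assert m2["w1"].group == "seawater"
        assert m2["a2"].replicate == 2

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValidationError):
            SampleManifest(
                [
                    ManifestEntry("a1", "adult", "x", 1),
                    ManifestEntry("a1", "adult", "x", 2),
                ]
            )

    def test_bad_group_rejected(self):
        with pytest.raises(ValidationError, match="group"):
            ManifestEntry("a1", "juvenile", "x", 1)

    def test_resolution_fails_loudly(self, tiny_manifest, tag_factory):
        tags = [tag_factory("ACGT" * 15, sample_id="nope")]
        with pytest.raises(ValidationError, match="nope"):
            tiny_manifest.resolve(tags)

    def test_groups(self, tiny_manifest):
        assert tiny_manifest.samples_in_group("seawater") == ["w1", "w2"]
        assert tiny_manifest.group_of("l1") == "larvae"


class TestTables:
    def test_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"s1": [5, 0, 1], "s2": [3, 2, 0]},
            index=["OTU1", "OTU2", "OTU3"],
        )
        df.index.name = "otu_id"
        p = tmp_path / "t.tsv"
        write_table(df, p)
        assert len(p.read_text().splitlines()) == 4  # header + 3 rows
        df2 = read_table(p)
        assert (df2.values == df.values).all()

    def test_empty_table_header_only(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(columns=["s1", "s2"])
        p = tmp_path / "t.tsv"
        write_table(df, p, index=False)
        assert p.read_text().splitlines() == ["s1\ts2"]


class TestReadAlignedFasta:
    def test_gapped_rows(self, tmp_path):
        from v6pipe.fileio import read_aligned_fasta

        p = write_text(tmp_path, "a.fa", ">u1\nAC--GT\n>u2\nACTTGT\n")
        rows = read_aligned_fasta(p)
        assert rows == {"u1": "AC--GT", "u2": "ACTTGT"}

    def test_ragged_rejected(self, tmp_path):
        from v6pipe.fileio import read_aligned_fasta
        from v6pipe.fileio import ValidationError

        p = write_text(tmp_path, "a.fa", ">u1\nAC--GT\n>u2\nACT\n")
        with pytest.raises(ValidationError, match="length"):
            read_aligned_fasta(p)
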