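import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyfaidx import Fasta

from sreassoc import (
    GeneModel,
    MotifSet,
    VariantRecord,
    annotate_variants,
    classify_region,
    extract_window,
    read_motifs,
    read_vcf_records,
    scan_sre,
)
from sreassoc.annotate import AnnotationQC
from sreassoc.genemodels import read_bed12, read_gff3

from oracles import brute_force_scan

BASES = "ACGT"


@pytest.fixture()
def toy_genome(tmp_path):
    seq = "ACGTACGTACGTACGT"
    (tmp_path / "g.fa").write_text(">chr1\n" + seq + "\n")
    return Fasta(str(tmp_path / "g.fa"))


class TestExtractWindow:
    def test_direct_substring(self, toy_genome):
        assert extract_window(toy_genome, "chr1", 8) == "GTACGTACGTA"

    def test_window_length_is_eleven(self, toy_genome):
        for pos in range(6, 12):
            assert len(extract_window(toy_genome, "chr1", pos)) == 11

    def test_center_base_is_reference_base(self, toy_genome):
        for pos in range(6, 12):
            w = extract_window(toy_genome, "chr1", pos)
            assert w[5] == str(toy_genome["chr1"][pos - 1]).upper()

    def test_out_of_bounds_named_in_error(self, toy_genome):
        with pytest.raises(ValueError, match="chr1:4"):
            extract_window(toy_genome, "chr1", 4)
        with pytest.raises(ValueError, match="chr1:13"):
            extract_window(toy_genome, "chr1", 13)

    def test_unknown_contig(self, toy_genome):
        with pytest.raises(KeyError, match="chr9"):
            extract_window(toy_genome, "chr9", 8)


class TestScanSre:
    def test_positive_match(self):
        assert scan_sre("AAAAAAAAAAA", MotifSet("ESE", frozenset({"AAAAAA"})))

    def test_no_match(self):
        assert not scan_sre("ACGTACGTACG", MotifSet("ESE", frozenset({"TTTTTT"})))

    def test_n_never_matches(self):
        assert not scan_sre("AANAAAAANAA", MotifSet("ESE", frozenset({"AAAAAA"})))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="11-mer"):
            scan_sre("AAAA", MotifSet("ESE", frozenset({"AAAAAA"})))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            window = "".join(rng.choice(list(BASES), 11))
            motifs = frozenset(
                "".join(rng.choice(list(BASES), 6)) for _ in range(rng.integers(1, 5))
            )
            ms = MotifSet("ESS", motifs)
            assert scan_sre(window, ms) == brute_force_scan(window, motifs)

    @settings(max_examples=300, derandomize=True)
    @given(
        window=st.text(alphabet="ACGT", min_size=11, max_size=11),
        motif=st.text(alphabet="ACGT", min_size=6, max_size=6),
    )
    def test_property_matches_brute_force(self, window, motif):
        ms = MotifSet("ISE", frozenset({motif}))
        assert scan_sre(window, ms) == brute_force_scan(window, {motif})


def _variant(contig, pos):
    return VariantRecord(contig, pos, None, "A", "C", np.zeros(4, dtype=np.int8))


class TestClassifyRegion:
    model = GeneModel("g1", "chr1", "+", ((100, 199), (300, 399), (500, 599)))

    @pytest.mark.parametrize(
        "pos,expect",
        [
            (100, [("exonic", "g1")]),  # first exon start boundary
            (199, [("exonic", "g1")]),  # exon end boundary
            (200, [("intronic", "g1")]),  # first intron base
            (299, [("intronic", "g1")]),  # last intron base
            (300, [("exonic", "g1")]),
            (350, [("exonic", "g1")]),
            (450, [("intronic", "g1")]),
            (99, [("intergenic", None)]),
            (600, [("intergenic", None)]),
        ],
    )
    def test_boundaries(self, pos, expect):
        assert classify_region(_variant("chr1", pos), [self.model]) == expect

    def test_other_contig_is_intergenic(self):
        assert classify_region(_variant("chr2", 150), [self.model]) == [
            ("intergenic", None)
        ]

    def test_overlapping_genes_yield_both_assignments(self):
        other = GeneModel("g2", "chr1", "-", ((150, 250),))
        hits = classify_region(_variant("chr1", 180), [self.model, other])
        assert ("exonic", "g1") in hits and ("exonic", "g2") in hits
        hits = classify_region(_variant("chr1", 230), [self.model, other])
        assert set(hits) == {("intronic", "g1"), ("exonic", "g2")}


class TestGeneModelReaders:
    def test_bed12_zero_based_conversion(self, tmp_path):
        # one gene, two exons: [10,20) and [40,55) in BED -> 1-based closed
        bed = "chr1\t10\t55\tgX\t0\t+\t10\t55\t0\t2\t10,15\t0,30\n"
        (tmp_path / "m.bed").write_text(bed)
        (m,) = read_bed12(tmp_path / "m.bed")
        assert m.exons == ((11, 20), (41, 55))
        assert m.introns == ((21, 40),)

    def test_gff3_reader_agrees_with_bed12(self, tmp_path):
        bed = "chr1\t10\t55\tgX\t0\t+\t10\t55\t0\t2\t10,15\t0,30\n"
        gff = (
            "##gff-version 3\n"
            "chr1\t.\texon\t11\t20\t.\t+\t.\tgene_id=gX;Parent=gX.t1\n"
            "chr1\t.\texon\t41\t55\t.\t+\t.\tgene_id=gX;Parent=gX.t1\n"
        )
        (tmp_path / "m.bed").write_text(bed)
        (tmp_path / "m.gff3").write_text(gff)
        (b,) = read_bed12(tmp_path / "m.bed")
        (g,) = read_gff3(tmp_path / "m.gff3")
        assert b.exons == g.exons
        assert b.contig == g.contig

    def test_invalid_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g", "c", "+", ((10, 30), (20, 40)))


class TestAnnotateVariants:
    def _setup(self, tmp_path, seq, exons):
        (tmp_path / "g.fa").write_text(">chr1\n" + seq + "\n")
        genome = Fasta(str(tmp_path / "g.fa"))
        model = GeneModel("g1", "chr1", "+", exons)
        return genome, [model]

    def test_exonic_ese_match(self, tmp_path):
        seq = "T" * 50
        seq = seq[:19] + "AAAAAA" + seq[25:]  # motif at 1-based 20..25
        genome, models = self._setup(tmp_path, seq, ((10, 40),))
        v = VariantRecord("chr1", 22, None, seq[21], "G", np.zeros(2, dtype=np.int8))
        (ann,) = annotate_variants([v], genome, models, {"ESE": MotifSet("ESE", frozenset({"AAAAAA"}))})
        assert ann.region == "exonic"
        assert ann.categories == {"ESE"}

    def test_intronic_variant_never_gets_coding_category(self, tmp_path):
        seq = "T" * 80
        seq = seq[:49] + "AAAAAA" + seq[55:]  # motif inside the intron
        genome, models = self._setup(tmp_path, seq, ((10, 30), (60, 79)))
        v = VariantRecord("chr1", 52, None, seq[51], "G", np.zeros(2, dtype=np.int8))
        motif_sets = {
            "ESE": MotifSet("ESE", frozenset({"AAAAAA"})),
            "ESS": MotifSet("ESS", frozenset({"AAAAAA"})),
        }
        (ann,) = annotate_variants([v], genome, models, motif_sets)
        assert ann.region == "intronic"
        assert ann.categories == frozenset()  # ESE motif cannot fire intronic

    def test_ref_mismatch_warns_and_counts(self, tmp_path):
        genome, models = self._setup(tmp_path, "A" * 50, ((10, 40),))
        v = VariantRecord("chr1", 20, None, "C", "G", np.zeros(2, dtype=np.int8))
        qc = AnnotationQC()
        with pytest.warns(UserWarning, match="chr1:20"):
            list(annotate_variants([v], genome, models, {}, qc=qc))
        assert qc.n_ref_mismatch == 1

    def test_truth_table_recovery_and_consistency(self, small_cohort):
        genome = Fasta(str(small_cohort.fasta_path))
        models = read_bed12(small_cohort.gene_model_path)
        motif_sets = {
            cat: read_motifs(p, cat) for cat, p in small_cohort.motif_paths.items()
        }
        variants = list(read_vcf_records(small_cohort.vcf_path))
        anns = list(annotate_variants(variants, genome, models, motif_sets))
        by_key = {}
        for a in anns:
            by_key.setdefault(a.key, []).append(a)
        # every variant annotated; region/category consistency on all outputs
        assert len(by_key) == len(variants)
        for a in anns:
            if "ESE" in a.categories or "ESS" in a.categories:
                assert a.region == "exonic"
            if "ISE" in a.categories:
                assert a.region == "intronic"
        # every planted SRE site recovered with its planted category
        for gid, truth in small_cohort.truth.items():
            for pos, cat in truth.planted_categories.items():
                matches = by_key[f"{gid}:{pos}"]
                assert any(cat in a.categories for a in matches), (gid, pos, cat)
                (a,) = [x for x in matches if x.gene_id == gid]
                expected_region = "exonic" if cat in ("ESE", "ESS") else "intronic"
                assert a.region == expected_region
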