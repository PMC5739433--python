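"""Consequence annotation, HGVS parsing, UV-context flags, novelty lookup."""

import numpy as np
import pytest

from conftest import random_transcript
from oracles import consequence_by_diff
from lenscall.annotate import (CatalogRecord, HgvsParseError, annotate_variant,
                               classify_substitution, dipyrimidine_flags,
                               is_damaging, lookup_novelty, parse_hgvs,
                               read_catalog, read_damage_labels, write_catalog)
from lenscall.calling import VariantCall
from lenscall.refmodel import Genome


def call(pos, ref, alt, contig="c"):
    return VariantCall(contig, pos, ref, alt, 10, 1000, 1.0, "somatic")


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", "transition"), ("A", "G", "transition"),
        ("G", "A", "transition"), ("C", "G", "transversion"),
        ("A", "T", "transversion"), ("G", "T", "transversion"),
    ])
    def test_purine_pyrimidine_classes(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("C", "C")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("C", "U")


class TestAnnotateVariant:
    def test_plus_missense(self, plus_toy):
        genome, tm = plus_toy
        cons = annotate_variant(call(14, "G", "A"), tm, genome)
        assert (cons.klass, cons.hgvs_c, cons.hgvs_p) == ("missense", "c.4G>A", "p.E2K")

    def test_plus_stopgain(self, plus_toy):
        genome, tm = plus_toy
        cons = annotate_variant(call(14, "G", "T"), tm, genome)
        assert (cons.klass, cons.hgvs_p) == ("stopgain", "p.E2X")

    def test_plus_synonymous(self, plus_toy):
        genome, tm = plus_toy
        # codon 2 GAA -> GAG, both E
        cons = annotate_variant(call(16, "A", "G"), tm, genome)
        assert (cons.klass, cons.hgvs_p) == ("synonymous", "p.E2E")

    def test_minus_coding_alleles_are_complemented(self, minus_toy):
        genome, tm = minus_toy
        # c.4 maps to genomic 36; coding G -> plus-strand C
        from lenscall.refmodel import CdsCoordinate, cds_to_genomic, CDS
        g4 = cds_to_genomic(CdsCoordinate(4, 0, CDS), tm)
        plus_ref = genome.base("c", g4)
        cons = annotate_variant(call(g4, plus_ref, "T"), tm, genome)
        assert cons.hgvs_c.startswith("c.4")
        assert cons.coding_ref == "G" and cons.coding_alt == "A"

    def test_intron_plus_one_is_splice(self, minus_toy):
        genome, tm = minus_toy
        # genomic 30 is transcript-orientation +1 past c.9 (exon ends at g=31)
        b = genome.base("c", 30)
        alt = "A" if b != "A" else "G"
        cons = annotate_variant(call(30, b, alt), tm, genome)
        assert cons.klass == "splice"
        assert cons.hgvs_c.startswith("c.9+1")

    def test_deep_intron_is_intronic(self, minus_toy):
        genome, tm = minus_toy
        b = genome.base("c", 25)
        alt = "A" if b != "A" else "G"
        assert annotate_variant(call(25, b, alt), tm, genome).klass == "intronic"

    def test_off_transcript_is_intergenic_not_error(self, plus_toy):
        genome, tm = plus_toy
        assert annotate_variant(call(2, "C", "T"), tm, genome).klass == "intergenic"

    def test_reference_mismatch_detected(self, plus_toy):
        genome, tm = plus_toy
        with pytest.raises(ValueError, match="mismatch"):
            annotate_variant(call(11, "C", "T"), tm, genome)  # true ref is A

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_translate_and_diff_oracle(self, strand):
        """klass equals a brute-force oracle that rebuilds the mRNA,
        substitutes, translates both proteins and diffs them (500 random
        substitutions over random transcripts, both strands)."""
        rng = np.random.default_rng(42 if strand == "+" else 43)
        checked = 0
        while checked < 250:
            genome, tm = random_transcript(rng, strand)
            seq = genome.sequences["c" if "c" in genome.sequences else "r"]
            lo, hi = sorted((tm.cds_start_genomic, tm.cds_end_genomic))
            pos = int(rng.integers(lo, hi + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            expected = consequence_by_diff(seq, tm.exons, strand,
                                           tm.cds_start_genomic,
                                           tm.cds_end_genomic, pos, ref, alt)
            if expected is None:  # intronic draw
                continue
            got = annotate_variant(call(pos, ref, alt, tm.contig), tm, genome)
            assert got.klass == expected, (strand, pos, ref, alt)
            checked += 1

    def test_parse_round_trip_recovers_class_and_position(self, plus_toy):
        genome, tm = plus_toy
        for pos, ref, alt in [(14, "G", "A"), (14, "G", "T"), (16, "A", "G")]:
            cons = annotate_variant(call(pos, ref, alt), tm, genome)
            back = parse_hgvs(cons.hgvs_c, cons.hgvs_p)
            assert back.klass == cons.klass
            assert back.cds_pos == cons.cds_pos
            assert (back.aa_ref, back.aa_alt) == (cons.aa_ref, cons.aa_alt)


class TestParseHgvs:
    @pytest.mark.parametrize("c,p,klass,cds_pos", [
        ("c.G2740T", "p.E914X", "stopgain", 2740),
        ("c.C2826T", "p.D942D", "synonymous", 2826),
        ("c.2162G>A", "p.R721Q", "missense", 2162),
        ("c.1682+1G>A", "", "splice", 1682),
        ("c.*3C>T", "", "UTR3", 3),
        ("c.-12G>A", "", "UTR5", 12),
        ("c.2016 C>T", "p.H672H", "synonymous", 2016),
    ])
    def test_printed_dialects(self, c, p, klass, cds_pos):
        cons = parse_hgvs(c, p)
        assert (cons.klass, cons.cds_pos) == (klass, cds_pos)

    def test_unparseable_string_names_the_token(self):
        with pytest.raises(HgvsParseError, match="c.bogus"):
            parse_hgvs("c.bogus")

    def test_alleles_recovered_from_ref_first_dialect(self):
        cons = parse_hgvs("c.G2740T")
        assert (cons.coding_ref, cons.coding_alt) == ("G", "T")


class TestDipyrimidineFlags:
    def g(self, seq):
        return Genome({"c": seq})

    def test_plus_strand_tc_context_is_uv_signature(self):
        fl = dipyrimidine_flags(call(2, "C", "T"), self.g("TCG"))
        assert (fl.dipyrimidine, fl.uv_signature, fl.pyrimidine_strand) \
            == (True, True, "+")

    def test_no_adjacent_pyrimidine_no_dipy(self):
        fl = dipyrimidine_flags(call(2, "C", "T"), self.g("ACA"))
        assert (fl.dipyrimidine, fl.uv_signature) == (False, False)

    def test_minus_strand_g_to_a_reads_complement(self):
        # plus AGT -> minus 5'-ACT-3'; the C has a 3' T neighbour
        fl = dipyrimidine_flags(call(2, "G", "A"), self.g("AGT"))
        assert (fl.dipyrimidine, fl.uv_signature, fl.pyrimidine_strand) \
            == (True, True, "-")

    def test_dipyrimidine_without_c_to_t_is_not_uv(self):
        fl = dipyrimidine_flags(call(2, "C", "G"), self.g("TCG"))
        assert fl.dipyrimidine and not fl.uv_signature

    def test_adjacent_n_disqualifies_conservatively(self):
        fl = dipyrimidine_flags(call(2, "C", "T"), self.g("NCA"))
        assert not fl.dipyrimidine and fl.ambiguous_context

    def test_contig_edge_uses_single_neighbour(self):
        fl = dipyrimidine_flags(call(1, "C", "T"), self.g("CTG"))
        assert fl.dipyrimidine and fl.uv_signature

    def test_strand_invariance_of_flags(self, rng):
        """The same physical event expressed on either strand (complemented
        alleles at the same position) yields identical flags."""
        from lenscall.refmodel import revcomp
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=5))
            ref = seq[2]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fwd = dipyrimidine_flags(call(3, ref, alt), self.g(seq))
            # expressing the event on the opposite strand = same plus-strand
            # record; the flagger must choose the pyrimidine strand itself
            rev = dipyrimidine_flags(call(3, ref, alt),
                                     self.g(seq))  # same record
            assert fwd == rev
            # and the minus-strand expression of a purine ref maps to the
            # complemented pyrimidine change
            if ref in "AG":
                assert fwd.pyrimidine_strand == "-"
                twin = dipyrimidine_flags(
                    call(3, revcomp(ref), revcomp(alt)),
                    self.g(revcomp(seq)))
                assert twin.dipyrimidine == fwd.dipyrimidine
                assert twin.uv_signature == fwd.uv_signature


class TestNovelty:
    cat = [CatalogRecord("chr1", 100, "C", "T", ("rs116506614",), "dbsnp")]
    cat2 = [CatalogRecord("chr1", 100, "C", "T", ("COSM1",), "cosmic")]

    def test_exact_match_is_reference_with_ids(self):
        nov, ids = lookup_novelty(call(100, "C", "T", "chr1"), [self.cat])
        assert nov == "reference" and ids == ("dbsnp:rs116506614",)

    def test_absent_is_novel(self):
        nov, ids = lookup_novelty(call(101, "C", "T", "chr1"), [self.cat])
        assert nov == "novel" and ids == ()

    def test_allele_exact_not_position_only(self):
        nov, _ = lookup_novelty(call(100, "C", "G", "chr1"), [self.cat])
        assert nov == "novel"

    def test_two_catalogs_concatenate_ids(self):
        nov, ids = lookup_novelty(call(100, "C", "T", "chr1"),
                                  [self.cat, self.cat2])
        assert nov == "reference" and len(ids) == 2

    def test_catalog_tsv_round_trip(self, tmp_path):
        write_catalog(self.cat, tmp_path / "c.tsv")
        assert read_catalog(tmp_path / "c.tsv") == self.cat

    def test_damage_aggregation_any_damaging(self, tmp_path):
        assert is_damaging(["tolerated", "damaging"])
        assert not is_damaging(["tolerated", "benign"])
        (tmp_path / "d.tsv").write_text(
            "contig\tpos\tref\talt\tpredictor\tlabel\tscore\n"
            "chr1\t100\tC\tT\tsift\tdamaging\t0.0\n"
            "chr1\t100\tC\tT\tpolyphen2\tbenign\t0.1\n")
        labels = read_damage_labels(tmp_path / "d.tsv")
        assert labels[("chr1", 100, "C", "T")] == ["damaging", "benign"]
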