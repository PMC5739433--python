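import numpy as np
import pytest

from lenscall.refmodel import Genome, TranscriptModel, revcomp


@pytest.fixture
def plus_toy():
    """Single-exon plus-strand model: CDS 'ATGGAATAG' at genomic 11..19."""
    seq = "ACGTACGTAC" + "ATGGAATAG" + "CGTACGTACGT"
    genome = Genome({"c": seq})
    tm = TranscriptModel("G", "T", "c", "+", [(5, 25)], 11, 19)
    return genome, tm


@pytest.fixture
def minus_toy():
    """Two-exon minus-strand model; the spliced CDS covers all 18 exonic bases.

    Exons at genomic 11..19 and 31..39; the transcript runs right-to-left, so
    c.1 sits at genomic 39 and the plus-strand exonic sequence is the reverse
    complement of the spliced CDS.
    """
    tx = "ATGGAAGGATCCTATTAG"  # 18 coding bases, starts ATG ends TAG
    ex_hi = revcomp(tx[:9])    # genomic 31..39
    ex_lo = revcomp(tx[9:])    # genomic 11..19
    seq = "A" * 10 + ex_lo + "ACGTACGTACG" + ex_hi + "ACGTA"
    genome = Genome({"c": seq})
    tm = TranscriptModel("G", "T", "c", "-", [(11, 19), (31, 39)], 11, 39)
    return genome, tm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_transcript(rng, strand, n_exons=3, codons_per_exon=4, utr=4,
                      intron=7, contig="r"):
    """Random toy genome + transcript for property tests (either strand)."""
    from lenscall.simdata import _random_cds

    cds = _random_cds(rng, codons_per_exon * n_exons)
    tx = ("".join(rng.choice(list("ACGT"), size=utr)) + cds
          + "".join(rng.choice(list("ACGT"), size=utr)))
    sizes = [3 * codons_per_exon] * n_exons
    sizes[0] += utr
    sizes[-1] += utr
    start = 6
    exons = []
    g = start
    for s in sizes:
        exons.append((g, g + s - 1))
        g += s + intron
    length = g + 5
    bases = list(rng.choice(list("ACGT"), size=length))
    order = [p for s, e in exons for p in range(s, e + 1)]
    if strand == "-":
        order = order[::-1]
    for i, p in enumerate(order):
        bases[p - 1] = revcomp(tx[i]) if strand == "-" else tx[i]
    cds_pos = order[utr: utr + len(cds)]
    genome = Genome({contig: "".join(bases)})
    tm = TranscriptModel("G", "T", contig, strand, exons,
                         min(cds_pos), max(cds_pos))
    return genome, tm
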