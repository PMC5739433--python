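"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code path with the package internals: the exact
test enumerates margin-preserving tables in rational arithmetic; the
consequence oracle rebuilds the whole spliced CDS, substitutes, translates
both proteins with a hard-coded codon table, and diffs them; the coordinate
oracle walks the exon chain base by base.
"""

from fractions import Fraction
from math import comb

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "X", "TAG": "X",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "X", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration in rational arithmetic."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(row2, col1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return total


def walk_exon_chain(exons, strand):
    """Exonic genomic positions in transcript (5'->3') orientation."""
    order = []
    for s, e in exons:
        order.extend(range(s, e + 1))
    return order[::-1] if strand == "-" else order


def spliced_cds(genome_seq, exons, strand, cds_start, cds_end):
    """Transcript-orientation CDS string, rebuilt base by base."""
    lo, hi = sorted((cds_start, cds_end))
    order = [p for p in walk_exon_chain(exons, strand) if lo <= p <= hi]
    bases = [genome_seq[p - 1] for p in order]
    if strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
    return "".join(bases)


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds) - 2, 3))


def consequence_by_diff(genome_seq, exons, strand, cds_start, cds_end,
                        pos, ref, alt):
    """Consequence class of a plus-strand substitution by whole-protein diff.

    Returns one of synonymous / missense / stopgain / stoploss, or None when
    the position is not a coding base.
    """
    lo, hi = sorted((cds_start, cds_end))
    order = [p for p in walk_exon_chain(exons, strand) if lo <= p <= hi]
    if pos not in order:
        return None
    assert genome_seq[pos - 1] == ref
    mutated = genome_seq[:pos - 1] + alt + genome_seq[pos:]
    before = translate(spliced_cds(genome_seq, exons, strand, cds_start, cds_end))
    after = translate(spliced_cds(mutated, exons, strand, cds_start, cds_end))
    i = order.index(pos) // 3
    aa_ref, aa_alt = before[i], after[i]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "X":
        return "stopgain"
    if aa_ref == "X":
        return "stoploss"
    return "missense"
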