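"""Reference sequence access and strand-aware transcript coordinate arithmetic.

A :class:`TranscriptModel` describes one transcript per gene as an ordered set
of 1-based closed exon intervals on a contig, plus the genomic CDS boundaries.
All public coordinates are 1-based; external half-open formats (BED12) are
converted at the reader boundary.  For minus-strand transcripts, increasing
genomic position corresponds to decreasing coding (c.) position, and codons
are read off the reverse complement of the plus-strand genomic sequence.

Intron offsets follow HGVS convention: ``c.N+k`` counts k bases into the
intron after coding base N (transcript orientation), ``c.N-k`` counts k bases
before coding base N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

#: Region labels used by :class:`CdsCoordinate`.
CDS, UTR5, UTR3, INTRON = "CDS", "UTR5", "UTR3", "intron"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Genome:
    """In-memory reference: contig name -> uppercase A/C/G/T/N string."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty contig name")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name}: invalid bases {sorted(bad)}")

    def base(self, contig: str, pos: int) -> str:
        """1-based single-base access."""
        seq = self.sequences[contig]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} off contig {contig} (len {len(seq)})")
        return seq[pos - 1]


@dataclass(frozen=True)
class CdsCoordinate:
    """A transcript-orientation coordinate.

    ``cds_pos`` is 1-based within the region: coding bases count 1..CDS-length,
    5' UTR bases count backwards from the CDS start (c.-k -> cds_pos=k), and
    3' UTR bases count forwards from the stop (c.*k -> cds_pos=k).  Intronic
    positions anchor to the nearest exonic coding base and carry a signed
    ``intron_offset`` in transcript orientation.
    """

    cds_pos: int
    intron_offset: int
    region: str

    def __post_init__(self) -> None:
        if (self.intron_offset == 0) != (self.region != INTRON):
            raise ValueError("intron_offset must be nonzero iff region is intron")

    def hgvs_position(self) -> str:
        if self.region == CDS:
            return str(self.cds_pos)
        if self.region == UTR5:
            return f"-{self.cds_pos}"
        if self.region == UTR3:
            return f"*{self.cds_pos}"
        sign = "+" if self.intron_offset > 0 else "-"
        return f"{self.cds_pos}{sign}{abs(self.intron_offset)}"


@dataclass
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based closed, sorted by genomic start
    cds_start_genomic: int
    cds_end_genomic: int

    # lazily built lookup caches
    _g2t: dict[int, CdsCoordinate] = field(default_factory=dict, repr=False)
    _cds2g: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-" or len(self.strand) != 1:
            raise ValueError(f"bad strand {self.strand!r}")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be sorted by genomic start")
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or touch")
        for s, e in self.exons:
            if s > e:
                raise ValueError("empty exon")
        if self.cds_start_genomic > self.cds_end_genomic:
            raise ValueError("cds_start_genomic > cds_end_genomic")
        for p in (self.cds_start_genomic, self.cds_end_genomic):
            if not any(s <= p <= e for s, e in self.exons):
                raise ValueError(f"CDS boundary {p} not inside an exon")
        if self.cds_length % 3 != 0 or self.cds_length < 6:
            raise ValueError(f"CDS length {self.cds_length} not a multiple of 3 >= 6")
        self._build_maps()

    # -- derived structure ------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exonic_positions_transcript_order(self) -> list[int]:
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos

    @property
    def cds_length(self) -> int:
        lo, hi = sorted((self.cds_start_genomic, self.cds_end_genomic))
        return sum(max(0, min(e, hi) - max(s, lo) + 1) for s, e in self.exons)

    def _build_maps(self) -> None:
        lo, hi = sorted((self.cds_start_genomic, self.cds_end_genomic))
        order = self.exonic_positions_transcript_order()
        coding = [p for p in order if lo <= p <= hi]
        utr5 = [p for p in order if self._is_before_cds(p, lo, hi)]
        utr3 = [p for p in order if self._is_after_cds(p, lo, hi)]
        for k, p in enumerate(reversed(utr5), start=1):
            self._g2t[p] = CdsCoordinate(k, 0, UTR5)
        for k, p in enumerate(coding, start=1):
            self._g2t[p] = CdsCoordinate(k, 0, CDS)
            self._cds2g[k] = p
        for k, p in enumerate(utr3, start=1):
            self._g2t[p] = CdsCoordinate(k, 0, UTR3)

    def _is_before_cds(self, p: int, lo: int, hi: int) -> bool:
        """True if exonic p lies 5' of the CDS in transcript orientation."""
        return p < lo if self.strand == "+" else p > hi

    def _is_after_cds(self, p: int, lo: int, hi: int) -> bool:
        return p > hi if self.strand == "+" else p < lo


def genomic_to_cds(pos: int, tm: TranscriptModel) -> CdsCoordinate | None:
    """Map a 1-based genomic position to a transcript-orientation coordinate.

    Returns ``None`` when ``pos`` lies outside the transcript span (the
    out-of-transcript signal).  Intronic positions are anchored to the nearest
    exonic base in genomic distance, with an HGVS-style signed offset in
    transcript orientation; ties (equidistant) anchor to the 5' exon.
    """
    lo, hi = tm.span
    if not lo <= pos <= hi:
        return None
    hit = tm._g2t.get(pos)
    if hit is not None:
        return hit
    # intronic: find flanking exonic neighbours by genomic distance
    prev_end = max(e for _, e in tm.exons if e < pos)
    next_start = min(s for s, _ in tm.exons if s > pos)
    d_prev, d_next = pos - prev_end, next_start - pos
    if tm.strand == "+":
        anchor, off = (prev_end, d_prev) if d_prev <= d_next else (next_start, -d_next)
    else:
        # transcript runs right-to-left: upstream exon is the one at higher coords
        anchor, off = (next_start, d_next) if d_next <= d_prev else (prev_end, -d_prev)
    a = tm._g2t[anchor]
    return CdsCoordinate(a.cds_pos, off, INTRON)


def cds_to_genomic(c: CdsCoordinate, tm: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cds` for exonic CDS coordinates."""
    if c.region != CDS or c.intron_offset != 0:
        raise ValueError("cds_to_genomic accepts exonic CDS coordinates only")
    if not 1 <= c.cds_pos <= tm.cds_length:
        raise ValueError(f"cds_pos {c.cds_pos} outside 1..{tm.cds_length}")
    return tm._cds2g[c.cds_pos]


def cds_sequence(tm: TranscriptModel, g: Genome) -> str:
    """The spliced CDS in transcript orientation (reverse-complemented for -)."""
    contig = g.sequences[tm.contig]
    bases = [contig[tm._cds2g[k] - 1] for k in range(1, tm.cds_length + 1)]
    if tm.strand == "-":
        return "".join(revcomp(b) for b in bases)
    return "".join(bases)


def codon_at(cds_pos: int, tm: TranscriptModel, g: Genome) -> tuple[str, int]:
    """Return the codon containing CDS base ``cds_pos`` and its frame index."""
    if not 1 <= cds_pos <= tm.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside CDS")
    frame = (cds_pos - 1) % 3
    start = cds_pos - frame
    codon = ""
    for k in range(start, start + 3):
        gpos = tm._cds2g.get(k)
        if gpos is None:
            raise ValueError(f"codon spans missing CDS base {k}")
        b = g.base(tm.contig, gpos)
        codon += revcomp(b) if tm.strand == "-" else b
    return codon, frame


def context(pos: int, g: Genome, contig: str, flank: int = 1) -> str:
    """Plus-strand window of ``2*flank+1`` bases centred on ``pos``, clipped."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = g.sequences[contig]
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} off contig {contig}")
    return seq[max(0, pos - 1 - flank): pos + flank]


# ---------------------------------------------------------------------------
# readers

def read_fasta(path: str | Path) -> Genome:
    """Load a (possibly wrapped, multi-contig) FASTA into a :class:`Genome`."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_SPEC_COLUMNS = ["gene", "transcript_id", "contig", "strand",
                 "exon_starts", "exon_ends", "cds_start", "cds_end"]


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read the tab-delimited transcript spec (1-based closed coordinates)."""
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SPEC_COLUMNS:
            raise ValueError(f"bad transcript header {header}")
        for line in fh:
            if not line.strip():
                continue
            gene, tid, contig, strand, starts, ends, cs, ce = line.rstrip("\n").split("\t")
            exons = list(zip((int(x) for x in starts.split(",") if x),
                             (int(x) for x in ends.split(",") if x)))
            models.append(TranscriptModel(gene, tid, contig, strand, exons,
                                          int(cs), int(ce)))
    return models


def write_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SPEC_COLUMNS) + "\n")
        for tm in models:
            fh.write("\t".join([
                tm.gene_symbol, tm.transcript_id, tm.contig, tm.strand,
                ",".join(str(s) for s, _ in tm.exons),
                ",".join(str(e) for _, e in tm.exons),
                str(tm.cds_start_genomic), str(tm.cds_end_genomic)]) + "\n")


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 (0-based half-open) transcript records, converting to the
    1-based closed internal model.  thickStart/thickEnd give the CDS."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            contig, chrom_start, _, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n or len(offsets) != n:
                raise ValueError(f"BED12 block count mismatch in {name}")
            exons = [(chrom_start + o + 1, chrom_start + o + s)
                     for o, s in zip(offsets, sizes)]
            models.append(TranscriptModel(name, name, contig, strand, exons,
                                          thick_start + 1, thick_end))
    return models
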