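"""Consequence, substitution-class, UV-context and novelty annotation.

Each single-base call is mapped through the transcript model to an HGVS c.
coordinate, the affected codon is translated before and after substitution,
and a consequence class is assigned (synonymous / missense / stopgain /
stoploss / splice / UTR / intronic / intergenic).  Context flags classify the
change as transition or transversion and test the UV-mutagenesis signature:
a C>T change on the pyrimidine-carrying strand at a di-pyrimidine site (the
substrate of cyclobutane pyrimidine dimers).  Novelty is an exact
(contig, pos, ref, alt) lookup against local variant catalogs.

Stop codons are written ``X`` in protein notation, matching the dialect of
the published variant tables this package re-tallies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .calling import VariantCall
from .refmodel import (CDS, INTRON, UTR3, UTR5, CdsCoordinate, Genome,
                       TranscriptModel, codon_at, genomic_to_cds, revcomp)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

TRANSITION, TRANSVERSION = "transition", "transversion"
NOVEL, REFERENCE = "novel", "reference"

SYNONYMOUS, MISSENSE, STOPGAIN, STOPLOSS = "synonymous", "missense", "stopgain", "stoploss"
SPLICE, INTRONIC, INTERGENIC = "splice", "intronic", "intergenic"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Single-letter amino acid under the standard nuclear code; stop -> X."""
    if codon in _STANDARD_TABLE.stop_codons:
        return "X"
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class Consequence:
    klass: str
    hgvs_c: str
    hgvs_p: str = ""
    aa_ref: str = ""
    aa_alt: str = ""
    cds_pos: int = 0
    coding_ref: str = ""
    coding_alt: str = ""


@dataclass(frozen=True)
class ContextFlags:
    substitution_class: str
    dipyrimidine: bool
    uv_signature: bool
    pyrimidine_strand: str
    ambiguous_context: bool = False  # an adjacent N disqualified the flags

    def __post_init__(self) -> None:
        if self.uv_signature and not self.dipyrimidine:
            raise ValueError("uv_signature requires dipyrimidine")


@dataclass(frozen=True)
class CatalogRecord:
    contig: str
    pos: int
    ref: str
    alt: str
    ids: tuple[str, ...]
    source: str = ""
    population_af: float | None = None


@dataclass
class AnnotatedVariant:
    call: VariantCall
    consequence: Consequence
    flags: ContextFlags | None = None
    novelty: str = NOVEL
    catalog_ids: tuple[str, ...] = ()
    damage_label: str | None = None
    dipyrimidine_override: bool | None = None  # externally supplied flag

    @property
    def dipyrimidine(self) -> bool:
        if self.dipyrimidine_override is not None:
            return self.dipyrimidine_override
        return bool(self.flags and self.flags.dipyrimidine)


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT alleles {ref!r}>{alt!r}")
    same_class = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


def annotate_variant(v: VariantCall, tm: TranscriptModel, g: Genome,
                     splice_window: int = 2) -> Consequence:
    """Assign a consequence class and HGVS c./p. names to a substitution.

    Alleles on ``v`` are plus-strand; for minus-strand transcripts the coding
    alleles are their complements.  Intronic positions within
    ``splice_window`` bases of an exon boundary are classed splice.
    """
    if v.contig != tm.contig:
        return Consequence(INTERGENIC, "")
    coord = genomic_to_cds(v.pos, tm)
    if coord is None:
        return Consequence(INTERGENIC, "")
    ref_c = revcomp(v.ref_base) if tm.strand == "-" else v.ref_base
    alt_c = revcomp(v.alt_base) if tm.strand == "-" else v.alt_base
    change = f"{ref_c}>{alt_c}"
    hgvs_c = f"c.{coord.hgvs_position()}{change}"
    if coord.region == INTRON:
        klass = SPLICE if abs(coord.intron_offset) <= splice_window else INTRONIC
        return Consequence(klass, hgvs_c, cds_pos=coord.cds_pos,
                           coding_ref=ref_c, coding_alt=alt_c)
    if coord.region == UTR5:
        return Consequence(UTR5, hgvs_c, coding_ref=ref_c, coding_alt=alt_c)
    if coord.region == UTR3:
        return Consequence(UTR3, hgvs_c, coding_ref=ref_c, coding_alt=alt_c)
    codon, frame = codon_at(coord.cds_pos, tm, g)
    if codon[frame] != ref_c:
        raise ValueError(f"reference mismatch at c.{coord.cds_pos}: "
                         f"codon has {codon[frame]}, call has {ref_c}")
    alt_codon = codon[:frame] + alt_c + codon[frame + 1:]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(alt_codon)
    aa_num = (coord.cds_pos - 1) // 3 + 1
    if aa_ref == aa_alt:
        klass = SYNONYMOUS
    elif aa_alt == "X":
        klass = STOPGAIN
    elif aa_ref == "X":
        klass = STOPLOSS
    else:
        klass = MISSENSE
    hgvs_p = f"p.{aa_ref}{aa_num}{aa_alt}"
    return Consequence(klass, hgvs_c, hgvs_p, aa_ref, aa_alt,
                       cds_pos=coord.cds_pos, coding_ref=ref_c, coding_alt=alt_c)


# -- HGVS parsing (dialect of the published tables) -------------------------

_C_REF_FIRST = re.compile(r"^c\.([ACGT])(\d+)([ACGT])$")          # c.G2740T
_C_ARROW = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")             # c.2162G>A
_C_SPLICE = re.compile(r"^c\.(\d+)([+\-−])(\d+)([ACGT])>([ACGT])$")  # c.1682+1G>A
_C_UTR3 = re.compile(r"^c\.\*(\d+)([ACGT])>([ACGT])$")            # c.*20C>T
_C_UTR5 = re.compile(r"^c\.-(\d+)([ACGT])>([ACGT])$")             # c.-12G>A
_P = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


class HgvsParseError(ValueError):
    pass


def parse_hgvs(hgvs_c: str, hgvs_p: str = "") -> Consequence:
    """Parse printed HGVS c./p. strings into a consequence record.

    Class is derived as in the tables: equal amino acids -> synonymous,
    alt amino acid X -> stopgain, an intron offset -> splice, ``c.*``/``c.-``
    -> UTR3/UTR5, otherwise missense.
    """
    hgvs_c = hgvs_c.replace(" ", "")
    aa_ref = aa_alt = ""
    aa_num = 0
    if hgvs_p:
        mp = _P.match(hgvs_p.replace(" ", ""))
        if not mp:
            raise HgvsParseError(f"unparseable protein change {hgvs_p!r}")
        aa_ref, aa_num, aa_alt = mp.group(1), int(mp.group(2)), mp.group(3)

    if m := _C_SPLICE.match(hgvs_c):
        pos, sign, off, ref, alt = m.groups()
        return Consequence(SPLICE, hgvs_c, cds_pos=int(pos),
                           coding_ref=ref, coding_alt=alt)
    if m := _C_UTR3.match(hgvs_c):
        return Consequence(UTR3, hgvs_c, cds_pos=int(m.group(1)),
                           coding_ref=m.group(2), coding_alt=m.group(3))
    if m := _C_UTR5.match(hgvs_c):
        return Consequence(UTR5, hgvs_c, cds_pos=int(m.group(1)),
                           coding_ref=m.group(2), coding_alt=m.group(3))
    if m := _C_REF_FIRST.match(hgvs_c):
        ref, pos, alt = m.groups()
    elif m := _C_ARROW.match(hgvs_c):
        pos, ref, alt = m.groups()
    else:
        raise HgvsParseError(f"unparseable coding change {hgvs_c!r}")
    if aa_ref and aa_alt:
        if aa_ref == aa_alt:
            klass = SYNONYMOUS
        elif aa_alt == "X":
            klass = STOPGAIN
        elif aa_ref == "X":
            klass = STOPLOSS
        else:
            klass = MISSENSE
    else:
        klass = MISSENSE
    return Consequence(klass, f"c.{pos}{ref}>{alt}",
                       hgvs_p if aa_ref else "", aa_ref, aa_alt,
                       cds_pos=int(pos), coding_ref=ref, coding_alt=alt)


def dipyrimidine_flags(v: VariantCall, g: Genome) -> ContextFlags:
    """UV-signature context of a plus-strand substitution.

    The pyrimidine strand is the strand whose reference base at the site is C
    or T.  The site is di-pyrimidine when either immediately adjacent base on
    that strand is also a pyrimidine; the UV signature additionally requires
    the pyrimidine-strand change to be C>T.  An adjacent N disqualifies the
    flags (conservative).
    """
    sub = classify_substitution(v.ref_base, v.alt_base)
    seq = g.sequences[v.contig]
    left = seq[v.pos - 2] if v.pos >= 2 else ""
    right = seq[v.pos] if v.pos < len(seq) else ""
    if v.ref_base in PYRIMIDINES:
        strand, ref_s, alt_s = "+", v.ref_base, v.alt_base
        neighbours = [b for b in (left, right) if b]
    else:
        strand, ref_s, alt_s = "-", revcomp(v.ref_base), revcomp(v.alt_base)
        neighbours = [revcomp(b) for b in (left, right) if b]
    ambiguous = "N" in neighbours
    dipy = any(b in PYRIMIDINES for b in neighbours)
    uv = dipy and ref_s == "C" and alt_s == "T"
    return ContextFlags(sub, dipy, uv, strand, ambiguous_context=ambiguous)


def lookup_novelty(v: VariantCall, catalogs: Sequence[Sequence[CatalogRecord]],
                   ) -> tuple[str, tuple[str, ...]]:
    """Exact-allele catalog lookup: reference iff any catalog matches."""
    ids: list[str] = []
    for catalog in catalogs:
        for rec in catalog:
            if (rec.contig, rec.pos, rec.ref, rec.alt) == v.key:
                for i in rec.ids:
                    tag = f"{rec.source}:{i}" if rec.source else i
                    if tag not in ids:
                        ids.append(tag)
    return (REFERENCE, tuple(ids)) if ids else (NOVEL, ())


DAMAGING_LABELS = frozenset({"damaging", "probably_damaging"})


def is_damaging(labels: Iterable[str]) -> bool:
    """Aggregate predictor verdicts: damaging iff any predictor says so."""
    return any(l in DAMAGING_LABELS for l in labels)


def annotate_panel(calls: Sequence[VariantCall], tm: TranscriptModel, g: Genome,
                   catalogs: Sequence[Sequence[CatalogRecord]] = (),
                   damage_labels: dict[tuple, list[str]] | None = None,
                   splice_window: int = 2) -> list[AnnotatedVariant]:
    """Full annotation of a list of calls against one transcript model."""
    out = []
    for c in calls:
        cons = annotate_variant(c, tm, g, splice_window=splice_window)
        flags = dipyrimidine_flags(c, g)
        novelty, ids = lookup_novelty(c, catalogs)
        dmg = None
        if damage_labels and c.key in damage_labels:
            dmg = "damaging" if is_damaging(damage_labels[c.key]) else "tolerated"
        out.append(AnnotatedVariant(c, cons, flags, novelty, ids, dmg))
    return out


# ---------------------------------------------------------------------------
# readers / writers

def read_catalog(path: str | Path) -> list[CatalogRecord]:
    """Catalog TSV: contig, pos, ref, alt, id, source[, af]."""
    recs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["contig", "pos", "ref", "alt", "id", "source"]:
            raise ValueError(f"bad catalog header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            af = float(f[6]) if len(f) > 6 and f[6] else None
            recs.append(CatalogRecord(f[0], int(f[1]), f[2], f[3],
                                      tuple(f[4].split(";")), f[5], af))
    return recs


def write_catalog(recs: Iterable[CatalogRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tid\tsource\taf\n")
        for r in recs:
            af = "" if r.population_af is None else f"{r.population_af:g}"
            fh.write(f"{r.contig}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                     f"{';'.join(r.ids)}\t{r.source}\t{af}\n")


def read_damage_labels(path: str | Path) -> dict[tuple, list[str]]:
    """Damage-label TSV: contig, pos, ref, alt, predictor, label[, score]."""
    out: dict[tuple, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["contig", "pos", "ref", "alt", "predictor", "label"]:
            raise ValueError(f"bad damage-label header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.setdefault((f[0], int(f[1]), f[2], f[3]), []).append(f[5])
    return out


def write_annotated_tsv(annotated: Iterable[AnnotatedVariant], path: str | Path) -> None:
    cols = ["contig", "pos", "ref", "alt", "klass", "hgvs_c", "hgvs_p",
            "substitution", "dipyrimidine", "uv_signature", "novelty",
            "catalog_ids", "damage", "depth", "vaf_percent", "pair_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotated:
            c = a.call
            fh.write("\t".join([
                c.contig, str(c.pos), c.ref_base, c.alt_base,
                a.consequence.klass, a.consequence.hgvs_c, a.consequence.hgvs_p,
                a.flags.substitution_class if a.flags else "",
                str(int(a.dipyrimidine)),
                str(int(a.flags.uv_signature)) if a.flags else "",
                a.novelty, ";".join(a.catalog_ids), a.damage_label or "",
                str(c.depth), f"{c.vaf_percent:.4f}", c.pair_id]) + "\n")
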