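"""Germ-line and somatic SNV designation from per-site allele-count tables.

The designation logic follows the count-level rules of a paired-tissue deep
sequencing design: variant allele frequency (VAF) is variant reads over total
reads at the site, as a percentage.  Alleles at VAF >= 20% in a single-sample
(case-control) panel are designated germ-line.  In a paired-lens panel, an
allele "present" (VAF above a low floor with minimum read support) in exactly
one lens of a pair is designated somatic; present in both lenses, germ-line.
Somatic calls are then filtered: VAF < 3% or depth < 600 reads are flagged as
likely sequencing error, and variants recurring across pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

ALT_BASES = ("A", "C", "G", "T")

# designation labels
GERMLINE, SOMATIC, AMBIGUOUS, ABSENT = "germline", "somatic", "ambiguous", "absent"
# filter labels
PASS, LOW_VAF, LOW_DEPTH, RECURRENT = "PASS", "LOW_VAF", "LOW_DEPTH", "RECURRENT"


@dataclass(frozen=True)
class PileupSite:
    """Per-sample, per-position depth and A/C/G/T allele counts."""

    sample_id: str
    contig: str
    pos: int
    ref_base: str
    depth: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in ALT_BASES:
            raise ValueError(f"bad ref base {self.ref_base!r}")
        if self.depth < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("negative depth or count")
        if sum(self.counts.values()) > self.depth:
            raise ValueError("allele counts exceed depth")

    def vaf_percent(self, base: str) -> float:
        return compute_vaf(self.counts.get(base, 0), self.depth)


@dataclass
class VariantCall:
    contig: str
    pos: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    vaf_percent: float
    origin: str
    sample_id: str = ""
    pair_id: str = ""
    genotype: str = ""  # het / hom for germ-line calls
    filter_status: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity (contig, pos, ref, alt)."""
        return (self.contig, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the designation pipeline (percent scales, read counts).

    Defaults are the published pipeline's operating point: 1% presence floor
    for paired discordance, 20% germ-line designation, somatic retention at
    VAF >= 3% and depth >= 600 reads.
    """

    presence_vaf_percent: float = 1.0
    germline_vaf_percent: float = 20.0
    somatic_min_vaf_percent: float = 3.0
    min_depth: int = 600
    het_range_percent: tuple[float, float] = (20.0, 80.0)
    min_alt_reads: int = 4
    somatic_fisher_alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.presence_vaf_percent < self.somatic_min_vaf_percent
                <= self.germline_vaf_percent <= 100):
            raise ValueError("thresholds must satisfy 0 < presence < somatic_min "
                             "<= germline <= 100")
        if self.min_depth < 0 or self.min_alt_reads < 0:
            raise ValueError("negative read thresholds")


@dataclass(frozen=True)
class LensPair:
    pair_id: str
    left_sample: str
    right_sample: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.left_sample == self.right_sample:
            raise ValueError("left and right samples must differ")


class UndefinedVAFError(ZeroDivisionError):
    """VAF is undefined at zero depth."""


def compute_vaf(alt_count: int, depth: int) -> float:
    """VAF percent: 100 * variant reads / total reads at the site."""
    if depth == 0:
        raise UndefinedVAFError("depth is zero")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count outside [0, depth]")
    return 100.0 * alt_count / depth


def call_germline(site: PileupSite, cfg: CallConfig = CallConfig()) -> list[VariantCall]:
    """One germ-line call per non-reference allele with VAF >= the 20% rule."""
    calls = []
    if site.depth == 0:
        return calls
    lo, hi = cfg.het_range_percent
    for base in ALT_BASES:
        if base == site.ref_base:
            continue
        vaf = site.vaf_percent(base)
        if vaf >= cfg.germline_vaf_percent:
            gt = "het" if lo <= vaf <= hi else "hom"
            calls.append(VariantCall(site.contig, site.pos, site.ref_base, base,
                                     site.counts.get(base, 0), site.depth, vaf,
                                     GERMLINE, sample_id=site.sample_id,
                                     genotype=gt))
    calls.sort(key=lambda c: c.key)
    return calls


def _present(site: PileupSite, base: str, cfg: CallConfig) -> bool:
    if site.depth == 0:
        return False
    return (site.vaf_percent(base) >= cfg.presence_vaf_percent
            and site.counts.get(base, 0) >= cfg.min_alt_reads)


def call_paired_discordant(left: PileupSite, right: PileupSite,
                           cfg: CallConfig = CallConfig(),
                           pair_id: str = "") -> list[VariantCall]:
    """Designate each alt allele at a paired site.

    Present in exactly one lens -> somatic (carrying that lens's VAF/depth);
    present in both -> germ-line; in neither -> no call emitted.  With
    ``somatic_fisher_alpha`` set, a somatic designation additionally requires
    the two-sided exact test on the two lenses' alt/ref counts to reject.
    """
    if (left.contig, left.pos, left.ref_base) != (right.contig, right.pos, right.ref_base):
        raise ValueError("paired sites must share contig/pos/ref")
    calls = []
    for base in ALT_BASES:
        if base == left.ref_base:
            continue
        in_l, in_r = _present(left, base, cfg), _present(right, base, cfg)
        if not in_l and not in_r:
            continue
        if in_l and in_r:
            carrier = left if left.vaf_percent(base) >= right.vaf_percent(base) else right
            calls.append(VariantCall(left.contig, left.pos, left.ref_base, base,
                                     carrier.counts.get(base, 0), carrier.depth,
                                     carrier.vaf_percent(base), GERMLINE,
                                     sample_id=carrier.sample_id, pair_id=pair_id))
            continue
        carrier = left if in_l else right
        origin = SOMATIC
        if cfg.somatic_fisher_alpha is not None:
            from .stats import ContingencyTable2x2, fisher_exact_2x2

            alt_l = left.counts.get(base, 0)
            alt_r = right.counts.get(base, 0)
            table = ContingencyTable2x2(alt_l, left.depth - alt_l,
                                        alt_r, right.depth - alt_r)
            if fisher_exact_2x2(table) >= cfg.somatic_fisher_alpha:
                origin = AMBIGUOUS
        calls.append(VariantCall(left.contig, left.pos, left.ref_base, base,
                                 carrier.counts.get(base, 0), carrier.depth,
                                 carrier.vaf_percent(base), origin,
                                 sample_id=carrier.sample_id, pair_id=pair_id))
    calls.sort(key=lambda c: c.key)
    return calls


def apply_somatic_filters(calls: Sequence[VariantCall],
                          cfg: CallConfig = CallConfig()) -> list[VariantCall]:
    """Flag somatic calls below the VAF floor or the read-depth floor.

    PASS iff VAF >= somatic_min_vaf_percent and depth >= min_depth (both
    boundaries inclusive: the excluded region is strictly below each floor).
    Input order is preserved.
    """
    out = []
    for c in calls:
        if c.origin != SOMATIC:
            raise ValueError("apply_somatic_filters expects somatic calls")
        flags = set()
        if c.vaf_percent < cfg.somatic_min_vaf_percent:
            flags.add(LOW_VAF)
        if c.depth < cfg.min_depth:
            flags.add(LOW_DEPTH)
        out.append(replace(c, filter_status=frozenset(flags or {PASS})))
    return out


def exclude_recurrent(calls: Sequence[VariantCall]) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split PASS somatic calls into singly occurring and recurrent sets.

    A variant identity seen in more than one pair is recurrent; every one of
    its occurrences is excluded.  Repeats within one pair count once.
    """
    pairs_by_key: dict[tuple, set[str]] = {}
    for c in calls:
        pairs_by_key.setdefault(c.key, set()).add(c.pair_id)
    retained, excluded = [], []
    for c in calls:
        (excluded if len(pairs_by_key[c.key]) > 1 else retained).append(c)
    retained.sort(key=lambda c: (c.key, c.pair_id))
    excluded.sort(key=lambda c: (c.key, c.pair_id))
    return retained, excluded


def summarize_coverage(sites: Sequence[PileupSite], threshold: int) -> float:
    """Fraction of sites with depth >= threshold."""
    if not sites:
        raise ValueError("no sites")
    return sum(1 for s in sites if s.depth >= threshold) / len(sites)


# ---------------------------------------------------------------------------
# readers / writers

_PILEUP_COLUMNS = ["sample_id", "contig", "pos", "ref", "depth",
                   "count_A", "count_C", "count_G", "count_T"]


def read_pileups(path: str | Path) -> list[PileupSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PILEUP_COLUMNS:
            raise ValueError(f"bad pileup header {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{i}: expected 9 columns, got {len(f)}")
            sites.append(PileupSite(f[0], f[1], int(f[2]), f[3], int(f[4]),
                                    {b: int(x) for b, x in zip(ALT_BASES, f[5:9])}))
    return sites


def write_pileups(sites: Iterable[PileupSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PILEUP_COLUMNS) + "\n")
        for s in sites:
            fh.write("\t".join([s.sample_id, s.contig, str(s.pos), s.ref_base,
                                str(s.depth)] +
                               [str(s.counts.get(b, 0)) for b in ALT_BASES]) + "\n")


def read_pairs(path: str | Path) -> list[LensPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["pair_id", "left_sample", "right_sample", "phenotype"]:
            raise ValueError(f"bad pair manifest header {header}")
        for line in fh:
            if line.strip():
                pairs.append(LensPair(*line.rstrip("\n").split("\t")))
    return pairs


def write_pairs(pairs: Iterable[LensPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tleft_sample\tright_sample\tphenotype\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.left_sample}\t{p.right_sample}\t{p.phenotype}\n")


def group_sites(sites: Iterable[PileupSite]) -> dict[str, dict[tuple[str, int], PileupSite]]:
    """Index pileup sites as sample_id -> (contig, pos) -> site."""
    out: dict[str, dict[tuple[str, int], PileupSite]] = {}
    for s in sites:
        out.setdefault(s.sample_id, {})[(s.contig, s.pos)] = s
    return out


def call_panel_somatic(sites: Sequence[PileupSite], pairs: Sequence[LensPair],
                       cfg: CallConfig = CallConfig()) -> list[VariantCall]:
    """Run paired discordance over a whole panel, one pass per lens pair.

    Sites present for only one lens of a pair are skipped (no paired evidence).
    """
    by_sample = group_sites(sites)
    calls: list[VariantCall] = []
    for pair in pairs:
        lefts = by_sample.get(pair.left_sample, {})
        rights = by_sample.get(pair.right_sample, {})
        for key in sorted(set(lefts) & set(rights)):
            calls.extend(call_paired_discordant(lefts[key], rights[key], cfg,
                                                pair_id=pair.pair_id))
    return calls


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    cols = ["contig", "pos", "ref", "alt", "alt_count", "depth", "vaf_percent",
            "origin", "sample_id", "pair_id", "genotype", "filter"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            fh.write("\t".join([c.contig, str(c.pos), c.ref_base, c.alt_base,
                                str(c.alt_count), str(c.depth),
                                f"{c.vaf_percent:.4f}", c.origin, c.sample_id,
                                c.pair_id, c.genotype,
                                ";".join(sorted(c.filter_status)) or "."]) + "\n")


def write_calls_vcf(calls: Iterable[VariantCall], path: str | Path,
                    source: str = "lenscall") -> None:
    """Write calls as minimal VCF 4.2 (one record per call; ORIGIN/VAF/DP INFO)."""
    header = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Designation: germline, somatic, ambiguous">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency, percent">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth in the carrier sample">',
        '##INFO=<ID=PAIR,Number=1,Type=String,Description="Lens pair id">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample id">',
        '##FILTER=<ID=LOW_VAF,Description="VAF below the somatic retention floor">',
        '##FILTER=<ID=LOW_DEPTH,Description="Depth below the somatic retention floor">',
        '##FILTER=<ID=RECURRENT,Description="Variant identity recurs across pairs">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt_base)):
            filt = ";".join(sorted(c.filter_status)) if c.filter_status else "."
            info = (f"ORIGIN={c.origin};VAF={c.vaf_percent:.4f};DP={c.depth}"
                    + (f";PAIR={c.pair_id}" if c.pair_id else "")
                    + (f";SAMPLE={c.sample_id}" if c.sample_id else ""))
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref_base}\t{c.alt_base}\t.\t"
                     f"{filt}\t{info}\n")
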