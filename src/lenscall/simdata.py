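"""Synthetic paired-lens amplicon data with known truth.

The generator emulates the statistical structure the designation pipeline
assumes: a random mini-genome carrying one multi-exon minus-strand transcript
(the study genes are both on the reverse strand), shared germ-line
heterozygous variants with per-lens VAF spread around 50%, single-lens
somatic variants at low VAF (3-13% by default) with a configurable fraction
forced to be pyrimidine-strand C>T changes at di-pyrimidine sites (the UV
signature), lognormal per-site read depths with a heavy right tail, and a
symmetric per-base miscall rate.  Every random draw flows from one seeded
generator, and every injected variant is recorded in a truth set for
parameter-recovery testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import dipyrimidine_flags
from .calling import ALT_BASES, LensPair, PileupSite, VariantCall
from .refmodel import Genome, TranscriptModel, revcomp

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic paired-lens panel.

    Depths follow a lognormal with median ~3000x (printed depths in the
    emulated study span roughly 600-8000x); germ-line het VAFs spread around
    50% with SD 5 points truncated to [20, 80]; somatic VAFs are uniform on
    [3, 13] percent; the per-base miscall rate is 0.1%.
    """

    seed: int = 0
    genome_length: int = 10_000
    gc_fraction: float = 0.45
    n_exons: int = 3
    codons_per_exon: int = 30
    utr_length: int = 30
    n_pairs: int = 20
    n_individuals: int = 225
    depth_log_mean: float = math.log(3000.0)
    depth_log_sd: float = 0.5
    error_rate: float = 0.001
    germline_maf_spectrum: tuple[float, ...] = (0.35, 0.05, 0.01, 0.005)
    n_germline_sites: int = 8
    het_vaf_sd: float = 5.0
    somatic_vaf_range: tuple[float, float] = (3.0, 13.0)
    somatic_per_pair_rate: float = 3.0
    uv_fraction: float = 0.7
    n_background_sites: int = 40
    strand: str = "-"

    def __post_init__(self) -> None:
        if not 0 <= self.gc_fraction <= 1 or not 0 <= self.error_rate <= 1 \
                or not 0 <= self.uv_fraction <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.somatic_vaf_range
        if not 0 < lo <= hi < 100:
            raise ValueError("somatic_vaf_range must lie inside (0, 100)")
        if any(not 0 <= f <= 1 for f in self.germline_maf_spectrum):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.genome_length < 300:
            raise ValueError("genome_length must be >= 300")


@dataclass
class TruthVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    true_vaf: float
    uv_signature: bool = False


@dataclass
class TruthSet:
    germline: list[dict] = field(default_factory=list)  # pair, variant, genotype
    somatic: list[dict] = field(default_factory=list)   # pair, side, variant, vaf

    def somatic_keys(self) -> set[tuple]:
        return {(s["pair_id"], s["contig"], s["pos"], s["ref"], s["alt"])
                for s in self.somatic}

    def germline_keys(self) -> set[tuple]:
        return {(g["pair_id"], g["contig"], g["pos"], g["ref"], g["alt"])
                for g in self.germline}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"germline": self.germline, "somatic": self.somatic},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["germline"], d["somatic"])


def _random_genome(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop, in transcript orientation."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in STOPS:
            codons.append(c)
    codons.append(rng.choice(sorted(STOPS)))
    return "".join(codons)


def make_reference(cfg: SimulationConfig) -> tuple[Genome, TranscriptModel]:
    """Random genome plus one valid multi-exon transcript (minus strand by
    default), with short UTRs inside the terminal exons."""
    rng = np.random.default_rng(cfg.seed)
    bases = _random_genome(rng, cfg.genome_length, cfg.gc_fraction)

    cds_len = 3 * cfg.codons_per_exon * cfg.n_exons
    tx_len = cds_len + 2 * cfg.utr_length
    # terminal exons carry the UTRs (which end is 5' depends on strand)
    per_exon = [3 * cfg.codons_per_exon] * cfg.n_exons
    per_exon[0] += cfg.utr_length
    per_exon[-1] += cfg.utr_length
    intron = 200
    span = sum(per_exon) + intron * (cfg.n_exons - 1)
    if span + 200 > cfg.genome_length:
        raise ValueError("genome too short for requested transcript")
    start = (cfg.genome_length - span) // 2
    exons = []
    g = start + 1
    for size in per_exon:
        exons.append((g, g + size - 1))
        g += size + intron

    # transcript-orientation sequence: UTR5 + CDS + UTR3
    tx_seq = ("".join(rng.choice(list("ACGT"), size=cfg.utr_length))
              + _random_cds(rng, cds_len // 3)
              + "".join(rng.choice(list("ACGT"), size=cfg.utr_length)))
    assert len(tx_seq) == tx_len == sum(per_exon)

    order = [p for s, e in exons for p in range(s, e + 1)]
    if cfg.strand == "-":
        order = order[::-1]
    for i, p in enumerate(order):
        b = tx_seq[i]
        bases[p - 1] = revcomp(b) if cfg.strand == "-" else b

    cds_positions = order[cfg.utr_length: cfg.utr_length + cds_len]
    genome = Genome({"chrS": "".join(bases)})
    tm = TranscriptModel("GENE1", "TX1", "chrS", cfg.strand, exons,
                         min(cds_positions), max(cds_positions))
    return genome, tm


def _uv_eligible_sites(genome: Genome, tm: TranscriptModel) -> list[tuple[int, str, str]]:
    """CDS sites where a pyrimidine-strand C>T lands at a di-pyrimidine site.

    Returns (genomic pos, plus-strand ref, plus-strand alt).
    """
    out = []
    for k in range(1, tm.cds_length + 1):
        pos = tm._cds2g[k]
        ref = genome.base(tm.contig, pos)
        if ref == "C":
            alt = "T"
        elif ref == "G":
            alt = "A"
        else:
            continue
        probe = VariantCall(tm.contig, pos, ref, alt, 0, 1, 0.0, "somatic")
        fl = dipyrimidine_flags(probe, genome)
        if fl.uv_signature:
            out.append((pos, ref, alt))
    return out


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def inject_and_pileup(cfg: SimulationConfig, genome: Genome, tm: TranscriptModel,
                      ) -> tuple[list[PileupSite], list[LensPair], TruthSet]:
    """Simulate per-lens pileups for every pair with injected variants.

    Germ-line variants are shared by both lenses of a pair (het VAF around
    50%, hom near 100%); somatic variants sit in exactly one lens at a VAF
    drawn uniformly from ``somatic_vaf_range``.  Allele counts are binomial
    at the true VAF, with symmetric miscalls at ``error_rate`` spread over
    the three non-reference bases.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    contig = tm.contig
    cds_sites = [tm._cds2g[k] for k in range(1, tm.cds_length + 1)]

    uv_sites = _uv_eligible_sites(genome, tm)
    if cfg.uv_fraction > 0 and not uv_sites:
        raise ValueError("no di-pyrimidine-eligible site in the reference")

    # germ-line variant definitions shared by the whole panel
    spectrum = cfg.germline_maf_spectrum
    g_sites = sorted(rng.choice(len(cds_sites), size=min(cfg.n_germline_sites,
                                                         len(cds_sites)),
                                replace=False))
    germline_defs = []
    for i, si in enumerate(g_sites):
        pos = cds_sites[int(si)]
        ref = genome.base(contig, pos)
        alt = str(rng.choice([b for b in ALT_BASES if b != ref]))
        germline_defs.append((pos, ref, alt, spectrum[i % len(spectrum)]))

    pairs = []
    truth = TruthSet()
    half = cfg.n_pairs // 2
    phenos = ["clear"] * (cfg.n_pairs - half) + ["cataract"] * half
    pair_variants: dict[str, dict] = {}
    for i in range(cfg.n_pairs):
        pid = f"P{i + 1:03d}"
        pair = LensPair(pid, f"{pid}_L", f"{pid}_R", phenos[i])
        pairs.append(pair)
        per_sample: dict[str, dict[tuple, float]] = {pair.left_sample: {},
                                                     pair.right_sample: {}}
        taken: set[int] = set()
        for pos, ref, alt, af in germline_defs:
            n_alt = int(rng.binomial(2, af))
            if n_alt == 0:
                continue
            taken.add(pos)
            gt = "het" if n_alt == 1 else "hom"
            for sample in per_sample:
                vaf = (_truncnorm(rng, 50.0, cfg.het_vaf_sd, 20.0, 80.0)
                       if gt == "het" else 100.0)
                per_sample[sample][(pos, ref, alt)] = vaf
            truth.germline.append({"pair_id": pid, "contig": contig, "pos": pos,
                                   "ref": ref, "alt": alt, "genotype": gt})
        n_som = int(rng.poisson(cfg.somatic_per_pair_rate))
        for _ in range(n_som):
            for _try in range(200):
                if rng.random() < cfg.uv_fraction:
                    pos, ref, alt = uv_sites[int(rng.integers(len(uv_sites)))]
                    uv = True
                else:
                    pos = cds_sites[int(rng.integers(len(cds_sites)))]
                    ref = genome.base(contig, pos)
                    alt = str(rng.choice([b for b in ALT_BASES if b != ref]))
                    probe = VariantCall(contig, pos, ref, alt, 0, 1, 0.0, "somatic")
                    uv = dipyrimidine_flags(probe, genome).uv_signature
                if pos not in taken:
                    break
            else:
                continue
            taken.add(pos)
            side = "left" if rng.random() < 0.5 else "right"
            sample = pair.left_sample if side == "left" else pair.right_sample
            lo, hi = cfg.somatic_vaf_range
            vaf = float(rng.uniform(lo, hi))
            per_sample[sample][(pos, ref, alt)] = vaf
            truth.somatic.append({"pair_id": pid, "side": side, "contig": contig,
                                  "pos": pos, "ref": ref, "alt": alt,
                                  "true_vaf": vaf, "uv_signature": bool(uv)})
        pair_variants[pid] = per_sample

    # emit pileups at every truth site plus background sites, for every sample
    truth_pos = sorted({t["pos"] for t in truth.germline + truth.somatic})
    bg = [cds_sites[int(i)] for i in
          rng.choice(len(cds_sites), size=min(cfg.n_background_sites,
                                              len(cds_sites)), replace=False)]
    all_pos = sorted(set(truth_pos) | set(bg))

    sites: list[PileupSite] = []
    for pair in pairs:
        for sample in (pair.left_sample, pair.right_sample):
            variants = pair_variants[pair.pair_id][sample]
            by_pos: dict[int, list[tuple[str, str, float]]] = {}
            for (pos, ref, alt), vaf in variants.items():
                by_pos.setdefault(pos, []).append((ref, alt, vaf))
            for pos in all_pos:
                ref = genome.base(contig, pos)
                depth = int(round(rng.lognormal(cfg.depth_log_mean,
                                                cfg.depth_log_sd)))
                depth = max(depth, 1)
                counts = {b: 0 for b in ALT_BASES}
                remaining = depth
                for vref, valt, vaf in by_pos.get(pos, []):
                    k = int(rng.binomial(depth, vaf / 100.0))
                    k = min(k, remaining)
                    counts[valt] += k
                    remaining -= k
                # symmetric miscalls on the residual reference reads
                n_err = int(rng.binomial(remaining, cfg.error_rate))
                others = [b for b in ALT_BASES if b != ref]
                for b in rng.choice(others, size=n_err):
                    counts[b] += 1
                counts[ref] += remaining - n_err
                sites.append(PileupSite(sample, contig, pos, ref, depth, counts))
    return sites, pairs, truth


def make_cohort_genotypes(cfg: SimulationConfig,
                          variants: Sequence[tuple[str, int, str, str, float]],
                          ) -> tuple[list, "object"]:
    """Hardy-Weinberg genotypes for a case-control cohort.

    ``variants`` are (contig, pos, ref, alt, population_af).  Phenotypes are
    assigned in the emulated study's proportions: 64 clear-lens controls and
    161 cataract cases split over subtypes (67 nuclear, 43 cortical, 2 PSC,
    49 mixed), rescaled to ``n_individuals``.
    """
    from .stats import CohortPanel, GenotypeRecord

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    weights = {"clear": 64, "nuclear": 67, "cortical": 43, "psc": 2, "mixed": 49}
    total = sum(weights.values())
    labels: list[str] = []
    for pheno, w in weights.items():
        labels += [pheno] * round(cfg.n_individuals * w / total)
    while len(labels) < cfg.n_individuals:
        labels.append("clear")
    labels = labels[:cfg.n_individuals]
    individuals = tuple((f"S{i + 1:04d}", labels[i])
                        for i in range(cfg.n_individuals))
    panel = CohortPanel(individuals)
    records = []
    for contig, pos, ref, alt, af in variants:
        draws = rng.binomial(2, af, size=cfg.n_individuals)
        for (sid, _), n_alt in zip(individuals, draws):
            if n_alt:
                records.append(GenotypeRecord(sid, contig, pos, ref, alt,
                                              "het" if n_alt == 1 else "hom"))
    return records, panel


def simulate_run(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a full synthetic input set (FASTA, transcript spec, pileups,
    pair manifest, catalog of the germ-line truth, truth JSON).  Returns a
    manifest of what was written."""
    from .annotate import CatalogRecord, write_catalog
    from .calling import write_pairs, write_pileups
    from .refmodel import write_fasta, write_transcripts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, tm = make_reference(cfg)
    sites, pairs, truth = inject_and_pileup(cfg, genome, tm)
    write_fasta(genome, out / "genome.fa")
    write_transcripts([tm], out / "transcripts.tsv")
    write_pileups(sites, out / "pileups.tsv")
    write_pairs(pairs, out / "pairs.tsv")
    seen = {}
    for g in truth.germline:
        key = (g["contig"], g["pos"], g["ref"], g["alt"])
        if key not in seen:
            seen[key] = CatalogRecord(*key, ids=(f"sim{len(seen) + 1:04d}",),
                                      source="simdb")
    write_catalog(seen.values(), out / "catalog.tsv")
    truth.to_json(out / "truth.json")
    return {
        "n_pairs": len(pairs),
        "n_pileup_rows": len(sites),
        "n_germline_truth": len(truth.germline),
        "n_somatic_truth": len(truth.somatic),
        "files": ["genome.fa", "transcripts.tsv", "pileups.tsv", "pairs.tsv",
                  "catalog.tsv", "truth.json"],
    }
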