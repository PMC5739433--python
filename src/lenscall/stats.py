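"""Cohort summaries and contingency statistics.

Panel minor-allele frequencies are carrier-count arithmetic over diploid
individuals; class tallies aggregate annotated variants by consequence,
substitution class, UV context, novelty and damage verdict.  The exact test
on a 2x2 table is the two-sided Fisher rule: the sum of hypergeometric
probabilities of all margin-preserving tables no more probable than the
observed one (ties admitted within a 1e-12 relative tolerance).  Pearson
chi-square is computed without continuity correction by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .annotate import AnnotatedVariant, NOVEL, REFERENCE, TRANSITION


@dataclass(frozen=True)
class CohortPanel:
    """Diploid individuals with phenotype labels."""

    individuals: tuple[tuple[str, str], ...]  # (sample_id, phenotype)

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError("empty panel")
        ids = [s for s, _ in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.individuals)


@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str  # het / hom

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"bad genotype {self.genotype!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell")
        if self.total == 0:
            raise ValueError("all-zero table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class PanelSummary:
    n_variants: int = 0
    n_pairs: int | None = None
    by_class: Counter = field(default_factory=Counter)
    by_substitution: Counter = field(default_factory=Counter)
    dipyrimidine: int = 0
    uv_signature: int = 0
    novel: int = 0
    reference: int = 0
    damaging: int = 0
    pairs_with_variant: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_pairs": self.n_pairs,
            "by_class": dict(self.by_class),
            "by_substitution": dict(self.by_substitution),
            "dipyrimidine": self.dipyrimidine,
            "uv_signature": self.uv_signature,
            "novel": self.novel,
            "reference": self.reference,
            "damaging": self.damaging,
            "n_pairs_with_variant": len(self.pairs_with_variant),
        }


def panel_maf(carriers: Sequence[GenotypeRecord], panel: CohortPanel) -> float:
    """Alternate-allele frequency: (het + 2*hom) / (2 * N individuals)."""
    ids = panel.sample_ids
    seen = set()
    for rec in carriers:
        if rec.sample_id not in ids:
            raise ValueError(f"carrier {rec.sample_id} not in panel")
        if rec.sample_id in seen:
            raise ValueError(f"duplicate carrier record for {rec.sample_id}")
        seen.add(rec.sample_id)
    alleles = sum(1 if r.genotype == "het" else 2 for r in carriers)
    return alleles / (2 * panel.n_individuals)


def fold_maf(af: float) -> float:
    """Fold an alternate-allele frequency to the minor allele (<= 0.5)."""
    return min(af, 1.0 - af)


def tally_classes(annotated: Sequence[AnnotatedVariant],
                  n_pairs: int | None = None) -> PanelSummary:
    s = PanelSummary(n_variants=len(annotated), n_pairs=n_pairs)
    pairs = set()
    for a in annotated:
        s.by_class[a.consequence.klass] += 1
        if a.flags:
            s.by_substitution[a.flags.substitution_class] += 1
            if a.flags.uv_signature:
                s.uv_signature += 1
        if a.dipyrimidine:
            s.dipyrimidine += 1
        if a.novelty == NOVEL:
            s.novel += 1
        elif a.novelty == REFERENCE:
            s.reference += 1
        if a.damage_label in ("damaging", "probably_damaging"):
            s.damaging += 1
        if a.call.pair_id:
            pairs.add(a.call.pair_id)
    s.pairs_with_variant = frozenset(pairs)
    assert sum(s.by_class.values()) == s.n_variants
    return s


def fisher_exact_2x2(t: ContingencyTable2x2, rel_tol: float = 1e-12) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Enumerates the hypergeometric distribution over the free cell and sums
    the probabilities of tables no more probable than the observed one.
    """
    n = t.total
    row1, col1 = t.a + t.b, t.a + t.c
    rv = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t.a)
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def chi_square_2x2(t: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p (1 df); optional Yates correction."""
    obs = t.as_array().astype(float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if rows.min() == 0 or cols.min() == 0:
        raise ValueError("zero margin")
    expected = np.outer(rows, cols) / t.total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def compare_panels(a: PanelSummary, b: PanelSummary, metric: str = "total",
                   construction: str = "pairs_with_variant",
                   ) -> tuple[ContingencyTable2x2, float]:
    """Exact-test comparison of two paired-lens panels.

    ``pairs_with_variant`` tables pairs carrying >= 1 qualifying variant
    against pairs without; ``variant_counts`` tables the metric's count
    against the remaining variants in each panel.
    """
    def metric_count(s: PanelSummary) -> int:
        if metric == "total":
            return s.n_variants
        if metric == "damaging":
            return s.damaging
        if metric == "novel":
            return s.novel
        raise ValueError(f"unknown metric {metric!r}")

    if metric == "damaging" and a.damaging == 0 and b.damaging == 0 \
            and a.n_variants + b.n_variants > 0:
        raise ValueError("damage labels unavailable in both panels")

    if construction == "pairs_with_variant":
        if a.n_pairs is None or b.n_pairs is None:
            raise ValueError("pair counts required for pairs_with_variant")
        ka, kb = len(a.pairs_with_variant), len(b.pairs_with_variant)
        table = ContingencyTable2x2(ka, a.n_pairs - ka, kb, b.n_pairs - kb)
    elif construction == "variant_counts":
        ma, mb = metric_count(a), metric_count(b)
        table = ContingencyTable2x2(ma, a.n_variants - ma, mb, b.n_variants - mb)
    else:
        raise ValueError(f"unknown construction {construction!r}")
    return table, fisher_exact_2x2(table)


def shared_positions(a: Sequence[AnnotatedVariant],
                     b: Sequence[AnnotatedVariant]) -> set[tuple[str, int]]:
    """Genomic (contig, pos) present in both variant lists."""
    pos_a = {(v.call.contig, v.call.pos) for v in a}
    pos_b = {(v.call.contig, v.call.pos) for v in b}
    return pos_a & pos_b


def bonferroni(pvals: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values, capped at 1."""
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]


def transition_count(pairs: Sequence[tuple[str, str]]) -> int:
    """Count transitions among (ref, alt) allele pairs."""
    from .annotate import classify_substitution

    return sum(1 for r, a in pairs if classify_substitution(r, a) == TRANSITION)
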