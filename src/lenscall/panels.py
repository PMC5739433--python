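"""Embedded variant panels from a published paired-lens deep-sequencing study.

Four small TSVs ship with the package: germ-line coding SNVs for two genes
(EPHA2, TP53) from a cataract case-control cohort (N = 225: 161 cataract
cases, 64 clear-lens controls), and somatic (paired-lens discordant) EPHA2
SNVs from post-mortem donor lenses (35 clear pairs, 22 cataract pairs).
They carry the printed per-variant fields — position, alleles, HGVS names,
read depth, VAF, di-pyrimidine footnote, database ids and predictor verdicts
— and drive the package's regression tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .annotate import (AnnotatedVariant, Consequence, NOVEL, REFERENCE,
                       parse_hgvs)
from .calling import SOMATIC, VariantCall

#: Cohort sizes of the embedded panels.
N_CASE_CONTROL = 225
N_CLEAR_PAIRS = 35
N_CATARACT_PAIRS = 22

_FUNC_TO_KLASS = {
    "synonymous SNV": "synonymous",
    "nonsynonymous SNV": "missense",
    "stopgain": "stopgain",
    "splicing": "splice",
    "UTR-3": "UTR3",
    "UTR-5": "UTR5",
}


@dataclass(frozen=True)
class GermlineRow:
    exon: int
    rsid: str
    cosmic_id: str
    hgvs_c: str
    hgvs_p: str
    polyphen2: str
    sift: str
    maf_panel: float
    carriers: dict[str, int]  # phenotype -> carrier count

    @property
    def novel(self) -> bool:
        return self.rsid.lower() == "novel"

    @property
    def alleles(self) -> tuple[str, str]:
        """Coding-strand (ref, alt) parsed from the printed DNA change."""
        cons = parse_hgvs(self.hgvs_c)
        return cons.coding_ref, cons.coding_alt

    @property
    def consequence(self) -> Consequence:
        return parse_hgvs(self.hgvs_c, self.hgvs_p)

    @property
    def n_carriers(self) -> int:
        return sum(self.carriers.values())


def _read(name: str) -> list[dict[str, str]]:
    text = resources.files("lenscall").joinpath("data", name).read_text()
    lines = text.strip("\n").split("\n")
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


_PHENOTYPES = ["clear", "cortical", "nuclear", "psc", "mixed"]


def _germline(name: str) -> list[GermlineRow]:
    rows = []
    for r in _read(name):
        carriers = {p: int(r[f"n_{p}"] or 0) for p in _PHENOTYPES}
        rows.append(GermlineRow(int(r["exon"]), r["rsid"], r.get("cosmic_id", ""),
                                r["hgvs_c"], r["hgvs_p"], r["polyphen2"],
                                r["sift"], float(r["maf_panel"]), carriers))
    return rows


def germline_epha2() -> list[GermlineRow]:
    """Germ-line EPHA2 coding SNVs of the case-control panel (30 rows)."""
    return _germline("germline_epha2.tsv")


def germline_tp53() -> list[GermlineRow]:
    """Germ-line TP53 coding SNVs of the case-control panel (9 rows)."""
    return _germline("germline_tp53.tsv")


def _split_aachange(s: str) -> tuple[str, str]:
    """Pull (hgvs_c, hgvs_p) out of 'GENE:TX:exonN:c.X123Y:p.A1B' strings."""
    parts = s.split(":")
    hgvs_c = next((p for p in parts if p.startswith("c.")), "")
    hgvs_p = next((p for p in parts if p.startswith("p.")), "")
    return hgvs_c, hgvs_p


def _somatic(name: str) -> list[AnnotatedVariant]:
    out = []
    for r in _read(name):
        call = VariantCall(r["contig"], int(r["pos"]), r["ref"], r["alt"],
                           alt_count=round(int(r["depth"]) * float(r["vaf_percent"]) / 100),
                           depth=int(r["depth"]),
                           vaf_percent=float(r["vaf_percent"]), origin=SOMATIC)
        hgvs_c, hgvs_p = _split_aachange(r["aachange"])
        cons = parse_hgvs(hgvs_c, hgvs_p)
        printed = _FUNC_TO_KLASS[r["func"]]
        if cons.klass != printed:  # printed class is authoritative for UTRs
            cons = Consequence(printed, cons.hgvs_c, cons.hgvs_p, cons.aa_ref,
                               cons.aa_alt, cons.cds_pos, cons.coding_ref,
                               cons.coding_alt)
        ids = tuple(x for x in (r["dbsnp_id"], r["cosmic_id"]) if x)
        in_db = bool(ids or r["exac_af"])
        dmg = {"D": "damaging", "T": "tolerated"}.get(r["sift"])
        out.append(AnnotatedVariant(
            call, cons, flags=None,
            novelty=REFERENCE if in_db else NOVEL, catalog_ids=ids,
            damage_label=dmg,
            dipyrimidine_override=bool(int(r["dipyrimidine"]))))
    return out


def somatic_epha2_clear() -> list[AnnotatedVariant]:
    """Retained somatic EPHA2 SNVs of the paired clear-lens panel (66 rows)."""
    return _somatic("somatic_epha2_clear.tsv")


def somatic_epha2_cataract() -> list[AnnotatedVariant]:
    """Retained somatic EPHA2 SNVs of the paired cataract-lens panel (33 rows)."""
    return _somatic("somatic_epha2_cataract.tsv")
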