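# Methods

## Designation model

The pipeline operates purely on per-site allele counts ("pileups"); read
alignment, base-quality modelling and strand-bias statistics are upstream of
its inputs and out of scope. Variant allele frequency (VAF) is
`100 × alt_reads / depth`; it is undefined (a distinct error, not 0) at zero
depth.

**Germ-line rule.** In single-sample panels, every non-reference allele with
VAF ≥ `germline_vaf_percent` (default 20%) is designated germ-line.
Genotype class is het inside `het_range_percent` (default [20, 80]) and hom
above it; the 80% boundary is a convention, not an estimate, and is
configurable.

**Paired discordance.** For a lens pair, an allele is *present* in a sample
when VAF ≥ `presence_vaf_percent` (default 1%) **and** alt reads ≥
`min_alt_reads` (default 4). The read floor is our addition: a pure
percentage floor admits one-read artifacts at low depth. Present in exactly
one lens ⇒ somatic (the call carries the carrier lens's VAF/depth); present
in both ⇒ germ-line; neither ⇒ no call. Alleles at a site are evaluated
independently, so a multi-allelic site can yield two designations. An
optional exact-test gate (`somatic_fisher_alpha`) additionally requires the
two-sided Fisher test on `[[alt_L, ref_L], [alt_R, ref_R]]` to reject;
discordant-by-threshold calls that fail it are labelled ambiguous. This is
the count-level analogue of a paired somatic caller's significance filter.

**Somatic retention filters.** Somatic calls with VAF < 3% or depth < 600
reads are flagged `LOW_VAF` / `LOW_DEPTH` (boundaries inclusive: exactly 3%
and exactly 600 pass). A variant identity `(contig, pos, ref, alt)` seen in
more than one pair is recurrent — inconsistent with independent single-cell
origin at these rates — and *all* of its occurrences are excluded. Outputs
are ordered by `(contig, pos, alt)`; run manifests record the count at every
filter step and assert `in = retained + Σ excluded`.

## Coordinate arithmetic and annotation

Coordinates are 1-based closed throughout; BED12 input is converted at the
reader. One transcript model per gene: ordered non-overlapping exons, CDS
boundaries inside exons, CDS length a multiple of 3 and ≥ 6. For
minus-strand models the coding sequence is the reverse complement of the
exonic plus-strand sequence, so increasing genomic position maps to
decreasing c. position and coding alleles are complements of the plus-strand
pair. Intron offsets follow HGVS convention (`c.N+k` / `c.N-k` in
transcript orientation, anchored to the nearer exon boundary; equidistant
bases anchor 5′). Positions outside the transcript span return a distinct
out-of-transcript value rather than raising.

Consequences are assigned by translating the affected codon before and after
substitution under the standard nuclear code (stops written `X`):
synonymous, missense, stopgain, stoploss; intronic positions within the
splice window (|offset| ≤ 2, configurable — covering the canonical donor and
acceptor dinucleotides) are splice; other intronic positions intronic; exonic
non-coding positions UTR5/UTR3 by side. The HGVS parser accepts the dialects
used in published variant tables (`c.G2740T:p.E914X`, `c.2162G>A`,
`c.1682+1G>A`, `c.*20C>T`, embedded blanks), enabling re-tallies of printed
tables without the underlying reference sequence.

**UV context.** The pyrimidine strand of a substitution is the strand whose
reference base is C or T. A site is di-pyrimidine when at least one
immediately adjacent base *on that strand* is also a pyrimidine — 5′ or 3′
adjacency both qualify, a deliberate choice since photodimer chemistry
involves either neighbour and published site flags include both patterns.
The UV signature additionally requires the pyrimidine-strand change to be
C>T. Tandem CC>TT detection is out of scope at the single-base call level.
An adjacent N disqualifies both flags (conservative) and marks the context
ambiguous.

**Novelty** is an exact `(contig, pos, ref, alt)` match against local
catalogs — allele-exact, not position-only, because catalog identifiers are
allele-specific. Damage labels (e.g. SIFT/PolyPhen-style verdicts) are
consumed from input TSVs, never computed; a variant counts as damaging if
*any* supplied predictor says damaging/probably damaging.

## Statistics

Panel allele frequency is `(het + 2·hom) / 2N` over N diploid individuals;
folding to the minor allele is a presentation option. The two-sided Fisher
exact p sums hypergeometric probabilities of all margin-preserving tables no
more probable than the observed one (ties admitted within 1e-12 relative
tolerance); the test suite holds it to an exact-rational full-enumeration
oracle and to an independent library implementation. Pearson chi-square is
computed without continuity correction by default (Yates available as a
flag), p from the 1-df chi-square distribution. Panel comparison builds the
2×2 either as pairs-with-variant vs pairs-without (default) or as variant
counts; the construction is explicit because narrative p-values in the
literature rarely state theirs. Bonferroni is offered for multiple-testing
adjustment, reported alongside raw p.

## Synthetic data

The generator emulates the paired-lens amplicon design, not reads: no
FASTQ, no PCR duplicates, no amplicon dropout beyond depth variance.

* Genome: i.i.d. bases at `gc_fraction` (default 0.45), default length
  10 kb; one transcript with ≥ 3 exons on the minus strand by default
  (mirroring the study genes), UTRs inside the terminal exons, CDS a valid
  ORF with no internal stop.
* Depth: lognormal with log-mean ln 3000 and log-sd 0.5 — median ~3000×
  with a heavy right tail spanning roughly the 600–8000× range the design
  produces; >70% of sites attain 1000×.
* Germ-line variants: population AFs from `germline_maf_spectrum`
  (default 0.35/0.05/0.01/0.005, a common-plus-rare mix), Hardy–Weinberg
  genotypes per pair, per-lens het VAF ~ Normal(50, 5) truncated to
  [20, 80] (amplification noise), hom at 100%.
* Somatic variants: Poisson(`somatic_per_pair_rate` = 3) per pair — a
  testing convenience, not a biological estimate — placed in one lens with
  VAF uniform on [3, 13]% (the retained range the design observes);
  `uv_fraction` (default 0.7) of them are forced to pyrimidine-strand C>T
  at di-pyrimidine-eligible CDS sites, the rest uniform.
* Counts: binomial at the true VAF; residual reads miscalled at
  `error_rate` (default 0.1%), spread evenly over the three other bases.
  An optional C>T-biased error mode was considered and left unimplemented.
* All randomness flows from one `numpy` generator seeded by
  `SimulationConfig.seed`; identical configs give byte-identical outputs.

What passing recovery tests show — and don't. At this operating point the
designation pipeline recovers injected somatic variants at true VAF ≥ 5%
with sensitivity ≥ 0.95, never converts germ-line truth to somatic (rate
≤ 0.01), and estimates somatic VAF to ≤ 0.5 percentage points MAE at depth
≥ 2000×. Real amplicon data adds PCR jackpot errors, strand bias, alignment
artifacts and context-dependent error rates that this generator does not
model, so these figures bound statistical, not protocol, error. Bilateral
mosaicism is not simulated; the paired design cannot distinguish it from
germ-line, and neither can the simulator's truth labels.

## Embedded panels

`lenscall.panels` ships four small TSVs transcribed from a published
paired-lens study's printed variant tables: germ-line coding SNVs for EPHA2
(30 rows) and TP53 (9 rows) from a 225-individual case-control cohort, and
retained somatic EPHA2 SNVs from 35 clear (66 rows) and 22 cataract
(33 rows) lens pairs. Consequence classes are re-derived by HGVS parsing
(the printed class column is kept authoritative for UTR rows, where the c.
string alone is ambiguous about transcript side); di-pyrimidine status comes
from the printed site footnotes, since the study genome is not shipped;
novelty reflects presence of any printed database id or population
frequency. Approximate alt read counts are reconstructed as
`round(depth × VAF)`.

## Problem sizes and numerical choices

Regression tallies run on the embedded tables (≤ 66 rows each); oracle
equivalence tests use 500 random tables (totals ≤ 60) and 500 random
substitutions over toy transcripts; recovery tests use one seed-fixed
20-pair simulation (~50 pileup sites × 40 samples) — sizes chosen so the
whole suite completes in seconds while leaving every estimate's sampling
error far inside the asserted bounds. Exact-test ties are compared at 1e-9
relative tolerance against the rational oracle; VAFs are plain floating
point (depths ≤ 10⁴ leave them exact to well below printed precision).

## Known limitations

* One transcript per gene; no multi-isoform annotation, no liftover.
* Single-base substitutions only — no indels, MNVs, or tandem CC>TT calls.
* The recurrence rule excludes all occurrences of a recurrent identity;
  published accounts that mix recurrence with other filters can therefore
  differ by a few variants in the excluded column.
* Logistic-regression covariate correction (e.g. for sex) is out of scope;
  use any standard GLM library on the genotype matrix the package writes.
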