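# Methods

This document records the analytical model implemented by the package, the
parameter defaults and the reasoning behind them, the design of the synthetic
data generator, the numerical choices, and the known limitations.

## Coordinate model

All intervals are 0-based, half-open `[start, end)` internally. GFF3 input
(1-based, inclusive) is converted once at the parsing boundary; BED input is
native. Report tables print genomic locations 1-based inclusive
(`chrom:start-end`) to match genome-browser conventions. Overlap lengths,
densities and containment tests are therefore exact integer arithmetic with
no off-by-one ambiguity.

## cis-NAT detection

Two transcripts form a candidate pair when they lie on the same chromosome,
on opposite strands, and the union of their pairwise exon intersections —
merged so that overlapping or abutting intersection blocks are not counted
twice — exceeds `min_overlap` (default 25 nt, strict). Candidates are
enumerated over all transcripts, then pairs with a member in an excluded
biotype (transposon, rRNA, tRNA, snRNA, snoRNA, miRNA) are removed in a
separate, logged step so the pre- and post-exclusion counts are auditable.

Orientation is classified on genomic spans: *enclosed* when one span
contains the other (equal spans included), otherwise *convergent* when the
plus-strand member starts first (3′ ends meet), otherwise *divergent*.
Partner class is the unordered combination of member biotypes among `CDS-p`
(protein-coding with a recognized domain), `CDS-n` (predicted CDS without a
domain) and `ncRNA`, giving six labels.

When several isoforms of the same locus pair overlap, one *representative*
pair is kept per unordered locus pair: the pair with the largest overlap,
ties broken lexicographically on (plus id, minus id). This keeps downstream
counts per-locus rather than per-isoform.

## Pairing networks

Representatives define a graph on transcripts; connected components
(computed with networkx) are the pairing groups. A group's type is the
strand-wise member count ordered min-to-max ("one-to-two", "two-to-two", …;
counts above four are printed numerically). One-to-two groups carry a
subtype: the two orientations joined by "+" in the canonical order
enclosed < convergent < divergent.

## nat-siRNA profiling

Small RNA reads are filtered to 18–34 nt, to nuclear chromosomes, and away
from structural-RNA/transposon annotations. A read counts as a nat-siRNA of
a pair when it is wholly contained in a single merged overlap block.
Per pair and condition:

- **Strand bias** is computed on unique reads. If one strand has reads and
  the other none the class is one-strand; otherwise a ratio ≥ 5 is a strong
  bias, ≥ 2 a weak bias, and below 2 balanced.
- **Density enrichment** compares unique reads per kilobase in the overlap
  against the flanks (the members' exon union minus the overlap). The pair
  is *enriched* when the ratio strictly exceeds 5. A flank density of zero
  with overlap reads present yields an infinite ratio, serialized as the
  string `inf`.
- **Exclusivity** holds when every read touching the members' exons is
  contained in the overlap and the overlap has strictly more than 5 unique
  reads.

## Expression analysis

A pair is *expressed* under a condition when both members have FPKM > 0 and
at least one nat-siRNA is observed; *co-expressed* means expressed under
every condition; *stress-preferential* means expressed under a stress but
not under control. Co-expressed one-to-one pairs are assigned to subgroups
from Δsense and Δantisense, the log2 ratios of stress to control FPKM (with
pseudocount ε = 0.1): subgroup 1 when both |Δ| < 1; subgroups 2–5 for the
four sign combinations at |Δ| ≥ 1; *outlier* otherwise (one member changed,
the other not).

Differential expression of a member between a stress and the control library
uses a two-sided Fisher exact test on the 2×2 table of fragment counts vs.
the remaining library mass; a member is a DEG when `|log2 fold| ≥ 1` on
FPKM (ε = 0.1) and p < 0.001. Domain enrichment contrasts, for each
subgroup, the domain counts of its sense members against all
domain-annotated transcripts with the same exact test and threshold.

## Numerical choices

- **Fisher exact test, dual branch.** For total counts N ≤ 10,000 the
  two-sided p-value is computed by full enumeration of the hypergeometric
  support in exact rational arithmetic (`math.comb` numerators, `Fraction`
  sums), so results are exact to float conversion; the test suite checks
  agreement with an independent factorial-based oracle to 1e-12. Above that,
  a log-space implementation (`scipy.special.gammaln`) is used, with a
  relative tie tolerance of 1e-10 on the observed table's probability — the
  standard guard against floating-point ties misclassifying equal-probability
  tables.
- **Pseudocount ε = 0.1** keeps log2 fold changes defined at FPKM 0 while
  preserving the "expressed ⇔ FPKM > 0" definition, which is applied before
  any ratio is computed.
- **Infinite density ratios** are represented as `math.inf` internally and
  the string `inf` in reports, never as a sentinel number.
- **Determinism.** Every table is sorted by an explicit key before writing
  and floats are formatted with fixed precision, so identical inputs yield
  byte-identical reports.

## Synthetic data generator

The generator (`cisnat.simulate`) is truth-first: it decides every label —
orientation, partner class, overlap length, network membership, strand-bias
class, exclusivity, enrichment, expression subgroup, DEG status — and then
constructs coordinates, reads and counts that realize those labels, writing
the labels to `truth.json`. Geometry templates place exons so the realized
merged overlap equals the drawn target exactly (asserted at generation
time). Each data layer draws from its own seeded child generator
(`numpy.random.default_rng([seed, role])`), so changing, say, the read
model does not perturb the annotation.

Realism and effect sizes:

- Transcript and overlap lengths: overlaps drawn uniformly from 60–400 nt
  inside multi-exon transcripts on two 250 kb chromosomes plus a small
  organelle chromosome; decoys cover same-strand overlap, at-threshold
  (exactly 25 nt) overlap, excluded biotypes, isoforms of the same locus,
  structural RNAs and transposons.
- Small RNA reads: lengths follow a plant-like distribution peaked at
  21/24 nt. Each pair receives exactly `reads_per_pair = 100` reads in its
  overlap; strand membership is binomial with plus-strand fraction 0.9 (or
  0.1) for planted strong bias, 1.0/0.0 for one-strand and 0.5 for
  balanced. With n = 100 and p = 0.9 the probability that the observed
  ratio falls below the 5-fold call boundary (fewer than ~83 reads on the
  major strand) is below 2%, which is what makes ≥ 95% recovery a fair,
  pre-computable bar rather than a tuned one. Flank read counts are derived
  from a target overlap/flank density ratio (2 for plain pairs, 12 for
  enriched ones, either side of the 5-fold call boundary).
- Expression: FPKM baselines are log-normal (median 8); planted subgroup
  effects are 4-fold (log2 = 2) against the 2-fold classification threshold,
  with multiplicative log-normal noise σ = 0.15, so a planted effect is
  ~6.7 noise standard deviations from the boundary. Fragment counts are
  Poisson draws consistent with FPKM and a 2×10⁷-read library. DEG truth is
  planted through those same effects, not as an independent label.
- Domains: one term ("PPR") is planted at high frequency in subgroup-1
  sense members against a low background, giving a recoverable enrichment
  signal; other terms are assigned at background rates.

## Limitations

- Detection operates on annotated transcript models only; it cannot find
  antisense transcription absent from the annotation, and overlap is
  defined on exons, so intron-only overlaps are not pairs.
- FPKM > 0 as the expression criterion is deliberately simple and inherits
  any noise in upstream quantification; no abundance threshold or
  replicate-based variance model is applied.
- The Fisher DEG test treats each library as a single sample; without
  biological replicates it can call small fold changes significant at high
  depth, which is why the fold-change criterion is applied jointly.
- Strand-bias and density statistics use unique reads, so they are
  insensitive to copy-number amplification but also discard it as evidence.
- The synthetic generator validates correctness of the implementation, not
  biological completeness: it does not model sequencing error, positional
  read bias within overlaps, isoform-level expression mixtures, or
  correlated noise across conditions.
- Domain enrichment tests each term marginally with no multiple-testing
  correction; with many terms the significant set should be treated as a
  ranking, not an error-controlled discovery list.
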