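# cisnat

Detection and characterization of *cis*-natural antisense transcripts
(*cis*-NATs) and their overlap-derived small RNAs (nat-siRNAs) from
strand-specific RNA-seq annotations, small RNA alignments, and expression
tables.

## Scientific problem

A *cis*-NAT is a pair of transcripts encoded on opposite strands of the same
locus whose exons overlap. The double-stranded RNA formed in the overlap can
be processed into nat-siRNAs, making these loci candidate regulators —
particularly under abiotic stress, where one member of a pair is often
induced while its antisense partner is repressed. Characterizing a genome's
*cis*-NAT complement requires answering, consistently and reproducibly:

1. **Which transcript pairs overlap?** Exonic overlap on opposite strands,
   above a minimum length (default > 25 nt), computed on merged exon
   intersections so multi-exon geometry is handled exactly.
2. **How are they arranged?** Each pair is *enclosed* (one genomic span
   contains the other), *convergent* (3′ ends overlap) or *divergent*
   (5′ ends overlap), and is classified by the biotypes of its members
   (protein-coding vs. non-coding RNA, etc.). Structural RNAs and
   transposons are excluded.
3. **Do they form networks?** A transcript can participate in several pairs;
   connected components of the pairing graph are classified one-to-one,
   one-to-two, two-to-two, and so on.
4. **Do the overlaps produce small RNAs?** Reads wholly contained in the
   overlap are nat-siRNA candidates; per pair and condition the package
   reports strand bias, overlap vs. flank read density (with an enrichment
   call), and whether small RNA production is exclusive to the overlap.
5. **How do pairs respond to stress?** A pair is *expressed* when both
   members have FPKM > 0 and the overlap yields at least one nat-siRNA.
   Co-expressed one-to-one pairs are placed into five expression subgroups
   by the log2 change of sense and antisense members between control and
   stress; differential expression of individual members is called with a
   two-sided Fisher exact test on fragment counts; protein-domain
   enrichment per subgroup uses the same exact test.

The package bundles the per-chromosome pair counts and cohort totals of a
genome-wide rice *cis*-NAT survey (3819 pairs among 76,013 transcripts;
2292 expressed pairs) so its headline percentages can be recomputed directly,
and it includes a truth-tracking synthetic data generator for end-to-end
validation.

## Worked example

Recompute the bundled reference survey's headline percentages:

```text
$ cisnat report
{
 "pct_coding_vs_noncoding": 36.08,
 "pct_coding_vs_undomained": 33.39,
 "pct_coexpressed": 46.77,
 "pct_convergent": 23.51,
 "pct_divergent": 20.21,
 "pct_enclosed": 56.27,
 "pct_epidermal": 54.01,
 "pct_epidermal_coexpressed": 58.56,
 "pct_one_to_one": 87.93,
 "pct_stress_preferential": 21.95,
 "pct_transcripts_in_cisnat": 9.74
}
```

Generate a synthetic bundle with known ground truth and run the full
pipeline on it:

```text
$ cisnat simulate --seed 7 --out demo/fixture
fixture bundle written to demo/fixture (9 files)

$ cisnat run \
    --gff demo/fixture/annotation.gff3 \
    --bed control=demo/fixture/smallrna_control.bed \
    --bed salt=demo/fixture/smallrna_salt.bed \
    --bed cold=demo/fixture/smallrna_cold.bed \
    --bed drought=demo/fixture/smallrna_drought.bed \
    --expr demo/fixture/expression.tsv \
    --domains demo/fixture/domains.tsv \
    --control control \
    --out demo/out
87 candidates -> 83 pairs -> 79 representatives; 54 one-to-one, 10 groups; reports in demo/out
```

`demo/out` then contains `pairs.tsv`, `groups.tsv`, `profiles.tsv`,
`pair_summary.tsv`, `expression_summary.tsv`, `expressed.tsv`, `degs.tsv`,
`domain_enrichment.tsv` and `run_log.json`. For example:

```text
$ head -3 demo/out/expression_summary.tsv
condition	expressed	exclusive	enriched
control	76	6	12
cold	79	6	12

$ head -2 demo/out/pairs.tsv
plus_id	plus_len	minus_id	minus_len	overlap_len	overlap_locations	orientation	partner_class
PT000	996	MT000	356	356	chr1:2447-2802	enclosed	CDS-p vs ncRNA
```

The same stages are available from Python:

```python
from cisnat import RunConfig, run

result = run(RunConfig(
    gff3="demo/fixture/annotation.gff3",
    bed_by_condition={c: f"demo/fixture/smallrna_{c}.bed"
                      for c in ("control", "salt", "cold", "drought")},
    expression_tsv="demo/fixture/expression.tsv",
    domain_map="demo/fixture/domains.tsv",
    control_condition="control",
    out_dir="demo/out",
))
print(len(result.representatives))   # 79
print(result.groups[0].group_type)   # "one-to-one"
```

## File formats

- **Annotation**: GFF3 with `transcript` and `exon` features; transcript
  attributes `ID`, `locus_id`, `biotype` (closed vocabulary: `CDS-p`,
  `CDS-n`, `ncRNA`, `transposon`, `rRNA`, `tRNA`, `snRNA`, `snoRNA`,
  `miRNA`).
- **Small RNA reads**: BED6, one alignment per line; the score column holds
  the read copy number and the name may carry the read sequence as a
  `_<seq>` suffix (in read orientation).
- **Expression**: TSV with `transcript_id`, `condition`, `fpkm`,
  `fragment_count`, `library_size`.
- **Domains**: TSV mapping `transcript_id` to a semicolon-separated domain
  list.

Coordinates are handled 0-based half-open internally; GFF3 is converted at
the parsing boundary and report locations are printed 1-based inclusive.

## Reproduction

All analyses are deterministic given a seed.

```bash
# full test suite (unit, property, and acceptance tests)
python -m pytest -q

# end-to-end acceptance metrics (headline percentages, oracle agreement,
# planted-truth recovery, closure and determinism checks) as JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Regenerating a fixture with the same seed reproduces every file byte for
byte, and re-running the pipeline on the same inputs reproduces every
report byte for byte; both properties are asserted in the test suite.

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
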