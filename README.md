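# varscreen

Comparative genomic-variant screening for clonal exposure experiments.

`varscreen` answers the question: *did a treatment leave mutations in a
clonal microbial strain, beyond what untreated replicate cultures accumulate
anyway?*  The motivating setting is astrobiology — a desert cyanobacterium
regrown after long-term exposure to space and Mars-like conditions, compared
against three ground-reference replicate cultures — but the machinery applies
to any mutation-accumulation design with one test sample and ≥ 2 untreated
replicates called against a shared reference genome.

## What it computes

Per-sample variant calls (SNVs/InDels from a short-read caller plus
structural variants from paired-end-, long-read- and assembly-based callers)
are merged into one multi-sample call set and pushed through a screening
cascade:

1. **merge** — sequence-resolved records match on the exact
   `(contig, pos, ref, alt)` key; SV records from different callers collapse
   when position, length and END agree within a breakpoint tolerance
   (default 50 bp);
2. **PASS filter** — only records with `FILTER` `PASS` (or `.`) survive;
3. **shared-genotype removal** — a site where *every* sample carries the
   identical called genotype (unphased allele multiset; `0/1` = `1/0`) is
   clonal background predating the treatment and is removed;
4. **SV size limit** — structural variants spanning strictly more than
   10 kbp are dropped (weakly supported calls);
5. **background-SV subtraction** — an SV carried by the test sample that is
   also alt-called in ≥ 1 replicate is background noise; only
   replicate-free test-sample SVs count as treatment-specific.

From the filtered set it derives the comparative summaries: per-sample
counts by class and the variant rate *r* = round(*L*/*n*) bp per variant
(the operational "nucleotide diversity": 1 variant every *r* bp, with *L*
the genome length and *n* the sample's variant count); windowed SNV density
in 50-kbp sectors with a circular bar-plot export; synonymous vs
non-synonymous percentages over coding variants from SnpEff-style `ANN`
annotations; stop-gain reports and affected-gene set intersections; and a
collinearity verdict (inversions, translocations, duplications, coverage
contiguity) over a show-coords-style whole-genome-alignment table, after
unique/repetitive segment classification by reciprocal overlap.

A seeded synthetic-study generator (`varscreen.simulate`) produces the whole
input universe — per-sample VCFs with clonal / replicate-private /
treatment-specific variants and SVs, exact-composition `ANN` annotations,
classification and alignment tables — together with a truth manifest and
closed-form expected outputs, so the entire pipeline is testable end to end.

## Worked example

```
varscreen simulate --seed 5 --outdir sim
# write run.yaml pointing at the generated files:
#   test_sample: space_derivate
#   replicate_samples: [ground_A, ground_B, ground_C]
#   vcfs: [sim/ground_A.vcf, sim/ground_B.vcf, sim/ground_C.vcf, sim/space_derivate.vcf]
#   genome_index: sim/genome_index.tsv
#   coords: sim/coords.tsv
#   outdir: out
varscreen screen --config run.yaml
```

prints (and writes to `out/summary.txt`):

```
comparative variant screen summary
==================================
samples: replicates=['ground_A', 'ground_B', 'ground_C'] test=space_derivate
post-cascade records: 4211
test-sample variants: 3 (replicate range 1402-1405)
test-sample rate: 2124333 bp/variant (replicate mean 4.5 kbp/variant)
variants private to the test sample (non-SV): 0
test-sample SVs surviving background subtraction: 0 (background: 3)
collinearity: collinear (7 unique / 40 repetitive alignments)
```

Reading: the cascade removed 221 non-PASS records, 211 shared-genotype
(clonal) sites and 2 oversized SVs from 4645 merged records.  The default
study conditions plant no treatment effect, so zero variants are private to
the test sample, every test-sample SV is explained by the replicate
background, and the whole-genome alignment shows no rearrangement — the
expected null outcome.  The three SVs the test sample still carries after
the cascade are the background ones shared with replicates.  Each number in
the summary is traceable to a TSV/JSON cell in the report bundle
(`diversity.tsv`, `filter_report.tsv`, `sv_report.tsv`,
`collinearity.json`, ...).

The library surface mirrors the CLI: `read_vcf`, `merge_variant_sets`,
`run_cascade`, `subtract_background_svs`, `diversity_table`, `union_snvs`,
`snv_window_counts`, `coding_effect_percentages`, `affected_gene_sets`,
`classify_segments`, `check_collinearity`, `simulate`, `expected_table`.

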