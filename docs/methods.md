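# Methods

## The screening model

The package implements a *screen*, not an estimator: in a clonal exposure
design, variants observed in a test sample decompose into (a) clonal
differences between the strain and its reference assembly, present in every
sample at the same genotype; (b) culture drift private to individual
replicates; (c) caller noise; and (d) true treatment-induced mutations.
The cascade operationalizes this decomposition with set logic rather than a
statistical model:

* caller noise is addressed by the caller's own `FILTER` flag (only `PASS`
  survives; an unset `.` filter is treated as the conventional unfiltered
  state and counted as PASS, which is logged so users can audit the choice);
* clonal background is removed as the sites where **all** samples share one
  identical, fully called genotype, compared unphased as allele multisets
  (`0/1` = `1/0`).  A site with any missing or partially called genotype is
  kept — the rule speaks of shared genotypes, not shared missingness — so
  per-sample removal counts can differ when callers leave samples uncalled;
* structural variants spanning strictly more than `max_sv_len` (default
  10 000 bp; the boundary value itself survives) are dropped as weakly
  supported — an explicit, reproducible stand-in for manual alignment
  inspection;
* treatment-specific SVs are those carried by the test sample
  (genotype contains ≥ 1 alternate allele; `0/0` and `./.` both count as
  "not carrying") with no replicate alt call *on the same merged record* —
  co-occurrence is defined on the merged call set, with no second fuzzy
  matching pass.

Merging uses two identity notions.  Sequence-resolved records are identical
iff `(contig, pos, ref, alt)` match exactly.  SV callers jitter breakpoints,
so SV records merge when contig, SVTYPE and length sign match and position,
|SVLEN| and END each agree within `sv_breakpoint_tolerance` (default 50 bp,
clustered greedily in input order; the merged record keeps the earliest
position and the union of caller labels).  Multi-allelic sites are split
into biallelic records at read time; a genotype allele pointing at the
*other* alternate becomes an uncalled slot (`1/2` → `1/.` + `./1`), which
keeps per-site counts deterministic.  No indel left-alignment is performed.

Every stage emits a report whose conservation identity
(input = output + removals) is asserted at construction, and every filter is
idempotent; both properties are tested, along with invariance of the result
to the order of the per-sample inputs.

## Summary statistics

* **Variant rate**: round(genome length / variant count), rounding half away
  from zero; undefined (None) at zero variants.  The denominator defaults to
  the full genome index (chromosome + plasmid) because the screen treats the
  whole assembly as the mutational target; it is a parameter for users who
  want chromosome-only rates.
* **Diversity in kbp**: mean of bp-per-variant rates / 1000, one decimal,
  half away from zero.  Count averages use the same rounding.  These
  conventions reproduce the reference study's printed averages from its
  printed per-sample rows (4.8 and 4.1 kbp; 16 insertions, 18 deletions),
  which the acceptance tests pin down.
* **Effect percentages** are computed on the variants whose *primary* (first,
  most severe) `ANN` annotation is coding: synonymous =
  {synonymous, stop/start retained}; non-synonymous = {missense, stop
  gained/lost, start lost}.  The two percentages are rounded independently
  half away from zero and may sum to 99–101; raw fractions are always
  reported alongside rather than forcing them to 100.
* **Affected genes** are genes named in any non-intergenic annotation of a
  carried variant (multi-gene annotations contribute the variant to every
  named gene; sets deduplicate).
* **Window counts** use 0-based half-open windows tiling each contig
  (default 50 kbp, final window short); position p (1-based) falls in window
  ⌊(p−1)/w⌋.  Doubling the window size must merge adjacent windows exactly,
  which is property-tested.  No hotspot threshold is defined — the circular
  plot is descriptive.

## Collinearity

MUMmer-style coordinate tables give segments, not the aligner's internal
uniqueness, so "unique vs repetitive" is re-derived with an explicit rule: a
segment is repetitive iff another segment overlaps its query or ref interval
by more than `overlap_threshold` (default 0.5) of its own length.  On the
unique segments, sorted by reference start: an inversion is a minus-strand
segment; a translocation is an adjacent plus-strand pair whose query order
disagrees with reference order (counting order breakpoints, so k disjoint
swaps yield k events); a duplication is reference-interval overlap beyond
`dup_tolerance` (100 bp); coverage is contiguous when inter-segment gaps are
≤ `gap_tolerance` (1 kbp) and the union spans ≥ 99% of the reference.  These
thresholds are reported in the output header, since the upstream aligner's
own counts cannot be reproduced from the coordinates table alone.

## The synthetic-study generator

`SimConfig` defaults define the study conditions the package is validated
under: a 5 700 000 bp chromosome plus a 673 000 bp plasmid; three replicate
samples and one test sample; 210 clonal shared variants; replicate-private
variants at 2.2 × 10⁻⁴ per bp per sample (≈ 1400 per replicate, the low
thousands typical of this design); no treatment-specific variants (the null
study); eight SVs covering background (test + replicate), replicate-private,
clonal and oversized (> 10 kbp) cases; 5% non-PASS records; variant classes
97% SNV / 1.5% INS / 1.5% DEL; primary effects 30% synonymous / 18%
missense / 1% stop-gain / 51% intergenic (≈ 61% synonymous within coding).

Design choices that make truth arithmetic exact rather than statistical:

* positions are drawn without replacement over the genome (no key
  collisions, margins keep indels and SVs inside contigs);
* class and effect compositions are assigned by stratified deal (largest
  remainder, then shuffle) within each category group, so per-sample
  compositions are exact at any n;
* every variant belongs to exactly one truth category
  (clonal_shared / private / treatment_specific / background_sv /
  oversized_sv / non_pass); `expected_table` computes all pipeline outputs
  — removal counts, per-sample class counts, union cardinality, effect
  percentages, planted rearrangement counts — by closed-form category
  arithmetic, and the end-to-end tests require byte-exact agreement;
* per-caller SV breakpoint jitter (≤ 10 bp) stays below the merge tolerance,
  so each planted SV merges to one record by construction;
* identical seed and config give byte-identical files.

The generator writes genuine VCF/TSV files, and the validation path reads
them back through the same parsers used on real data.  What it does *not*
emulate: read-level error models, mutation spectra, positional clustering,
caller-specific genotype-likelihood behaviour, partially called genotypes in
real multi-sample callers, and breakend (BND) adjacencies.  Passing tests
therefore demonstrate correctness of the screening logic and bookkeeping,
not robustness to upstream caller pathologies.

Randomized recovery sweeps use scaled-down genomes (0.2–0.6 Mbp with
proportional variant loads), the package's chosen problem size for the
20-configuration sweep; the full-size default configuration is exercised in
the null-study test and the acceptance script.

## Numerical and degenerate-input conventions

Rounding is half away from zero everywhere (not banker's).  Undefined
quantities are explicit markers, never silent zeros: rate at zero variants is
None, effect percentages with zero coding variants are None, empty window
tables and empty segment lists refuse to plot/check.  Shared-genotype
filtering requires ≥ 2 samples.  GC content excludes N and ambiguity codes
from the denominator and is undefined on all-ambiguous sequences.
Unclassified contigs are removed by default in lineage filtering (flag to
keep; strict mode errors on contigs missing from the classification).

## Known limitations

* The shared-genotype rule keys on exact genotype equality; a clonal variant
  genotyped inconsistently by the caller (e.g. `0/1` in one sample, `1/1`
  elsewhere) survives the cascade.  This mirrors the screening rule as
  defined, and is the main reason per-sample removal counts differ slightly
  in real data.
* SV merging is greedy single-linkage within tolerance; pathological chains
  of calls each within tolerance of the next could over-merge.  Real
  multi-caller jitter is far below the default tolerance.
* The unique/repetitive segment classification is an explicit reciprocal
  overlap rule, not a reconstruction of any aligner's internal definition;
  its counts are comparable across runs of this package, not across tools.
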