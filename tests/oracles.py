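"""Independent brute-force oracles and random-input builders for the tests.

These re-implement each filtering and counting rule directly from its plain
statement, without sharing code with the package, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np

from varscreen.model import (
    MISSING,
    AlignmentSegment,
    GenomeIndex,
    Genotype,
    VariantClass,
    VariantRecord,
    VariantSet,
)

GT_CHOICES = [
    Genotype((0, 0)),
    Genotype((0, 1)),
    Genotype((1, 0)),
    Genotype((1, 1)),
    Genotype((1, None)),
    MISSING,
]


def random_variant_set(
    rng: np.random.Generator,
    samples: Sequence[str],
    genome: GenomeIndex,
    n: int,
    sv_fraction: float = 0.2,
    fail_fraction: float = 0.2,
) -> VariantSet:
    """A random multi-sample VariantSet with mixed classes, filters, genotypes."""
    total = genome.total_length
    linear = rng.choice(total - 30, size=n, replace=False)
    records = []
    for x in sorted(int(v) for v in linear):
        running = 0
        for name, length in genome.contigs:
            if x < running + length:
                contig, pos = name, x - running + 1
                break
            running += length
        genotypes = {
            s: GT_CHOICES[int(rng.integers(0, len(GT_CHOICES)))] for s in samples
        }
        filt = "PASS" if rng.random() > fail_fraction else "lowq"
        if rng.random() < sv_fraction:
            svtype = ["DEL", "INS", "DUP"][int(rng.integers(0, 3))]
            length_bp = int(rng.integers(50, 15_000))
            svlen = -length_bp if svtype == "DEL" else length_bp
            rec = VariantRecord(
                contig=contig, pos=pos, ref="N", alt=f"<{svtype}>",
                variant_class=VariantClass["SV_" + ("BND" if svtype == "TRA" else svtype)],
                filter=filt, genotypes=genotypes,
                info={"SVTYPE": svtype, "SVLEN": svlen},
            )
        else:
            kind = int(rng.integers(0, 3))
            if kind == 0:
                ref, alt, vc = "A", "G", VariantClass.SNV
            elif kind == 1:
                ref, alt, vc = "A", "AT", VariantClass.INS
            else:
                ref, alt, vc = "AT", "A", VariantClass.DEL
            rec = VariantRecord(
                contig=contig, pos=pos, ref=ref, alt=alt, variant_class=vc,
                filter=filt, genotypes=genotypes,
            )
        records.append(rec)
    vset = VariantSet(tuple(samples), records, genome)
    vset.validate()
    return vset


# ---- filter rules restated literally ---------------------------------------

def carried(gt: Genotype) -> bool:
    return any(a is not None and a >= 1 for a in gt.alleles)


def oracle_pass(vset: VariantSet) -> list[VariantRecord]:
    return [r for r in vset.records if r.filter == "PASS"]


def oracle_shared_genotype_removed(rec: VariantRecord, samples) -> bool:
    gts = [rec.genotype(s) for s in samples]
    if any(any(a is None for a in g.alleles) for g in gts):
        return False
    canon = [tuple(sorted(g.alleles)) for g in gts]
    return all(c == canon[0] for c in canon)


def oracle_sv_size_removed(rec: VariantRecord, max_len: int) -> bool:
    if not rec.variant_class.name.startswith("SV_"):
        return False
    if rec.svlen is not None:
        span = abs(rec.svlen)
    elif rec.end is not None:
        span = rec.end - rec.pos + 1
    else:
        return False
    return span > max_len


def oracle_background_subtraction(
    vset: VariantSet, test: str, reps
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    kept, background = [], []
    for rec in vset.records:
        if not rec.variant_class.name.startswith("SV_"):
            continue
        if not carried(rec.genotype(test)):
            continue
        if any(carried(rec.genotype(r)) for r in reps):
            background.append(rec)
        else:
            kept.append(rec)
    return kept, background


def oracle_count_by_class(vset: VariantSet, sample: str) -> tuple[int, int, int, int, int]:
    tally = Counter(
        r.variant_class for r in vset.records if carried(r.genotype(sample))
    )
    n = sum(tally.values())
    snv = tally[VariantClass.SNV]
    ins = tally[VariantClass.INS]
    dele = tally[VariantClass.DEL]
    return n, snv, ins, dele, n - snv - ins - dele


def oracle_union_snv_cardinality(vset: VariantSet, reps) -> int:
    """Inclusion-exclusion over per-replicate SNV key sets."""
    sets = [
        {r.key for r in vset.records
         if r.variant_class is VariantClass.SNV and carried(r.genotype(s))}
        for s in reps
    ]
    from itertools import combinations

    total = 0
    for k in range(1, len(sets) + 1):
        for combo in combinations(sets, k):
            inter = set.intersection(*combo)
            total += (-1) ** (k + 1) * len(inter)
    return total


def oracle_window_counts(
    positions: Sequence[int], contig_length: int, window_size: int
) -> list[int]:
    n_windows = (contig_length + window_size - 1) // window_size
    counts = [0] * n_windows
    for p in positions:
        counts[(p - 1) // window_size] += 1
    return counts


def oracle_classify_segments(
    segments: Sequence[AlignmentSegment], threshold: float
) -> list[bool]:
    """True per segment iff repetitive, via the O(n^2) overlap rule."""

    def ov(a1, a2, b1, b2):
        return max(0, min(a2, b2) - max(a1, b1) + 1)

    flags = []
    for i, s in enumerate(segments):
        rep = False
        for j, o in enumerate(segments):
            if i == j:
                continue
            if ov(s.query_start, s.query_end, o.query_start, o.query_end) > (
                threshold * (s.query_end - s.query_start + 1)
            ) or ov(s.ref_start, s.ref_end, o.ref_start, o.ref_end) > (
                threshold * (s.ref_end - s.ref_start + 1)
            ):
                rep = True
                break
        flags.append(rep)
    return flags


def oracle_descents(plus_segments: Sequence[AlignmentSegment]) -> int:
    """Order breakpoints: adjacent ref-sorted pairs with descending query."""
    segs = sorted(plus_segments, key=lambda s: s.ref_start)
    return sum(1 for a, b in zip(segs, segs[1:]) if b.query_start < a.query_start)
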