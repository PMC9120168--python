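"""Per-sample diversity statistics.

The operational "nucleotide diversity" here is the simple variant rate:
genome length divided by variant count, i.e. "1 variant every X bp".  The
module builds the per-sample summary table (counts by class, rate), the
averages quoted from it, and the set-theoretic union of replicate SNVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import ModelError, VariantClass, VariantSet


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ClassCounts:
    """Per-sample variant tally grouped by class."""

    n_variants: int
    n_snv: int
    n_ins: int
    n_del: int
    n_other: int


def count_by_class(
    vset: VariantSet, sample: str, include_sv_indels: bool = False
) -> ClassCounts:
    """Count records carried by ``sample`` (genotype has an alt allele).

    INS/DEL count sequence-resolved indels only unless ``include_sv_indels``
    folds SV_INS/SV_DEL into them; everything else lands in ``n_other``.
    """
    if sample not in vset.samples:
        raise ModelError(f"unknown sample {sample!r}")
    n = n_snv = n_ins = n_del = n_other = 0
    ins_classes = {VariantClass.INS}
    del_classes = {VariantClass.DEL}
    if include_sv_indels:
        ins_classes.add(VariantClass.SV_INS)
        del_classes.add(VariantClass.SV_DEL)
    for rec in vset.records:
        if not rec.carried_by(sample):
            continue
        n += 1
        if rec.variant_class is VariantClass.SNV:
            n_snv += 1
        elif rec.variant_class in ins_classes:
            n_ins += 1
        elif rec.variant_class in del_classes:
            n_del += 1
        else:
            n_other += 1
    return ClassCounts(n, n_snv, n_ins, n_del, n_other)


def variant_rate(n_variants: int, genome_length: int) -> Optional[int]:
    """Genome length per variant in bp, rounded half away from zero.

    Returns None (undefined) when there are no variants.
    """
    if n_variants < 0 or genome_length < 1:
        raise ModelError("variant_rate needs n_variants >= 0 and genome_length >= 1")
    if n_variants == 0:
        return None
    return round_half_away(genome_length / n_variants)


def average_diversity_kbp(rates_bp: Sequence[float]) -> float:
    """Mean of bp-per-variant rates expressed in kbp, one decimal place."""
    if not rates_bp:
        raise ModelError("average_diversity_kbp needs at least one rate")
    if any(r <= 0 for r in rates_bp):
        raise ModelError("rates must be positive")
    mean_kbp = sum(rates_bp) / len(rates_bp) / 1000.0
    return round_half_away(mean_kbp * 10) / 10.0


def average_counts(values: Sequence[int]) -> int:
    """Arithmetic mean rounded half away from zero."""
    if not values:
        raise ModelError("average_counts needs a non-empty list")
    return round_half_away(sum(values) / len(values))


def diversity_table(
    vset: VariantSet,
    samples: Optional[Sequence[str]] = None,
    genome_length: Optional[int] = None,
    include_sv_indels: bool = False,
) -> pd.DataFrame:
    """Per-sample summary: variant count, rate (bp/variant) and class counts.

    The rate denominator defaults to the full genome index length
    (chromosome + plasmid); pass ``genome_length`` to restrict it.
    """
    samples = tuple(samples) if samples is not None else vset.samples
    length = genome_length if genome_length is not None else vset.genome.total_length
    rows = []
    for sample in samples:
        c = count_by_class(vset, sample, include_sv_indels=include_sv_indels)
        rows.append(
            {
                "sample": sample,
                "n_variants": c.n_variants,
                "rate_bp": variant_rate(c.n_variants, length),
                "n_snv": c.n_snv,
                "n_ins": c.n_ins,
                "n_del": c.n_del,
                "n_other": c.n_other,
            }
        )
    df = pd.DataFrame(rows)
    # keep the undefined-rate marker as None rather than letting pandas
    # coerce it to NaN
    df["rate_bp"] = df["rate_bp"].astype(object).where(df["rate_bp"].notna(), None)
    return df


def union_snvs(vset: VariantSet, replicate_samples: Sequence[str]) -> VariantSet:
    """SNV records carried by at least one of the given replicates.

    This is the set-theoretic sum of the replicates' SNVs: cardinality obeys
    inclusion-exclusion over the per-replicate SNV sets.
    """
    if not replicate_samples:
        raise ModelError("union_snvs needs at least one replicate")
    unknown = set(replicate_samples) - set(vset.samples)
    if unknown:
        raise ModelError(f"unknown sample name(s): {sorted(unknown)}")
    keep = [
        r
        for r in vset.records
        if r.variant_class is VariantClass.SNV
        and any(r.carried_by(s) for s in replicate_samples)
    ]
    return vset.subset(keep)
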