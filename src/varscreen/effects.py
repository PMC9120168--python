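"""Functional-effect summaries from annotator ANN INFO fields.

The ANN field is the pipe-delimited per-allele annotation emitted by variant
effect annotators (allele|effect|impact|gene_name|gene_id|...), with multiple
annotations comma-separated and ordered by decreasing severity.  Only the
primary (first) annotation determines a variant's effect class; all
annotations contribute to affected-gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .diversity import round_half_away
from .model import ModelError, VariantSet

SYNONYMOUS_TERMS = frozenset(
    {"synonymous_variant", "stop_retained_variant", "start_retained_variant"}
)
NONSYNONYMOUS_TERMS = frozenset(
    {"missense_variant", "stop_gained", "stop_lost", "start_lost"}
)
CODING_TERMS = SYNONYMOUS_TERMS | NONSYNONYMOUS_TERMS
INTERGENIC_TERMS = frozenset({"intergenic_region", "intergenic_variant"})


@dataclass(frozen=True)
class EffectRecord:
    """One parsed annotation for one variant allele."""

    allele: str
    effect_term: str
    impact: str
    gene_name: str
    gene_id: str
    primary: bool

    def __post_init__(self) -> None:
        if not self.effect_term:
            raise ModelError("empty effect term in annotation")

    @property
    def coding(self) -> bool:
        return self.effect_term in CODING_TERMS

    @property
    def intergenic(self) -> bool:
        return self.effect_term in INTERGENIC_TERMS

    @property
    def gene(self) -> str:
        """Preferred gene identifier: gene_id falling back to gene_name."""
        return self.gene_id or self.gene_name


def parse_ann(ann_string: str) -> list[EffectRecord]:
    """Parse an ANN INFO string into one EffectRecord per annotation.

    Effect terms joined with '&' are reduced to the first (most severe) term.
    An empty string yields an empty list; an annotation with fewer than four
    pipe-delimited fields is malformed.
    """
    if not ann_string or not ann_string.strip():
        return []
    records = []
    for i, chunk in enumerate(ann_string.split(",")):
        fields = chunk.split("|")
        if len(fields) < 4:
            raise ModelError(
                f"ANN annotation {i} has {len(fields)} pipe fields, need >= 4: "
                f"{chunk!r}"
            )
        allele, term, impact, gene_name = (f.strip() for f in fields[:4])
        gene_id = fields[4].strip() if len(fields) > 4 else ""
        term = term.split("&")[0]
        records.append(
            EffectRecord(
                allele=allele,
                effect_term=term,
                impact=impact,
                gene_name=gene_name,
                gene_id=gene_id,
                primary=(i == 0),
            )
        )
    return records


@dataclass(frozen=True)
class CodingEffectSummary:
    """Synonymous / non-synonymous split of one sample's coding variants.

    Percentages are rounded independently half away from zero, so they may
    sum to 99-101; the raw fractions are kept alongside.
    """

    sample: str
    n_coding: int
    n_synonymous: int
    n_nonsynonymous: int

    @property
    def frac_synonymous(self) -> float:
        return self.n_synonymous / self.n_coding

    @property
    def frac_nonsynonymous(self) -> float:
        return self.n_nonsynonymous / self.n_coding

    @property
    def pct_synonymous(self) -> int:
        return round_half_away(100.0 * self.frac_synonymous)

    @property
    def pct_nonsynonymous(self) -> int:
        return round_half_away(100.0 * self.frac_nonsynonymous)


def _primary_effect(rec) -> Optional[EffectRecord]:
    ann = rec.ann
    if ann is None:
        return None
    effects = parse_ann(ann)
    return effects[0] if effects else None


def coding_effect_percentages(
    vset: VariantSet, sample: str
) -> Optional[CodingEffectSummary]:
    """Synonymous vs non-synonymous percentages among coding variants.

    The denominator is the set of variants carried by ``sample`` whose
    primary annotation term is coding.  Returns None when the sample carries
    no coding variants (the split is undefined).
    """
    if sample not in vset.samples:
        raise ModelError(f"unknown sample {sample!r}")
    n_syn = n_nonsyn = 0
    for rec in vset.records:
        if not rec.carried_by(sample):
            continue
        primary = _primary_effect(rec)
        if primary is None or not primary.coding:
            continue
        if primary.effect_term in SYNONYMOUS_TERMS:
            n_syn += 1
        else:
            n_nonsyn += 1
    n_coding = n_syn + n_nonsyn
    if n_coding == 0:
        return None
    return CodingEffectSummary(sample, n_coding, n_syn, n_nonsyn)


def stop_gain_report(vset: VariantSet, sample: str) -> pd.DataFrame:
    """Variants carried by ``sample`` whose primary effect is stop_gained.

    Returns a DataFrame (gene, contig, pos, ref, alt, annotations) with one
    row per stop-gain variant, grouped (sorted) by gene.
    """
    if sample not in vset.samples:
        raise ModelError(f"unknown sample {sample!r}")
    rows = []
    for rec in vset.records:
        if not rec.carried_by(sample):
            continue
        primary = _primary_effect(rec)
        if primary is None or primary.effect_term != "stop_gained":
            continue
        labels = ";".join(
            f"{e.effect_term}:{e.gene}" for e in parse_ann(rec.ann or "")
        )
        rows.append(
            {
                "gene": primary.gene,
                "contig": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "annotations": labels,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "contig", "pos", "ref", "alt", "annotations"])
    return df.sort_values(["gene", "contig", "pos"]).reset_index(drop=True)


@dataclass
class GeneHitSets:
    """Per-sample affected-gene sets and the derived comparisons.

    An "affected gene" is any gene named in a non-intergenic annotation of a
    variant the sample carries; multi-gene annotations contribute the variant
    to every named gene.
    """

    per_sample: dict[str, frozenset[str]]
    replicate_samples: tuple[str, ...]
    test_sample: str

    @property
    def all_shared(self) -> frozenset[str]:
        sets = list(self.per_sample.values())
        return frozenset.intersection(*sets) if sets else frozenset()

    @property
    def replicates_shared(self) -> frozenset[str]:
        sets = [self.per_sample[s] for s in self.replicate_samples]
        return frozenset.intersection(*sets) if sets else frozenset()

    @property
    def test_only(self) -> frozenset[str]:
        union = frozenset().union(
            *(self.per_sample[s] for s in self.replicate_samples)
        )
        return self.per_sample[self.test_sample] - union

    def membership_table(self) -> pd.DataFrame:
        genes = sorted(frozenset().union(*self.per_sample.values()))
        data = {
            s: [g in self.per_sample[s] for g in genes] for s in self.per_sample
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def affected_gene_sets(
    vset: VariantSet,
    replicate_samples: Sequence[str],
    test_sample: str,
) -> GeneHitSets:
    """Per-sample sets of genes hit by >= 1 carried, non-intergenic variant."""
    samples = list(replicate_samples) + [test_sample]
    unknown = set(samples) - set(vset.samples)
    if unknown:
        raise ModelError(f"unknown sample name(s): {sorted(unknown)}")
    hits: dict[str, set[str]] = {s: set() for s in samples}
    for rec in vset.records:
        ann = rec.ann
        if ann is None:
            continue
        genes = {
            e.gene for e in parse_ann(ann) if not e.intergenic and e.gene
        }
        if not genes:
            continue
        for s in samples:
            if rec.carried_by(s):
                hits[s].update(genes)
    return GeneHitSets(
        per_sample={s: frozenset(h) for s, h in hits.items()},
        replicate_samples=tuple(replicate_samples),
        test_sample=test_sample,
    )


def effect_table(
    vset: VariantSet, samples: Sequence[str]
) -> pd.DataFrame:
    """Per-sample coding effect summary as a DataFrame (TSV-ready)."""
    rows = []
    for s in samples:
        summary = coding_effect_percentages(vset, s)
        if summary is None:
            rows.append({"sample": s, "n_coding": 0, "n_synonymous": 0,
                         "n_nonsynonymous": 0, "pct_synonymous": None,
                         "pct_nonsynonymous": None, "frac_synonymous": None,
                         "frac_nonsynonymous": None})
        else:
            rows.append(
                {
                    "sample": s,
                    "n_coding": summary.n_coding,
                    "n_synonymous": summary.n_synonymous,
                    "n_nonsynonymous": summary.n_nonsynonymous,
                    "pct_synonymous": summary.pct_synonymous,
                    "pct_nonsynonymous": summary.pct_nonsynonymous,
                    "frac_synonymous": summary.frac_synonymous,
                    "frac_nonsynonymous": summary.frac_nonsynonymous,
                }
            )
    return pd.DataFrame(rows)
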