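"""The variant filtering cascade.

Per-sample and per-caller call sets are merged into a single multi-sample
:class:`~varscreen.model.VariantSet`, then filtered in order: keep PASS,
remove sites at which every sample carries the identical called genotype
(clonal background predating the treatment), drop oversized structural
variants, and — for the SV report — subtract background-noise SVs that also
occur in untreated replicates.

Every stage returns a :class:`FilterReport` whose conservation invariant
(input = output + removals) is asserted on construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    MISSING,
    GenomeIndex,
    Genotype,
    ModelError,
    VariantClass,
    VariantRecord,
    VariantSet,
)

log = logging.getLogger(__name__)

RULE_NOT_PASS = "not_pass"
RULE_SHARED_GENOTYPE = "shared_genotype"
RULE_SV_TOO_LONG = "sv_too_long"
RULE_BACKGROUND_SV = "background_sv"
RULES = (RULE_NOT_PASS, RULE_SHARED_GENOTYPE, RULE_SV_TOO_LONG, RULE_BACKGROUND_SV)

DEFAULT_MAX_SV_LEN = 10_000
DEFAULT_SV_TOLERANCE = 50


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage."""

    stage: str
    input_count: int
    removed_by_rule: dict[str, int]
    output_count: int
    removed_keys: dict[str, list[tuple]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = sum(self.removed_by_rule.values())
        if self.input_count - removed != self.output_count:
            raise ModelError(
                f"{self.stage}: conservation violated "
                f"({self.input_count} - {removed} != {self.output_count})"
            )
        unknown = set(self.removed_by_rule) - set(RULES)
        if unknown:
            raise ModelError(f"{self.stage}: unknown rule names {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "input_count": self.input_count,
            "removed_by_rule": dict(self.removed_by_rule),
            "output_count": self.output_count,
        }


def write_reports(reports: Sequence[FilterReport], tsv_path: str | Path,
                  json_path: Optional[str | Path] = None) -> None:
    """Emit a chain of filter reports as TSV (and optionally JSON)."""
    lines = ["stage\tinput\trule\tremoved\toutput"]
    for rep in reports:
        rules = rep.removed_by_rule or {"-": 0}
        for rule, n in rules.items():
            lines.append(f"{rep.stage}\t{rep.input_count}\t{rule}\t{n}\t{rep.output_count}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([rep.to_dict() for rep in reports], indent=2) + "\n"
        )


def _sv_cluster_key(rec: VariantRecord) -> tuple:
    sign = 0
    if rec.svlen is not None:
        sign = (rec.svlen > 0) - (rec.svlen < 0)
    return (rec.contig, rec.info.get("SVTYPE"), sign)


def _sv_match(a: VariantRecord, b: VariantRecord, tol: int) -> bool:
    """Breakpoint-jitter SV identity: same contig/type/sign, coordinates within tol."""
    if _sv_cluster_key(a) != _sv_cluster_key(b):
        return False
    if abs(a.pos - b.pos) > tol:
        return False
    la, lb = a.sv_span, b.sv_span
    if la is not None and lb is not None and abs(la - lb) > tol:
        return False
    if a.end is not None and b.end is not None and abs(a.end - b.end) > tol:
        return False
    return True


def _merge_genotype(current: Genotype, incoming: Genotype) -> Genotype:
    """Prefer a called genotype; first caller wins on conflicting calls."""
    return incoming if current.is_missing else current


def merge_variant_sets(
    per_sample_sets: Sequence[VariantSet],
    genome: GenomeIndex,
    sv_breakpoint_tolerance: int = DEFAULT_SV_TOLERANCE,
) -> VariantSet:
    """Merge call sets into one multi-sample set over the union of samples.

    Sequence-resolved records match on the exact (contig, pos, ref, alt) key;
    SV records from different callers match within ``sv_breakpoint_tolerance``
    bp on position, length and END (same type and length sign), collapsing to
    one record that keeps the earliest position and the union of caller
    labels.  A sample without a call at a merged site receives MISSING.
    """
    all_samples: list[str] = []
    for vset in per_sample_sets:
        if vset.genome != genome:
            raise ModelError("input variant set bound to a different genome index")
        for s in vset.samples:
            if s in all_samples:
                raise ModelError(f"duplicate sample name across inputs: {s!r}")
            all_samples.append(s)
    samples = tuple(all_samples)

    seq_merged: dict[tuple, VariantRecord] = {}
    sv_clusters: dict[tuple, list[VariantRecord]] = {}

    def blank(rec: VariantRecord) -> VariantRecord:
        return VariantRecord(
            contig=rec.contig,
            pos=rec.pos,
            ref=rec.ref,
            alt=rec.alt,
            variant_class=rec.variant_class,
            filter=rec.filter,
            genotypes={s: MISSING for s in samples},
            info=dict(rec.info),
            origin_callers=tuple(rec.origin_callers),
        )

    for vset in per_sample_sets:
        for rec in vset.records:
            if rec.is_sv:
                cluster = sv_clusters.setdefault(_sv_cluster_key(rec), [])
                target = None
                for existing in cluster:
                    if _sv_match(existing, rec, sv_breakpoint_tolerance):
                        target = existing
                        break
                if target is None:
                    target = blank(rec)
                    cluster.append(target)
                else:
                    if rec.pos < target.pos:
                        target.pos = rec.pos
                        target.ref, target.alt = rec.ref, rec.alt
                        target.info.update(
                            {k: v for k, v in rec.info.items() if k != "ANN"}
                        )
                    merged_callers = set(target.origin_callers) | set(rec.origin_callers)
                    target.origin_callers = tuple(sorted(merged_callers))
            else:
                target = seq_merged.get(rec.key)
                if target is None:
                    target = blank(rec)
                    seq_merged[rec.key] = target
            for s in vset.samples:
                target.genotypes[s] = _merge_genotype(
                    target.genotypes[s], rec.genotype(s)
                )

    records = list(seq_merged.values())
    for cluster in sv_clusters.values():
        records.extend(cluster)
    merged = VariantSet(samples, records, genome)
    merged.validate()
    return merged


def filter_pass(vset: VariantSet) -> tuple[VariantSet, FilterReport]:
    """Keep only PASS records (FILTER "." counts as PASS at read time)."""
    kept = [r for r in vset.records if r.is_pass]
    removed = [r for r in vset.records if not r.is_pass]
    report = FilterReport(
        stage="filter_pass",
        input_count=len(vset),
        removed_by_rule={RULE_NOT_PASS: len(removed)},
        output_count=len(kept),
        removed_keys={RULE_NOT_PASS: [r.key for r in removed]},
    )
    return vset.subset(kept), report


def remove_shared_genotype(vset: VariantSet) -> tuple[VariantSet, FilterReport]:
    """Remove sites at which all samples share one identical called genotype.

    A record is removed iff every sample's genotype is fully called and all
    genotypes are equal under unphased comparison (allele multiset; 0/1 equals
    1/0).  Records with any missing or partial genotype are kept — the rule
    speaks of shared genotypes, not shared missingness.  Requires >= 2
    samples; with one sample the rule is undefined.
    """
    if len(vset.samples) < 2:
        raise ModelError("shared-genotype filtering needs at least 2 samples")
    kept, removed = [], []
    n_all_missing = 0
    for rec in vset.records:
        gts = [rec.genotype(s) for s in vset.samples]
        multisets = [g.allele_multiset() for g in gts]
        if all(m is not None for m in multisets) and len(set(multisets)) == 1:
            removed.append(rec)
        else:
            if all(g.is_missing for g in gts):
                n_all_missing += 1
            kept.append(rec)
    if n_all_missing:
        log.warning(
            "remove_shared_genotype: %d record(s) uncalled in every sample were kept",
            n_all_missing,
        )
    report = FilterReport(
        stage="remove_shared_genotype",
        input_count=len(vset),
        removed_by_rule={RULE_SHARED_GENOTYPE: len(removed)},
        output_count=len(kept),
        removed_keys={RULE_SHARED_GENOTYPE: [r.key for r in removed]},
    )
    return vset.subset(kept), report


def filter_sv_size(
    vset: VariantSet, max_sv_len: int = DEFAULT_MAX_SV_LEN
) -> tuple[VariantSet, FilterReport]:
    """Drop structural variants spanning strictly more than ``max_sv_len`` bp.

    The span is |SVLEN|, or END - pos + 1 when SVLEN is absent.  The boundary
    is strict: a 10 000 bp SV survives the default threshold.  Non-SV records
    are never removed.
    """
    kept, removed = [], []
    for rec in vset.records:
        span = rec.sv_span if rec.is_sv else None
        if span is not None and span > max_sv_len:
            removed.append(rec)
        else:
            kept.append(rec)
    report = FilterReport(
        stage="filter_sv_size",
        input_count=len(vset),
        removed_by_rule={RULE_SV_TOO_LONG: len(removed)},
        output_count=len(kept),
        removed_keys={RULE_SV_TOO_LONG: [r.key for r in removed]},
    )
    return vset.subset(kept), report


def subtract_background_svs(
    vset: VariantSet,
    test_sample: str,
    replicate_samples: Sequence[str],
) -> tuple[VariantSet, FilterReport]:
    """Restrict SVs to those carried by the test sample and by no replicate.

    An SV carried by the test sample (genotype contains an alternate allele)
    that is also alt-called in at least one replicate is background noise —
    it predates the treatment.  Homozygous-reference and missing genotypes
    count as "not carrying".  Returns only the surviving test-specific SVs.
    """
    unknown = ({test_sample} | set(replicate_samples)) - set(vset.samples)
    if unknown:
        raise ModelError(f"unknown sample name(s): {sorted(unknown)}")
    if test_sample in replicate_samples:
        raise ModelError("test sample cannot also be a replicate")
    test_svs = [r for r in vset.records if r.is_sv and r.carried_by(test_sample)]
    kept, background = [], []
    for rec in test_svs:
        if any(rec.carried_by(s) for s in replicate_samples):
            background.append(rec)
        else:
            kept.append(rec)
    report = FilterReport(
        stage="subtract_background_svs",
        input_count=len(test_svs),
        removed_by_rule={RULE_BACKGROUND_SV: len(background)},
        output_count=len(kept),
        removed_keys={RULE_BACKGROUND_SV: [r.key for r in background]},
    )
    return vset.subset(kept), report


@dataclass(frozen=True)
class CascadeConfig:
    """Sample roles and thresholds for :func:`run_cascade`."""

    test_sample: str
    replicate_samples: tuple[str, ...]
    max_sv_len: int = DEFAULT_MAX_SV_LEN
    sv_breakpoint_tolerance: int = DEFAULT_SV_TOLERANCE


def run_cascade(
    per_sample_sets: Sequence[VariantSet],
    genome: GenomeIndex,
    config: CascadeConfig,
) -> tuple[VariantSet, list[FilterReport]]:
    """merge -> keep PASS -> remove shared genotypes -> drop oversized SVs.

    Background-SV subtraction is a reporting step on the cascade output (it
    restricts to the test sample) and is exposed separately via
    :func:`subtract_background_svs`.
    """
    merged = merge_variant_sets(
        per_sample_sets, genome, sv_breakpoint_tolerance=config.sv_breakpoint_tolerance
    )
    reports: list[FilterReport] = []
    vset, rep = filter_pass(merged)
    reports.append(rep)
    vset, rep = remove_shared_genotype(vset)
    reports.append(rep)
    vset, rep = filter_sv_size(vset, max_sv_len=config.max_sv_len)
    reports.append(rep)
    for r in reports:
        log.info(
            "%s: %d -> %d (%s)",
            r.stage, r.input_count, r.output_count, dict(r.removed_by_rule),
        )
    return vset, reports


def private_to_sample(vset: VariantSet, sample: str) -> list[VariantRecord]:
    """Records carried by ``sample`` and by no other sample in the set."""
    if sample not in vset.samples:
        raise ModelError(f"unknown sample {sample!r}")
    others = [s for s in vset.samples if s != sample]
    return [
        r
        for r in vset.records
        if r.carried_by(sample) and not any(r.carried_by(o) for o in others)
    ]
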