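"""Seeded generator of a full synthetic screening study.

The generator emulates a clonal exposure experiment: three replicate
cultures of an untreated reference strain plus one test sample (a derivative
regrown after the exposure), all called against one reference genome of a
~Mbp chromosome plus a plasmid.  It produces per-sample VCFs containing

* clonal variants shared by every sample at identical genotype (pre-existing
  differences from the reference assembly),
* replicate-private variants at a configurable per-bp rate (culture drift),
* optional treatment-specific variants present only in the test sample,
* structural variants of several types and sizes, including oversized ones
  and ones shared between the test sample and replicates (background), and
* annotation (ANN) strings with an exactly known
  synonymous/missense/stop-gain/intergenic composition,

together with a genome index, a contig classification table, a whole-genome
alignment coordinates table with planted rearrangements, and a
:class:`TruthManifest` labelling every variant.  Compositions are assigned
by stratified deal (largest remainder), not i.i.d. draws, so category
arithmetic — and hence :func:`expected_table` — is exact, not in
expectation.  Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .diversity import round_half_away
from .model import (
    AlignmentSegment,
    ContigClassification,
    GenomeIndex,
    Genotype,
    ModelError,
    VariantClass,
    VariantRecord,
    VariantSet,
    classify_variant,
)

_BASES = "ACGT"
_CALLERS = ("delly", "sniffles", "assemblytics")
_SV_ALT = {"DEL": "<DEL>", "INS": "<INS>", "DUP": "<DUP>", "INV": "<INV>"}

CAT_CLONAL = "clonal_shared"
CAT_PRIVATE = "private"
CAT_TREATMENT = "treatment_specific"
CAT_BACKGROUND_SV = "background_sv"
CAT_OVERSIZED_SV = "oversized_sv"
CAT_NON_PASS = "non_pass"


@dataclass(frozen=True)
class SvSpec:
    """One structural variant to plant: type, span and carrying samples."""

    svtype: str
    length: int
    carriers: tuple[str, ...]
    shared_all: bool = False  # identical genotype in every sample (clonal)


def _default_sv_specs() -> tuple[SvSpec, ...]:
    reps = ("ground_A", "ground_B", "ground_C")
    test = "space_derivate"
    return (
        # background: carried by the test sample and >= 1 replicate
        SvSpec("DEL", 2_000, (test, reps[0])),
        SvSpec("DUP", 1_500, (test, reps[1])),
        SvSpec("INS", 900, (test, reps[0], reps[1])),
        # replicate-private SVs (culture drift)
        SvSpec("DEL", 1_200, (reps[0],)),
        SvSpec("DUP", 3_000, (reps[1],)),
        # clonal SV, identical genotype everywhere -> shared-genotype removal
        SvSpec("DEL", 2_500, reps + (test,), shared_all=True),
        # oversized SVs, dropped by the size rule
        SvSpec("DEL", 15_000, (test,)),
        SvSpec("DUP", 12_000, (reps[1],)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic screening experiment.

    Defaults mirror the magnitudes of a ~5.7 Mbp cyanobacterial chromosome
    plus a 673 kbp plasmid screened across three ground replicates and one
    test sample, with a few hundred clonal variants and a per-sample private
    load in the low thousands.
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (
        ("chromosome", 5_700_000),
        ("plasmid", 673_000),
    )
    replicate_samples: tuple[str, ...] = ("ground_A", "ground_B", "ground_C")
    test_sample: str = "space_derivate"
    n_clonal_shared: int = 210
    private_rate: float = 2.2e-4  # replicate-private variants per bp per sample
    n_treatment_specific: int = 0
    sv_specs: tuple[SvSpec, ...] = field(default_factory=_default_sv_specs)
    # exact composition of sequence-resolved variants: SNV, INS, DEL
    class_composition: tuple[float, float, float] = (0.97, 0.015, 0.015)
    # exact composition of primary effects:
    # synonymous, missense, stop_gained, intergenic
    ann_composition: tuple[float, float, float, float] = (0.30, 0.18, 0.01, 0.51)
    fail_fraction: float = 0.05
    sv_jitter: int = 10  # per-caller breakpoint jitter, < merge tolerance
    max_sv_len: int = 10_000  # size threshold used for category labelling
    gene_length: int = 2_000  # gene-id granularity for ANN gene assignment
    # whole-genome alignment table
    n_alignment_segments: int = 7
    n_inversions: int = 0
    n_translocations: int = 0
    n_repeat_pairs: int = 20
    # classification table
    target_lineage: tuple[str, ...] = (
        "root", "cellular organisms", "Bacteria", "Cyanobacteria",
    )
    contaminant_lineages: tuple[tuple[str, ...], ...] = (
        ("root", "cellular organisms", "Bacteria", "Proteobacteria"),
        ("root", "cellular organisms", "Bacteria", "Proteobacteria"),
        ("root", "cellular organisms", "Bacteria", "Bacteroidetes"),
    )
    emit_fasta: bool = False

    def __post_init__(self) -> None:
        if self.n_clonal_shared < 0 or self.n_treatment_specific < 0:
            raise ModelError("variant counts must be >= 0")
        if not (0.0 <= self.fail_fraction < 1.0):
            raise ModelError("fail_fraction must be in [0, 1)")
        for frac_set in (self.class_composition, self.ann_composition):
            if any(f < 0 for f in frac_set) or sum(frac_set) > 1.0 + 1e-9:
                raise ModelError("composition fractions must be >= 0 and sum <= 1")
        if 3 * self.n_translocations + self.n_inversions > self.n_alignment_segments:
            raise ModelError("too many planted rearrangements for the segment count")
        for spec in self.sv_specs:
            if spec.shared_all and spec.length > self.max_sv_len:
                raise ModelError(
                    "a clonal (shared_all) SV must not exceed max_sv_len: "
                    "categories would overlap"
                )

    @property
    def samples(self) -> tuple[str, ...]:
        return self.replicate_samples + (self.test_sample,)

    @property
    def genome(self) -> GenomeIndex:
        return GenomeIndex.from_pairs(self.contigs)

    @property
    def n_private_per_sample(self) -> int:
        return round_half_away(self.private_rate * self.genome.total_length)

    @property
    def n_fail(self) -> int:
        n_core = (
            self.n_clonal_shared
            + self.n_private_per_sample * len(self.replicate_samples)
            + self.n_treatment_specific
        )
        return round_half_away(self.fail_fraction * n_core)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one generated variant."""

    key: tuple
    category: str
    sample: Optional[str]  # owner for private / non_pass records
    variant_class: VariantClass
    effect_term: Optional[str]
    gene: Optional[str]


@dataclass
class TruthManifest:
    records: list[TruthRecord]

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.category == category]

    def count(self, category: str, sample: Optional[str] = None) -> int:
        return sum(
            1
            for r in self.records
            if r.category == category and (sample is None or r.sample == sample)
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["key\tcategory\tsample\tvariant_class\teffect_term\tgene"]
        for r in self.records:
            key = ":".join(str(k) for k in r.key)
            lines.append(
                f"{key}\t{r.category}\t{r.sample or '.'}\t{r.variant_class.value}"
                f"\t{r.effect_term or '.'}\t{r.gene or '.'}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass
class SimBundle:
    """Everything one synthetic study comprises, in memory."""

    config: SimConfig
    genome: GenomeIndex
    per_sample_sets: list[VariantSet]
    manifest: TruthManifest
    classifications: list[ContigClassification]
    segments: list[AlignmentSegment]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer apportionment of n by fractions (largest-remainder method)."""
    raw = [n * f for f in fractions]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    order = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - base[i], -i), reverse=True
    )
    for i in order[:short]:
        base[i] += 1
    return base


def _deal(n: int, fractions: Sequence[float], labels: Sequence[str],
          rng: np.random.Generator) -> list[str]:
    """Assign labels to n items matching fractions exactly, shuffled."""
    counts = _largest_remainder(n, fractions)
    items = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(items)
    return items


_EFFECT_LABELS = ("synonymous_variant", "missense_variant", "stop_gained",
                  "intergenic_region")
_EFFECT_IMPACT = {
    "synonymous_variant": "LOW",
    "missense_variant": "MODERATE",
    "stop_gained": "HIGH",
    "intergenic_region": "MODIFIER",
}
_CLASS_LABELS = ("SNV", "INS", "DEL")


class _PositionPool:
    """Distinct genomic positions, drawn without replacement."""

    def __init__(self, genome: GenomeIndex, rng: np.random.Generator, n: int,
                 margin: int = 25) -> None:
        self._genome = genome
        offsets = {}
        running = 0
        for name, length in genome.contigs:
            offsets[name] = running
            running += length
        self._offsets = offsets
        total = genome.total_length
        if n * 2 > total:
            raise ModelError("requested variant count exceeds genome capacity")
        # oversample, then drop positions too close to a contig end
        draw = min(total, n * 2 + 200)
        linear = rng.choice(total, size=draw, replace=False)
        keep = []
        bounds = [(offsets[name], offsets[name] + length)
                  for name, length in genome.contigs]
        for x in linear:
            for lo, hi in bounds:
                if lo <= x < hi:
                    if x - lo >= 1 and hi - x > margin:
                        keep.append(int(x))
                    break
        if len(keep) < n:
            raise ModelError("requested variant count exceeds genome capacity")
        self._linear = keep
        self._i = 0

    def take(self) -> tuple[str, int, int]:
        """Return (contig, 1-based pos, linear position)."""
        x = self._linear[self._i]
        self._i += 1
        for name, length in self._genome.contigs:
            lo = self._offsets[name]
            if lo <= x < lo + length:
                return name, x - lo + 1, x
        raise AssertionError("linear position outside genome")


def _ann_string(alt: str, term: str, gene: str) -> str:
    impact = _EFFECT_IMPACT[term]
    if term == "intergenic_region":
        return f"{alt}|{term}|{impact}||||||"
    return (
        f"{alt}|{term}|{impact}|{gene}|{gene}|transcript|{gene}.t1|"
        "protein_coding|1/1|c.1A>G"
    )


def simulate(config: SimConfig) -> SimBundle:
    """Generate the full synthetic study for one seed/config, in memory."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    samples = config.samples
    reps = config.replicate_samples
    test = config.test_sample

    n_priv = config.n_private_per_sample
    groups: list[tuple[str, Optional[str], int]] = [(CAT_CLONAL, None,
                                                     config.n_clonal_shared)]
    groups += [(CAT_PRIVATE, s, n_priv) for s in reps]
    groups.append((CAT_TREATMENT, test, config.n_treatment_specific))
    n_fail = config.n_fail
    n_small = sum(n for _, _, n in groups) + n_fail

    pool = _PositionPool(genome, rng, n_small + len(config.sv_specs) + 8)

    per_sample_records: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    truth: list[TruthRecord] = []

    def add_small(category: str, owner: Optional[str], vclass_label: str,
                  term: str, filt: str) -> None:
        contig, pos, linear = pool.take()
        base = _BASES[rng.integers(0, 4)]
        if vclass_label == "SNV":
            ref = base
            alt = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
        elif vclass_label == "INS":
            ref = base
            ins = "".join(_BASES[rng.integers(0, 4)]
                          for _ in range(int(rng.integers(1, 4))))
            alt = base + ins
        else:  # DEL
            tail = "".join(_BASES[rng.integers(0, 4)]
                           for _ in range(int(rng.integers(1, 4))))
            ref = base + tail
            alt = base
        gene = None
        if term != "intergenic_region":
            gene = f"gene{linear // config.gene_length:05d}"
        ann = _ann_string(alt, term, gene or "")
        info = {"ANN": ann}
        vclass = classify_variant(ref, alt, info)
        if category == CAT_CLONAL:
            carriers = samples
        elif owner is not None:
            carriers = (owner,)
        else:
            carriers = samples
        for s in carriers:
            per_sample_records[s].append(
                VariantRecord(
                    contig=contig, pos=pos, ref=ref, alt=alt,
                    variant_class=vclass, filter=filt,
                    genotypes={s: Genotype((1, 1))},
                    info=dict(info), origin_callers=("shortread",),
                )
            )
        truth.append(
            TruthRecord((contig, pos, ref, alt), category, owner, vclass, term, gene)
        )

    for category, owner, n in groups:
        classes = _deal(n, config.class_composition, _CLASS_LABELS, rng)
        effects = _deal(n, config.ann_composition, _EFFECT_LABELS, rng)
        for vclass_label, term in zip(classes, effects):
            add_small(category, owner, vclass_label, term, "PASS")

    # non-PASS records, cycled over samples so every input file sees some
    fail_classes = _deal(n_fail, config.class_composition, _CLASS_LABELS, rng)
    fail_effects = _deal(n_fail, config.ann_composition, _EFFECT_LABELS, rng)
    for i, (vclass_label, term) in enumerate(zip(fail_classes, fail_effects)):
        owner = samples[i % len(samples)]
        add_small(CAT_NON_PASS, owner, vclass_label, term, "LowQual")

    # structural variants, with per-caller breakpoint jitter below tolerance
    chrom_name, chrom_len = config.contigs[0]
    used_sv_pos: list[int] = []
    for spec in config.sv_specs:
        while True:
            base_pos = int(rng.integers(1000, chrom_len - spec.length
                                        - config.sv_jitter - 1000))
            if all(abs(base_pos - p) > spec.length + 2 * config.sv_jitter + 10
                   for p in used_sv_pos):
                break
        used_sv_pos.append(base_pos)
        svlen = -spec.length if spec.svtype == "DEL" else spec.length
        if spec.length > config.max_sv_len:
            category = CAT_OVERSIZED_SV
        elif spec.shared_all:
            category = CAT_CLONAL
        elif test in spec.carriers and any(r in spec.carriers for r in reps):
            category = CAT_BACKGROUND_SV
        elif spec.carriers == (test,):
            category = CAT_TREATMENT
        else:
            category = CAT_PRIVATE
        owner = spec.carriers[0] if category == CAT_PRIVATE else None
        for j, s in enumerate(spec.carriers):
            jitter = 0 if j == 0 else int(rng.integers(0, config.sv_jitter + 1))
            pos = base_pos + jitter
            end = pos + spec.length if spec.svtype != "INS" else pos
            caller = _CALLERS[int(rng.integers(0, len(_CALLERS)))]
            per_sample_records[s].append(
                VariantRecord(
                    contig=chrom_name, pos=pos, ref="N",
                    alt=_SV_ALT[spec.svtype],
                    variant_class=classify_variant(
                        "N", _SV_ALT[spec.svtype], {"SVTYPE": spec.svtype}
                    ),
                    filter="PASS",
                    genotypes={s: Genotype((1, 1))},
                    info={"SVTYPE": spec.svtype, "SVLEN": svlen, "END": end},
                    origin_callers=(caller,),
                )
            )
        truth.append(
            TruthRecord(
                (chrom_name, base_pos, spec.svtype, spec.length),
                category, owner,
                classify_variant("N", _SV_ALT[spec.svtype],
                                 {"SVTYPE": spec.svtype}),
                None, None,
            )
        )

    per_sample_sets = [
        VariantSet((s,), per_sample_records[s], genome) for s in samples
    ]
    for vset in per_sample_sets:
        vset.validate()

    classifications = _make_classifications(config)
    segments = _make_segments(config)
    return SimBundle(
        config=config,
        genome=genome,
        per_sample_sets=per_sample_sets,
        manifest=TruthManifest(truth),
        classifications=classifications,
        segments=segments,
    )


def _make_classifications(config: SimConfig) -> list[ContigClassification]:
    rows = [
        ContigClassification(name, config.target_lineage[-1], config.target_lineage)
        for name, _ in config.contigs
    ]
    for i, lineage in enumerate(config.contaminant_lineages, start=1):
        rows.append(ContigClassification(f"contaminant_{i}", lineage[-1], lineage))
    return rows


def _make_segments(config: SimConfig) -> list[AlignmentSegment]:
    """Tile the chromosome with unique segments, plant rearrangements and repeats.

    Translocations are disjoint adjacent query swaps (one order breakpoint
    each, at segment indices 0, 3, 6, ...); inversions flip the strand of
    segments taken from the tail.  Repeats are pairs of identical short
    segments, repetitive by construction while leaving the tiling unique.
    """
    _, chrom_len = config.contigs[0]
    n = config.n_alignment_segments
    bounds = [round(i * chrom_len / n) for i in range(n + 1)]
    tiles = [(bounds[i] + 1, bounds[i + 1]) for i in range(n)]
    query = list(tiles)
    for k in range(config.n_translocations):
        i = 3 * k
        query[i], query[i + 1] = query[i + 1], query[i]
    strands = ["+"] * n
    for k in range(config.n_inversions):
        strands[n - 1 - k] = "-"
    segments = [
        AlignmentSegment(rs, re_, qs, qe, strand, 0.999)
        for (rs, re_), (qs, qe), strand in zip(tiles, query, strands)
    ]
    repeat_len = 1_000
    for k in range(config.n_repeat_pairs):
        start = 1 + (k * 2 + 1) * repeat_len
        seg = AlignmentSegment(start, start + repeat_len - 1,
                               start, start + repeat_len - 1, "+", 0.95)
        segments.append(seg)
        segments.append(seg)
    return segments


@dataclass(frozen=True)
class ExpectedSampleCounts:
    n_variants: int
    n_snv: int
    n_ins: int
    n_del: int
    n_other: int
    n_coding: int
    n_synonymous: int
    n_nonsynonymous: int
    n_stop_gain: int

    @property
    def pct_synonymous(self) -> Optional[int]:
        if self.n_coding == 0:
            return None
        return round_half_away(100.0 * self.n_synonymous / self.n_coding)

    @property
    def pct_nonsynonymous(self) -> Optional[int]:
        if self.n_coding == 0:
            return None
        return round_half_away(100.0 * self.n_nonsynonymous / self.n_coding)


@dataclass(frozen=True)
class SimExpectation:
    """Closed-form post-cascade expectations from category arithmetic."""

    merged_count: int
    removed_not_pass: int
    removed_shared_genotype: int
    removed_sv_too_long: int
    output_count: int
    per_sample: dict[str, ExpectedSampleCounts]
    union_snv_count: int
    test_specific_count: int
    background_sv_count: int
    test_specific_sv_count: int
    n_inversions: int
    n_translocations: int


def expected_table(config: SimConfig) -> SimExpectation:
    """Expected pipeline outputs, derived without running the generator."""
    reps = config.replicate_samples
    test = config.test_sample
    n_priv = config.n_private_per_sample
    n_treat = config.n_treatment_specific

    sv_cat: dict[str, list[SvSpec]] = {
        CAT_OVERSIZED_SV: [], CAT_CLONAL: [], CAT_BACKGROUND_SV: [],
        CAT_TREATMENT: [], CAT_PRIVATE: [],
    }
    for spec in config.sv_specs:
        if spec.length > config.max_sv_len:
            sv_cat[CAT_OVERSIZED_SV].append(spec)
        elif spec.shared_all:
            sv_cat[CAT_CLONAL].append(spec)
        elif test in spec.carriers and any(r in spec.carriers for r in reps):
            sv_cat[CAT_BACKGROUND_SV].append(spec)
        elif spec.carriers == (test,):
            sv_cat[CAT_TREATMENT].append(spec)
        else:
            sv_cat[CAT_PRIVATE].append(spec)

    n_fail = config.n_fail
    n_small = config.n_clonal_shared + n_priv * len(reps) + n_treat + n_fail
    merged = n_small + len(config.sv_specs)
    removed_shared = config.n_clonal_shared + len(sv_cat[CAT_CLONAL])
    removed_size = len(sv_cat[CAT_OVERSIZED_SV])
    surviving_svs = (
        sv_cat[CAT_BACKGROUND_SV] + sv_cat[CAT_TREATMENT] + sv_cat[CAT_PRIVATE]
    )
    output = n_priv * len(reps) + n_treat + len(surviving_svs)

    def group_counts(n: int) -> tuple[list[int], list[int]]:
        return (
            _largest_remainder(n, config.class_composition),
            _largest_remainder(n, config.ann_composition),
        )

    per_sample: dict[str, ExpectedSampleCounts] = {}
    for s in config.samples:
        n_group = n_priv if s in reps else n_treat
        classes, effects = group_counts(n_group)
        n_other = sum(1 for spec in surviving_svs if s in spec.carriers)
        syn, mis, stop = effects[0], effects[1], effects[2]
        per_sample[s] = ExpectedSampleCounts(
            n_variants=n_group + n_other,
            n_snv=classes[0],
            n_ins=classes[1],
            n_del=classes[2],
            n_other=n_other,
            n_coding=syn + mis + stop,
            n_synonymous=syn,
            n_nonsynonymous=mis + stop,
            n_stop_gain=stop,
        )

    union_snv = sum(per_sample[s].n_snv for s in reps)
    return SimExpectation(
        merged_count=merged,
        removed_not_pass=n_fail,
        removed_shared_genotype=removed_shared,
        removed_sv_too_long=removed_size,
        output_count=output,
        per_sample=per_sample,
        union_snv_count=union_snv,
        test_specific_count=n_treat,
        background_sv_count=len(sv_cat[CAT_BACKGROUND_SV]),
        test_specific_sv_count=len(sv_cat[CAT_TREATMENT]),
        n_inversions=config.n_inversions,
        n_translocations=config.n_translocations,
    )


def generate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle to ``outdir``; returns artifact paths.

    Artifacts: one VCF per sample, genome_index.tsv, truth_manifest.tsv,
    classification.tsv, coords.tsv and (optionally) contigs.fasta.
    """
    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate(config)
    paths: dict[str, Path] = {}
    for vset in bundle.per_sample_sets:
        sample = vset.samples[0]
        paths[f"vcf:{sample}"] = vio.write_vcf(vset, outdir / f"{sample}.vcf")
    paths["genome_index"] = vio.write_genome_index(
        bundle.genome, outdir / "genome_index.tsv"
    )
    paths["truth_manifest"] = bundle.manifest.write_tsv(outdir / "truth_manifest.tsv")
    paths["classification"] = vio.write_classification_table(
        bundle.classifications, outdir / "classification.tsv"
    )
    paths["coords"] = vio.write_coords(bundle.segments, outdir / "coords.tsv")
    if config.emit_fasta:
        paths["fasta"] = _write_fasta(config, outdir / "contigs.fasta")
    return paths


def _write_fasta(config: SimConfig, path: Path) -> Path:
    """Random contig sequences at the configured lengths, plus contaminants."""
    rng = np.random.default_rng(config.seed + 1)
    with path.open("w") as fh:
        names = [name for name, _ in config.contigs]
        lengths = [length for _, length in config.contigs]
        for i, lineage in enumerate(config.contaminant_lineages, start=1):
            names.append(f"contaminant_{i}")
            lengths.append(5_000)
        for name, length in zip(names, lengths):
            seq = "".join(
                np.array(list(_BASES))[rng.integers(0, 4, size=length)]
            )
            fh.write(f">{name}\n")
            for i in range(0, length, 80):
                fh.write(seq[i : i + 80] + "\n")
    return path


def random_config(seed: int) -> SimConfig:
    """A randomized, scaled-down study configuration for recovery testing.

    Genomes of a few hundred kbp with proportional variant loads keep the
    end-to-end recovery sweep fast while still exercising every category.
    """
    rng = np.random.default_rng(seed)
    chrom = int(rng.integers(200_000, 600_000))
    plasmid = int(rng.integers(20_000, 80_000))
    reps = ("ground_A", "ground_B", "ground_C")
    test = "space_derivate"
    specs = [
        SvSpec("DEL", int(rng.integers(1_000, 4_000)), (test, reps[0])),
        SvSpec("DUP", int(rng.integers(1_000, 4_000)),
               (reps[int(rng.integers(0, 3))],)),
        SvSpec("DEL", int(rng.integers(10_001, 14_000)), (test,)),
        SvSpec("INS", int(rng.integers(500, 2_000)), reps + (test,),
               shared_all=True),
    ]
    if rng.integers(0, 2):
        specs.append(SvSpec("INV", int(rng.integers(1_000, 3_000)), (test,)))
    raw = rng.dirichlet([8, 4, 1, 10])
    head = tuple(round(float(f), 3) for f in raw[:3])
    comp = head + (round(1.0 - sum(head), 3),)
    return SimConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        contigs=(("chromosome", chrom), ("plasmid", plasmid)),
        n_clonal_shared=int(rng.integers(0, 80)),
        private_rate=float(rng.uniform(5e-5, 4e-4)),
        n_treatment_specific=int(rng.integers(0, 12)),
        sv_specs=tuple(specs),
        ann_composition=comp,
        fail_fraction=float(rng.uniform(0.0, 0.15)),
        n_alignment_segments=int(rng.integers(5, 10)),
        n_inversions=int(rng.integers(0, 2)),
        n_translocations=int(rng.integers(0, 2)),
        n_repeat_pairs=int(rng.integers(0, 10)),
    )
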