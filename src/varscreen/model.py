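"""Core data model for multi-sample variant screening.

The central containers are :class:`VariantSet` (an ordered, multi-sample
collection of :class:`VariantRecord` bound to a :class:`GenomeIndex`) and the
supporting value types for genotypes, contig classifications and whole-genome
alignment segments.  Coordinates follow the VCF convention (1-based positions
on records); window arithmetic elsewhere converts to 0-based half-open
intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

PASS = "PASS"


class VariantClass(str, enum.Enum):
    """Classification of a biallelic variant record.

    Sequence-resolved classes (SNV, MNP, INS, DEL) are determined from the
    REF/ALT allele lengths; SV_* classes come from the SVTYPE INFO key of
    structural-variant callers.
    """

    SNV = "SNV"
    MNP = "MNP"
    INS = "INS"
    DEL = "DEL"
    SV_DEL = "SV_DEL"
    SV_INS = "SV_INS"
    SV_DUP = "SV_DUP"
    SV_INV = "SV_INV"
    SV_BND = "SV_BND"

    @property
    def is_sv(self) -> bool:
        return self.name.startswith("SV_")


SVTYPE_TO_CLASS: dict[str, VariantClass] = {
    "DEL": VariantClass.SV_DEL,
    "INS": VariantClass.SV_INS,
    "DUP": VariantClass.SV_DUP,
    "INV": VariantClass.SV_INV,
    "BND": VariantClass.SV_BND,
    "TRA": VariantClass.SV_BND,
}


class ModelError(ValueError):
    """Invalid model state (invariant violation or bad argument)."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered list of (contig name, length in bp) defining the reference."""

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ModelError("duplicate contig names in genome index")
        for name, length in self.contigs:
            if not name:
                raise ModelError("empty contig name")
            if length < 1:
                raise ModelError(f"contig {name!r} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeIndex":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: length for name, length in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def order(self, contig: str) -> int:
        try:
            return self.names.index(contig)
        except ValueError:
            raise ModelError(f"contig {contig!r} not in genome index") from None

    def __contains__(self, contig: object) -> bool:
        return contig in self.names


@dataclass(frozen=True)
class Genotype:
    """An unphased or phased call: tuple of allele indices, None = uncalled.

    0 is the reference allele, >=1 an alternate allele index.  The fully
    uncalled diploid genotype ``./.`` is the module-level :data:`MISSING`
    constant; a partially called genotype (e.g. ``1/.`` from a multi-allelic
    split) is neither missing nor fully called.
    """

    alleles: tuple[Optional[int], ...] = (None, None)
    phased: bool = False

    def __post_init__(self) -> None:
        if len(self.alleles) == 0:
            raise ModelError("genotype must have at least one allele slot")
        for a in self.alleles:
            if a is not None and a < 0:
                raise ModelError(f"negative allele index {a}")

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def is_fully_called(self) -> bool:
        return all(a is not None for a in self.alleles)

    @property
    def carries_alt(self) -> bool:
        """True iff at least one called allele is an alternate allele."""
        return any(a is not None and a >= 1 for a in self.alleles)

    def allele_multiset(self) -> Optional[tuple[int, ...]]:
        """Sorted allele tuple for unphased comparison; None unless fully called."""
        if not self.is_fully_called:
            return None
        return tuple(sorted(a for a in self.alleles if a is not None))

    def same_unphased(self, other: "Genotype") -> bool:
        """Unphased genotype equality: both fully called with equal allele multisets."""
        mine, theirs = self.allele_multiset(), other.allele_multiset()
        return mine is not None and mine == theirs

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


MISSING = Genotype((None, None))


def classify_variant(ref: str, alt: str, info: Mapping[str, object]) -> VariantClass:
    """Classify a biallelic REF/ALT pair, honouring an SVTYPE INFO key.

    Symbolic alleles (``<DEL>``, breakend notation) require SVTYPE.  For
    sequence-resolved alleles classification is by length comparison: equal
    lengths give SNV (length 1) or MNP, a longer ALT an insertion, a longer
    REF a deletion.
    """
    if not ref or not alt:
        raise ModelError("ref and alt alleles must be non-empty")
    symbolic = alt.startswith("<") or "[" in alt or "]" in alt
    svtype = info.get("SVTYPE")
    if svtype is not None:
        svtype = str(svtype)
        if svtype not in SVTYPE_TO_CLASS:
            raise ModelError(f"unknown SVTYPE {svtype!r}")
        return SVTYPE_TO_CLASS[svtype]
    if symbolic:
        raise ModelError(f"symbolic alt {alt!r} without SVTYPE")
    if len(ref) == len(alt):
        return VariantClass.SNV if len(ref) == 1 else VariantClass.MNP
    return VariantClass.INS if len(alt) > len(ref) else VariantClass.DEL


@dataclass
class VariantRecord:
    """One normalized biallelic variant site with per-sample genotypes."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: VariantClass
    filter: str = PASS
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    info: dict[str, object] = field(default_factory=dict)
    origin_callers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"position {self.pos} is not 1-based")
        if not self.ref:
            raise ModelError("empty ref allele")
        if self.variant_class.is_sv:
            if self.svlen is None and self.end is None:
                raise ModelError("SV record requires SVLEN or END")
            if self.end is None:
                # Canonical END: span-consuming SV types end at pos + |SVLEN|,
                # insertions and breakends at pos.
                span = abs(self.svlen)  # type: ignore[arg-type]
                if self.variant_class in (
                    VariantClass.SV_DEL,
                    VariantClass.SV_DUP,
                    VariantClass.SV_INV,
                ):
                    self.info["END"] = self.pos + span
                else:
                    self.info["END"] = self.pos

    @property
    def is_pass(self) -> bool:
        return self.filter == PASS

    @property
    def is_sv(self) -> bool:
        return self.variant_class.is_sv

    @property
    def svlen(self) -> Optional[int]:
        v = self.info.get("SVLEN")
        return None if v is None else int(v)

    @property
    def end(self) -> Optional[int]:
        v = self.info.get("END")
        return None if v is None else int(v)

    @property
    def sv_span(self) -> Optional[int]:
        """Affected length in bp: |SVLEN|, falling back to END - pos + 1."""
        if self.svlen is not None:
            return abs(self.svlen)
        if self.end is not None:
            return self.end - self.pos + 1
        return None

    @property
    def ann(self) -> Optional[str]:
        v = self.info.get("ANN")
        return None if v is None else str(v)

    @property
    def key(self) -> tuple:
        """Site-level identity used for uniqueness and sequence-record merging."""
        return (self.contig, self.pos, self.ref, self.alt)

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample, MISSING)

    def carried_by(self, sample: str) -> bool:
        return self.genotype(sample).carries_alt


@dataclass
class VariantSet:
    """Ordered multi-sample variant collection bound to a genome index.

    Records are kept sorted by (contig order in the genome, position) and
    every record's genotype map is keyed exactly by ``samples``.
    """

    samples: tuple[str, ...]
    records: list[VariantRecord]
    genome: GenomeIndex

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ModelError("duplicate sample names")
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda r: (self.genome.order(r.contig), r.pos, r.ref, r.alt))

    def validate(self) -> None:
        lengths = self.genome.lengths
        seen: set[tuple] = set()
        sample_set = set(self.samples)
        for rec in self.records:
            if rec.contig not in lengths:
                raise ModelError(f"record contig {rec.contig!r} not in genome index")
            if rec.pos > lengths[rec.contig]:
                raise ModelError(
                    f"position {rec.pos} beyond contig {rec.contig!r} "
                    f"length {lengths[rec.contig]}"
                )
            if rec.key in seen:
                raise ModelError(f"duplicate record key {rec.key}")
            seen.add(rec.key)
            if set(rec.genotypes) != sample_set:
                raise ModelError(
                    f"record {rec.key} genotype samples {sorted(rec.genotypes)} "
                    f"!= set samples {sorted(sample_set)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def subset(self, keep: Sequence[VariantRecord]) -> "VariantSet":
        keep_ids = {id(r) for r in keep}
        return VariantSet(
            self.samples, [r for r in self.records if id(r) in keep_ids], self.genome
        )


@dataclass(frozen=True)
class ContigClassification:
    """Taxonomic classification of one contig (e.g. from a Kraken report)."""

    contig: str
    taxon_label: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ModelError("lineage must be non-empty")

    def lineage_contains(self, taxon: str) -> bool:
        """Case-insensitive membership of a taxon name at any rank."""
        want = taxon.strip().lower()
        return any(t.strip().lower() == want for t in self.lineage)


@dataclass(frozen=True)
class AlignmentSegment:
    """One whole-genome-alignment block between a reference and a query.

    Intervals are 1-based inclusive and stored strand-normalized
    (start <= end); a '-' strand records that the raw query coordinates were
    descending.
    """

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str = "+"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ModelError("ref_start > ref_end")
        if self.query_start > self.query_end:
            raise ModelError("query interval not strand-normalized")
        if self.strand not in {"+", "-"}:
            raise ModelError(f"invalid strand {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ModelError(f"identity {self.identity} outside [0, 1]")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start + 1
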