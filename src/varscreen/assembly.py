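"""Assembly hygiene before variant screening.

Filters contigs by taxonomic lineage (decontamination given an external
classification) and computes assembly summary statistics including per-contig
GC content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .model import ContigClassification, ModelError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContigStats:
    name: str
    length: int
    gc_fraction: float


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    longest_bp: int
    total_bp: int
    contigs: tuple[ContigStats, ...]

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "longest_bp": self.longest_bp,
            "total_bp": self.total_bp,
            "contigs": [
                {"name": c.name, "length": c.length, "gc_fraction": c.gc_fraction}
                for c in self.contigs
            ],
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def gc_fraction(sequence: str) -> float:
    """GC content as (G+C)/(A+C+G+T), case-insensitive.

    N and other ambiguity codes are excluded from the denominator; a sequence
    with no unambiguous base has undefined GC and raises.
    """
    seq = sequence.upper()
    g = seq.count("G")
    c = seq.count("C")
    a = seq.count("A")
    t = seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ModelError("GC content undefined: no unambiguous bases")
    return (g + c) / denom


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Contig count, longest/total length and per-contig GC."""
    if not contigs:
        raise ModelError("assembly has no contigs")
    per_contig = []
    for rec in contigs:
        seq = str(rec.seq)
        if len(seq) == 0:
            raise ModelError(f"contig {rec.id!r} is empty")
        per_contig.append(ContigStats(rec.id, len(seq), gc_fraction(seq)))
    lengths = [c.length for c in per_contig]
    return AssemblyStats(
        n_contigs=len(per_contig),
        longest_bp=max(lengths),
        total_bp=sum(lengths),
        contigs=tuple(per_contig),
    )


def filter_contigs_by_lineage(
    contigs: Sequence[SeqRecord],
    classifications: Iterable[ContigClassification],
    target_lineage: str,
    keep_unclassified: bool = False,
    strict: bool = True,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition contigs into (kept, removed) by lineage membership.

    A contig is kept iff its lineage contains ``target_lineage`` at any rank
    (case-insensitive exact taxon-name match).  Unclassified contigs are
    removed by default (``keep_unclassified`` flips that, logged either way).
    In strict mode a contig without any classification row is an error;
    otherwise it is treated as unclassified.
    """
    by_contig = {c.contig: c for c in classifications}
    kept, removed = [], []
    for rec in contigs:
        cls = by_contig.get(rec.id)
        if cls is None:
            if strict:
                raise ModelError(f"contig {rec.id!r} has no classification row")
            cls = ContigClassification(rec.id, "unclassified", ("root",))
        if cls.taxon_label == "unclassified":
            (kept if keep_unclassified else removed).append(rec)
            log.info(
                "contig %s unclassified -> %s",
                rec.id, "kept" if keep_unclassified else "removed",
            )
        elif cls.lineage_contains(target_lineage):
            kept.append(rec)
        else:
            removed.append(rec)
    return kept, removed


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(contigs: Sequence[SeqRecord], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(contigs, str(path), "fasta")
    return path
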