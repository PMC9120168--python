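"""Collinearity checking over whole-genome alignment segments.

From a coordinates table (one row per alignment block between a reference
and a query assembly) the module classifies segments as unique vs repetitive
by reciprocal interval overlap, then inspects the unique segments for
inversions (minus-strand blocks), translocations (query order disagreeing
with reference order), duplications (reference-interval overlap between
unique blocks) and reference coverage contiguity.  Two collinear genomes
yield an empty event list and contiguous coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .model import AlignmentSegment, ModelError

DEFAULT_OVERLAP_THRESHOLD = 0.5
DEFAULT_GAP_TOLERANCE = 1_000
DEFAULT_DUP_TOLERANCE = 100
DEFAULT_COVERAGE_TOLERANCE = 0.01


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp of two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_segments(
    segments: Sequence[AlignmentSegment],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[list[AlignmentSegment], list[AlignmentSegment]]:
    """Split segments into (unique, repetitive) by reciprocal overlap.

    A segment is repetitive iff another segment overlaps its query interval
    by more than ``overlap_threshold`` of its own query length, or its ref
    interval by more than that fraction of its own ref length.
    """
    if not (0.0 <= overlap_threshold <= 1.0):
        raise ModelError("overlap_threshold must be in [0, 1]")
    unique, repetitive = [], []
    for i, seg in enumerate(segments):
        is_rep = False
        for j, other in enumerate(segments):
            if i == j:
                continue
            q_ov = _overlap(
                seg.query_start, seg.query_end, other.query_start, other.query_end
            )
            r_ov = _overlap(seg.ref_start, seg.ref_end, other.ref_start, other.ref_end)
            if (
                q_ov > overlap_threshold * seg.query_length
                or r_ov > overlap_threshold * seg.ref_length
            ):
                is_rep = True
                break
        (repetitive if is_rep else unique).append(seg)
    return unique, repetitive


@dataclass
class CollinearityReport:
    """Verdict structure for a unique-segment set."""

    n_unique: int
    n_repetitive: int
    inversions: list[AlignmentSegment] = field(default_factory=list)
    translocations: list[tuple[AlignmentSegment, AlignmentSegment]] = field(
        default_factory=list
    )
    duplications: list[tuple[AlignmentSegment, AlignmentSegment]] = field(
        default_factory=list
    )
    ref_coverage_contiguous: bool = True
    parameters: dict = field(default_factory=dict)

    @property
    def is_collinear(self) -> bool:
        return (
            not self.inversions
            and not self.translocations
            and not self.duplications
            and self.ref_coverage_contiguous
        )

    def to_dict(self) -> dict:
        def seg(s: AlignmentSegment) -> dict:
            return {
                "ref": [s.ref_start, s.ref_end],
                "query": [s.query_start, s.query_end],
                "strand": s.strand,
            }

        return {
            "n_unique": self.n_unique,
            "n_repetitive": self.n_repetitive,
            "inversions": [seg(s) for s in self.inversions],
            "translocations": [[seg(a), seg(b)] for a, b in self.translocations],
            "duplications": [[seg(a), seg(b)] for a, b in self.duplications],
            "ref_coverage_contiguous": self.ref_coverage_contiguous,
            "is_collinear": self.is_collinear,
            "parameters": self.parameters,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def check_collinearity(
    unique_segments: Sequence[AlignmentSegment],
    ref_length: int,
    n_repetitive: int = 0,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    dup_tolerance: int = DEFAULT_DUP_TOLERANCE,
    coverage_tolerance: float = DEFAULT_COVERAGE_TOLERANCE,
) -> CollinearityReport:
    """Inspect unique alignment segments for rearrangement evidence.

    * inversion: a segment on the minus strand;
    * translocation: an adjacent pair of plus-strand segments (sorted by
      ref_start) whose query order disagrees with their ref order;
    * duplication: ref-interval overlap between unique segments beyond
      ``dup_tolerance`` bp;
    * contiguity: every gap between consecutive ref intervals is at most
      ``gap_tolerance`` bp and the union of ref intervals spans at least
      (1 - coverage_tolerance) of ``ref_length``.
    """
    if not unique_segments:
        raise ModelError("check_collinearity needs at least one segment")
    segs = sorted(unique_segments, key=lambda s: (s.ref_start, s.ref_end))
    inversions = [s for s in segs if s.strand == "-"]

    plus = [s for s in segs if s.strand == "+"]
    translocations = [
        (a, b) for a, b in zip(plus, plus[1:]) if b.query_start < a.query_start
    ]

    duplications = []
    for i, a in enumerate(segs):
        for b in segs[i + 1 :]:
            if b.ref_start > a.ref_end:
                break
            if _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end) > dup_tolerance:
                duplications.append((a, b))

    contiguous = True
    covered = segs[0].ref_length
    for a, b in zip(segs, segs[1:]):
        gap = b.ref_start - a.ref_end - 1
        if gap > gap_tolerance:
            contiguous = False
        covered += b.ref_length - _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end)
    span_ok = covered >= (1.0 - coverage_tolerance) * ref_length
    contiguous = contiguous and span_ok

    return CollinearityReport(
        n_unique=len(segs),
        n_repetitive=n_repetitive,
        inversions=inversions,
        translocations=translocations,
        duplications=duplications,
        ref_coverage_contiguous=contiguous,
        parameters={
            "gap_tolerance": gap_tolerance,
            "dup_tolerance": dup_tolerance,
            "coverage_tolerance": coverage_tolerance,
            "ref_length": ref_length,
        },
    )


def analyze_coords(
    segments: Sequence[AlignmentSegment],
    ref_length: int,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    dup_tolerance: int = DEFAULT_DUP_TOLERANCE,
    coverage_tolerance: float = DEFAULT_COVERAGE_TOLERANCE,
) -> CollinearityReport:
    """Classify segments, then run the collinearity check on the unique ones."""
    unique, repetitive = classify_segments(segments, overlap_threshold)
    if not unique:
        raise ModelError("no unique segments to check for collinearity")
    return check_collinearity(
        unique,
        ref_length=ref_length,
        n_repetitive=len(repetitive),
        gap_tolerance=gap_tolerance,
        dup_tolerance=dup_tolerance,
        coverage_tolerance=coverage_tolerance,
    )
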