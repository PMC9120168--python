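"""Readers and writers for VCF, genome indices, classification and coords tables.

VCF parsing goes through :mod:`pysam`; multi-allelic sites are split into
biallelic records at read time (see :func:`read_vcf`).  Writing emits plain
VCF 4.2 text so outputs remain inspectable and diffable.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .model import (
    MISSING,
    PASS,
    AlignmentSegment,
    ContigClassification,
    GenomeIndex,
    Genotype,
    ModelError,
    VariantRecord,
    VariantSet,
    classify_variant,
)

# INFO keys preserved across read/write round trips.
_INFO_KEYS = ("SVTYPE", "SVLEN", "END", "ANN")
_CALLER_KEY = "CALLER"


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def _split_genotype(raw, alt_index: int, phased: bool) -> Genotype:
    """Re-index a genotype onto the biallelic record for one alt allele.

    Allele 0 stays 0, the chosen alt becomes 1 and any *other* alt allele
    becomes an uncalled slot — the explicit multi-allelic split policy that
    keeps per-site counting deterministic.
    """
    alleles = []
    for a in raw:
        if a is None:
            alleles.append(None)
        elif a == 0:
            alleles.append(0)
        elif a == alt_index:
            alleles.append(1)
        else:
            alleles.append(None)
    return Genotype(tuple(alleles), phased=phased)


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def read_vcf(
    path: str | Path,
    genome: Optional[GenomeIndex] = None,
    sample_names_expected: Optional[Sequence[str]] = None,
) -> VariantSet:
    """Read a VCF 4.x file into a :class:`VariantSet`.

    One record is produced per (site, alt allele); multi-allelic sites are
    split with genotypes re-indexed.  FILTER "." or "PASS" maps to PASS,
    any other label is kept as the failing label.  If ``genome`` is omitted
    it is built from the header contig lines.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise ParseError(f"{path}: VCF lacks the required GT FORMAT field")
        samples = tuple(vf.header.samples)
        if sample_names_expected is not None:
            missing = set(sample_names_expected) - set(samples)
            if missing:
                raise ParseError(f"{path}: expected samples absent: {sorted(missing)}")
        if genome is None:
            contigs = [(c, vf.header.contigs[c].length or 0) for c in vf.header.contigs]
            if not contigs or any(l == 0 for _, l in contigs):
                raise ParseError(
                    f"{path}: no genome index given and header contigs lack lengths"
                )
            genome = GenomeIndex.from_pairs(contigs)

        records: list[VariantRecord] = []
        for site in vf:
            if site.contig not in genome:
                raise ParseError(
                    f"{path}: line for {site.contig}:{site.pos} names a contig "
                    "absent from the genome index"
                )
            filters = list(site.filter.keys())
            if not filters or filters == ["PASS"]:
                filt = PASS
            else:
                filt = ";".join(f for f in filters if f != "PASS")
            alts = site.alts or ()
            info = dict(site.info)
            callers = ()
            if _CALLER_KEY in info:
                raw = info.pop(_CALLER_KEY)
                callers = tuple(raw) if isinstance(raw, (tuple, list)) else (str(raw),)
            for alt_index, alt in enumerate(alts, start=1):
                rec_info: dict[str, object] = {}
                if "SVTYPE" in info:
                    rec_info["SVTYPE"] = str(info["SVTYPE"])
                if "SVLEN" in info:
                    rec_info["SVLEN"] = int(_scalar(info["SVLEN"]))
                if "SVTYPE" in info:
                    # pysam folds END into .stop; recover it for SV records.
                    rec_info["END"] = int(site.stop)
                if "ANN" in info:
                    ann = info["ANN"]
                    rec_info["ANN"] = (
                        ",".join(ann) if isinstance(ann, (tuple, list)) else str(ann)
                    )
                genotypes = {}
                for sample in samples:
                    call = site.samples[sample]
                    raw = call.get("GT")
                    if raw is None or all(a is None for a in raw):
                        genotypes[sample] = MISSING
                    else:
                        genotypes[sample] = _split_genotype(
                            raw, alt_index, bool(call.phased)
                        )
                try:
                    vclass = classify_variant(site.ref, alt, rec_info)
                except ModelError as exc:
                    raise ParseError(f"{path}: {site.contig}:{site.pos}: {exc}") from exc
                records.append(
                    VariantRecord(
                        contig=site.contig,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        variant_class=vclass,
                        filter=filt,
                        genotypes=genotypes,
                        info=rec_info,
                        origin_callers=callers,
                    )
                )
    vset = VariantSet(samples, records, genome)
    vset.validate()
    return vset


def _format_info(rec: VariantRecord) -> str:
    parts = []
    for key in _INFO_KEYS:
        if key in rec.info and rec.info[key] is not None:
            parts.append(f"{key}={rec.info[key]}")
    if rec.origin_callers:
        parts.append(f"{_CALLER_KEY}={','.join(rec.origin_callers)}")
    return ";".join(parts) if parts else "."


def write_vcf(vset: VariantSet, path: str | Path) -> Path:
    """Write a :class:`VariantSet` as VCF 4.2 text.

    Round-trip property: re-reading the file reproduces the set on
    (contig, pos, ref, alt, filter, genotypes, SVTYPE, SVLEN, END, ANN).
    """
    path = Path(path)
    fail_labels = sorted(
        {lab for r in vset.records if r.filter != PASS for lab in r.filter.split(";")}
    )
    lines = ["##fileformat=VCFv4.2"]
    for name, length in vset.genome.contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    for lab in fail_labels:
        lines.append(f'##FILTER=<ID={lab},Description="Failed caller filter">')
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        f'##INFO=<ID={_CALLER_KEY},Number=.,Type=String,Description="Originating caller(s)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_cols += list(vset.samples)
    lines.append("\t".join(header_cols))
    for rec in vset.records:
        row = [
            rec.contig,
            str(rec.pos),
            ".",
            rec.ref,
            rec.alt,
            ".",
            rec.filter,
            _format_info(rec),
            "GT",
        ]
        row += [str(rec.genotype(s)) for s in vset.samples]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a genome index from a samtools .fai or 2+ column name/length TSV."""
    pairs = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{i}: expected at least 2 tab-separated columns")
        try:
            pairs.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: bad contig length {fields[1]!r}") from exc
    return GenomeIndex.from_pairs(pairs)


def write_genome_index(genome: GenomeIndex, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{name}\t{length}\n" for name, length in genome.contigs)
    )
    return path


def read_classification_table(path: str | Path) -> list[ContigClassification]:
    """Read a contig classification table.

    Two dialects are accepted:

    * Kraken-style: columns classified-flag (C/U), contig id, taxon label/id,
      [length, LCA mapping ...].  Unclassified rows (flag U) get taxon_label
      "unclassified" and lineage ("root",).
    * Simple 2-column: contig id, semicolon-joined lineage string "a;b;c"
      (root first); the leaf taxon becomes the label.
    """
    rows: list[ContigClassification] = []
    seen: set[str] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 3 and fields[0] in {"C", "U"}:
            contig, taxon = fields[1], fields[2]
            if fields[0] == "U":
                cls = ContigClassification(contig, "unclassified", ("root",))
            else:
                cls = ContigClassification(contig, taxon, ("root", taxon))
        elif len(fields) >= 2:
            contig = fields[0]
            lineage = tuple(t.strip() for t in fields[1].split(";") if t.strip())
            if not lineage or fields[1].strip().lower() == "unclassified":
                cls = ContigClassification(contig, "unclassified", ("root",))
            else:
                cls = ContigClassification(contig, lineage[-1], lineage)
        else:
            raise ParseError(f"{path}:{i}: missing contig column")
        if cls.contig in seen:
            raise ParseError(f"{path}:{i}: duplicate contig id {cls.contig!r}")
        seen.add(cls.contig)
        rows.append(cls)
    return rows


def write_classification_table(
    rows: Iterable[ContigClassification], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow([row.contig, ";".join(row.lineage)])
    return path


def read_coords(path: str | Path) -> list[AlignmentSegment]:
    """Read a show-coords-style alignment table.

    Columns: ref_start, ref_end, query_start, query_end, identity
    [, ref_id, query_id].  Strand is inferred from query_start > query_end;
    query intervals are normalized to ascending order.  Identity above 1 is
    interpreted as a percentage.
    """
    segments = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{i}: expected at least 5 columns")
        try:
            rs, re_, qs, qe = (int(f) for f in fields[:4])
            ident = float(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-numeric coordinate field") from exc
        if ident > 1.0:
            ident /= 100.0
        strand = "+"
        if qs > qe:
            strand = "-"
            qs, qe = qe, qs
        segments.append(AlignmentSegment(rs, re_, qs, qe, strand, ident))
    return segments


def write_coords(segments: Iterable[AlignmentSegment], path: str | Path,
                 ref_id: str = "ref", query_id: str = "query") -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for seg in segments:
            qs, qe = seg.query_start, seg.query_end
            if seg.strand == "-":
                qs, qe = qe, qs
            writer.writerow(
                [seg.ref_start, seg.ref_end, qs, qe, f"{seg.identity * 100:.2f}",
                 ref_id, query_id]
            )
    return path
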