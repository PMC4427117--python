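"""Reading and writing the formats the pipeline touches: FASTA, BED, GFF3.

Internal coordinates are 0-based half-open. BED is already in that
convention; GFF3 uses 1-based closed coordinates and is converted at this
boundary ([s, e] -> [s-1, e)). Only plus-strand (or strandless) annotations
are accepted: the analysis is single-strand.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .types import DnaSequence, GenomicIntervals


def read_fasta(path: str | os.PathLike) -> list[DnaSequence]:
    """Read a (multi-record) FASTA file into validated DNA sequences.

    Sequences are uppercased; characters outside {A, C, G, T, N} — including
    RNA's U — raise :class:`ValidationError` naming the offending position.
    An empty file or an empty record is a :class:`FormatError`.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"FASTA {path}: no records")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"FASTA {path}: record {rec.id!r} is empty")
        out.append(DnaSequence(rec.id, seq))
    return out


def _parse_bed_line(line: str, lineno: int) -> tuple[str, int, int]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) == 1:  # tolerate space-separated minimal BED
        cols = line.split()
    if len(cols) < 3:
        raise FormatError(f"BED line {lineno}: expected >= 3 columns, got {len(cols)}")
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise FormatError(f"BED line {lineno}: non-integer coordinates") from exc
    if len(cols) >= 6 and cols[5] == "-":
        raise ValidationError(
            f"BED line {lineno}: minus-strand features are not supported "
            "(single-strand analysis)"
        )
    return cols[0], start, end


def _parse_gff3_line(line: str, lineno: int) -> tuple[str, int, int] | None:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise FormatError(f"GFF3 line {lineno}: expected >= 8 columns, got {len(cols)}")
    if cols[2].lower() not in ("exon", "cds"):
        return None
    try:
        start1, end1 = int(cols[3]), int(cols[4])
    except ValueError as exc:
        raise FormatError(f"GFF3 line {lineno}: non-integer coordinates") from exc
    if cols[6] == "-":
        raise ValidationError(
            f"GFF3 line {lineno}: minus-strand features are not supported "
            "(single-strand analysis)"
        )
    # 1-based closed -> 0-based half-open
    return cols[0], start1 - 1, end1


def read_annotations(
    path: str | os.PathLike, format: str = "bed", label: str = "exon"
) -> dict[str, GenomicIntervals]:
    """Read an annotation file into per-sequence interval sets.

    Overlapping intervals are merged and the result is sorted. Intervals with
    ``start >= end`` after coordinate conversion raise :class:`ValidationError`.
    """
    if format not in ("bed", "gff3"):
        raise ValidationError(f"unknown annotation format {format!r}")
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            if format == "bed":
                parsed = _parse_bed_line(line, lineno)
            else:
                parsed = _parse_gff3_line(line, lineno)
                if parsed is None:
                    continue
            seqid, start, end = parsed
            if start >= end:
                raise ValidationError(
                    f"{path} line {lineno}: empty or inverted interval "
                    f"[{start}, {end}) after conversion"
                )
            raw.setdefault(seqid, []).append((start, end))
    return {
        seqid: GenomicIntervals.from_unsorted(seqid, ivs, label=label)
        for seqid, ivs in raw.items()
    }


def read_annotation(
    path: str | os.PathLike, format: str = "bed", label: str = "exon"
) -> GenomicIntervals:
    """Read an annotation file that describes a single sequence."""
    per_seq = read_annotations(path, format=format, label=label)
    if not per_seq:
        raise FormatError(f"{path}: no annotation records")
    if len(per_seq) > 1:
        raise ValidationError(
            f"{path}: annotations span {len(per_seq)} sequences "
            f"({sorted(per_seq)}); expected one"
        )
    return next(iter(per_seq.values()))


def write_regions(
    regions: GenomicIntervals | Iterable[GenomicIntervals],
    path: str | os.PathLike,
    format: str = "bed",
) -> None:
    """Write interval sets as BED (0-based half-open) or GFF3 (1-based closed)."""
    if format not in ("bed", "gff3"):
        raise ValidationError(f"unknown output format {format!r}")
    if isinstance(regions, GenomicIntervals):
        regions = [regions]
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for reg in regions:
            for s, e in reg.intervals:
                if format == "bed":
                    fh.write(f"{reg.sequence_id}\t{s}\t{e}\t{reg.label}\n")
                else:
                    fh.write(
                        f"{reg.sequence_id}\twavexon\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"Name={reg.label}\n"
                    )
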