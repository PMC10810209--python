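"""Readers and writers for the text formats the pipeline touches.

All genomic coordinates are BED-style: 0-based, half-open.  SAM's 1-based
leftmost positions are converted at parse time and never leak past this
module.  Chromosome names are compared as exact strings — no "chr"
aliasing; use :func:`rename_chroms` when two inputs disagree.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

PathLike = Union[str, Path]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file violates its format grammar."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand is not None and self.strand not in _STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Shared-base-pair overlap; touching half-open intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        return self.start + self.length // 2


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# CIGAR operations that consume the reference.
_REF_CONSUMERS = frozenset("MDN=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """The slice of a SAM record the pipeline needs.

    ``pos`` keeps SAM's 1-based convention; :meth:`interval` converts.
    """

    query_name: str
    flag: int
    chrom: Optional[str]
    pos: int  # 1-based leftmost, 0 when unmapped
    mapq: int
    cigar: str
    mismatches: Optional[int] = None  # NM tag
    has_alt_hits: bool = False  # XA-style alternate-hit tag present

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def aligned_length(self) -> int:
        """Reference span of the alignment, from the CIGAR string."""
        if not self.cigar or self.cigar == "*":
            return 0
        span = 0
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if not num:
                    raise ParseError(f"malformed CIGAR {self.cigar!r}")
                if ch in _REF_CONSUMERS:
                    span += int(num)
                num = ""
        return span

    def interval(self) -> GenomicInterval:
        if not self.is_mapped or self.chrom is None:
            raise ValueError(f"record {self.query_name!r} is unmapped")
        start = self.pos - 1
        return GenomicInterval(self.chrom, start, start + self.aligned_length)


def _open_maybe_gzip(source: Union[PathLike, IO[bytes]]) -> IO[str]:
    """Open a path or byte stream as text, transparently decompressing gzip."""
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    else:
        raw = source
    buffered = io.BufferedReader(raw) if not isinstance(raw, io.BufferedReader) else raw
    if buffered.peek(2)[:2] == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=buffered))
    return io.TextIOWrapper(buffered)


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file; multi-line sequences are concatenated, case upper."""
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"record {header!r} at line {header_line} has no sequence")
        records.append(SequenceRecord(header, "".join(chunks).upper()))

    with _open_maybe_gzip(path) as fh:
        line_no = 0
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"empty FASTA header at line {line_no}")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"sequence before any header at line {line_no}")
                chunks.append(line)
        _flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(source: Union[PathLike, IO[bytes]]) -> Iterator[SequenceRecord]:
    """Lazily yield records from a FASTQ path or byte stream (plain or gzip)."""
    with _open_maybe_gzip(source) as fh:
        idx = 0
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                return
            if any(not ln for ln in lines[1:]):
                raise ParseError(f"truncated FASTQ record at index {idx}")
            head, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not head.startswith("@"):
                raise ParseError(f"FASTQ record {idx} header does not start with '@'")
            if not plus.startswith("+"):
                raise ParseError(f"FASTQ record {idx} separator does not start with '+'")
            if len(seq) != len(qual):
                raise ParseError(
                    f"FASTQ record {idx}: sequence/quality length mismatch"
                )
            yield SequenceRecord(head[1:].split()[0], seq.upper(), qual)
            idx += 1


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: PathLike, min_columns: int = 3) -> list[GenomicInterval]:
    """Read BED3/BED6 into 0-based half-open intervals; track lines skipped."""
    out: list[GenomicInterval] = []
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns or len(fields) < 3:
                raise ParseError(f"line {line_no}: expected ≥{min_columns} columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"line {line_no}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else None
            out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return out


def read_bedpe(path: PathLike) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read BEDPE (6+ columns): two anchors per line."""
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    with _open_maybe_gzip(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"line {line_no}: BEDPE needs ≥6 columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
            pairs.append((a, b))
    return pairs


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


def read_sam(path: PathLike) -> Iterator[AlignmentRecord]:
    """Iterate a text SAM file as :class:`AlignmentRecord`.

    Unmapped records are yielded with ``chrom`` unset; secondary and
    supplementary flags are preserved for downstream filtering.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            yield AlignmentRecord(
                query_name=rec.query_name or "",
                flag=rec.flag,
                chrom=rec.reference_name if not rec.is_unmapped else None,
                pos=(rec.reference_start + 1) if not rec.is_unmapped else 0,
                mapq=rec.mapping_quality,
                cigar=rec.cigarstring or "*",
                mismatches=int(nm) if nm is not None else None,
                has_alt_hits=rec.has_tag("XA"),
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    path: PathLike,
    references: Mapping[str, int],
) -> None:
    """Write text SAM with an @SQ header built from ``references`` (name→length)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            tags = []
            if rec.mismatches is not None:
                tags.append(f"NM:i:{rec.mismatches}")
            if rec.has_alt_hits:
                tags.append("XA:Z:alt")
            fields = [
                rec.query_name,
                str(rec.flag),
                rec.chrom if rec.chrom is not None else "*",
                str(rec.pos if rec.is_mapped else 0),
                str(rec.mapq),
                rec.cigar,
                "*",
                "0",
                "0",
                "*",
                "*",
            ] + tags
            fh.write("\t".join(fields) + "\n")


def write_table(records: Sequence, path: PathLike) -> None:
    """Write keyed rows (dicts, dataclasses or a DataFrame) as headered TSV.

    Floats keep ≥6 significant digits; the file is BED-compatible whenever
    the first three columns are chrom/start/end.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "to_row"):
                rows.append(r.to_row())
            elif hasattr(r, "__dataclass_fields__"):
                from dataclasses import asdict

                rows.append(asdict(r))
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def rename_chroms(
    intervals: Iterable[GenomicInterval], mapping: Mapping[str, str]
) -> list[GenomicInterval]:
    """Explicit chromosome renaming (e.g. '1' → 'chr1'); no silent aliasing."""
    return [replace(iv, chrom=mapping.get(iv.chrom, iv.chrom)) for iv in intervals]
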