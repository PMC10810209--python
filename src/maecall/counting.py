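"""Alignment filtering and per-locus fragment counting.

A locus is the genomic footprint of one 25-bp insert: chromosome, start,
end — strand collapsed, because reporter activity is orientation
independent.  PCR duplicates are deliberately retained: identical inserts
produce byte-identical reads, so duplicates cannot be distinguished from
independent molecules and the normalization model accounts for
amplification instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .formats import AlignmentRecord, GenomicInterval

logger = logging.getLogger(__name__)


class LocusKey(NamedTuple):
    chrom: str
    start: int
    end: int

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class CountTable:
    """Raw fragment counts per locus for a single library."""

    counts: dict[LocusKey, int] = field(default_factory=dict)
    total_retained: int = 0
    total_records_seen: int = 0
    insert_length: int = 25

    def add(self, key: LocusKey, n: int = 1) -> None:
        if key.end - key.start != self.insert_length:
            raise ValueError(
                f"locus {key} length {key.end - key.start} != insert length "
                f"{self.insert_length}"
            )
        self.counts[key] = self.counts.get(key, 0) + n
        self.total_retained += n

    def __len__(self) -> int:
        return len(self.counts)

    def total_count(self) -> int:
        return sum(self.counts.values())


def passes_filters(
    rec: AlignmentRecord,
    max_mismatches: int = 2,
    insert_length: int = 25,
    min_mapq: int = 1,
    assume_nm0: bool = False,
) -> bool:
    """Keep uniquely mapped records spanning exactly the insert length.

    "Uniquely mapped" means: primary (not secondary/supplementary), no
    alternate-hit tag, and mapping quality ≥ ``min_mapq``.  The reference
    span must equal ``insert_length`` and the edit distance (NM tag) must
    not exceed ``max_mismatches``; a missing NM tag fails the record
    unless ``assume_nm0`` is set.
    """
    if not rec.is_mapped or rec.is_secondary or rec.is_supplementary:
        return False
    if rec.has_alt_hits or rec.mapq < min_mapq:
        return False
    if rec.aligned_length != insert_length:
        return False
    if rec.mismatches is None:
        return assume_nm0
    return rec.mismatches <= max_mismatches


def count_loci(
    records: Iterable[AlignmentRecord],
    max_mismatches: int = 2,
    insert_length: int = 25,
    min_mapq: int = 1,
    assume_nm0: bool = False,
    known_chroms: Optional[set[str]] = None,
) -> CountTable:
    """Filter a record stream and count retained fragments per locus.

    Each passing record increments exactly one locus, so the table total
    equals the number of retained records.  Duplicates are kept.
    """
    table = CountTable(insert_length=insert_length)
    warned: set[str] = set()
    for rec in records:
        table.total_records_seen += 1
        if not passes_filters(
            rec,
            max_mismatches=max_mismatches,
            insert_length=insert_length,
            min_mapq=min_mapq,
            assume_nm0=assume_nm0,
        ):
            continue
        iv = rec.interval()
        if known_chroms is not None and iv.chrom not in known_chroms:
            if iv.chrom not in warned:
                logger.warning("chromosome %s absent from genome manifest", iv.chrom)
                warned.add(iv.chrom)
        table.add(LocusKey(iv.chrom, iv.start, iv.end))
    return table


class PairedRow(NamedTuple):
    locus: LocusKey
    x: int  # input count
    y: int  # output count


def pair_tables(input_table: CountTable, output_table: CountTable) -> list[PairedRow]:
    """Join input and output counts over the union of loci (missing side 0).

    Rows are returned sorted by locus for deterministic downstream output.
    """
    if input_table.insert_length != output_table.insert_length:
        raise ValueError(
            "insert-length mismatch between tables: "
            f"{input_table.insert_length} vs {output_table.insert_length}"
        )
    keys = set(input_table.counts) | set(output_table.counts)
    return [
        PairedRow(k, input_table.counts.get(k, 0), output_table.counts.get(k, 0))
        for k in sorted(keys)
    ]
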