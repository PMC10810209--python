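"""Insert extraction from construct-flanked reads.

Each sequencing read carries the 25-bp random fragment between two fixed
construct arms.  The extractor finds a short anchor — the suffix of the
left arm and the prefix of the right arm — by Hamming-distance scan
(no indels), cuts out the between-sequence, and keeps it only when its
length equals the designed insert length.

The default arms are the synthesis construct of the assay:
left  ...GACAG | 25-bp random insert | CTGTC... right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .formats import SequenceRecord

# Flanks of the random insert in the synthesized construct
# (homologous arms + Illumina adapters).
DEFAULT_LEFT_ARM = (
    "CTAACTGGCCGGTACCTGAGCTCGCTAGCCTCGAGTCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
)
DEFAULT_RIGHT_ARM = (
    "CTGTCTCTTATACACATCTCCGAGCCCACGAGACAAGCTTAGACACTAGAGGGTATATAATGGAAGCTCG"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConstructSpec:
    """Where the insert sits in a read and how tolerant the arm search is."""

    left_arm: str = DEFAULT_LEFT_ARM
    right_arm: str = DEFAULT_RIGHT_ARM
    insert_length: int = 25
    max_arm_mismatches: int = 1
    anchor_length: int = 20

    def __post_init__(self) -> None:
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")
        if self.anchor_length < 1:
            raise ValueError("anchor_length must be >= 1")
        if self.anchor_length > len(self.left_arm) or self.anchor_length > len(
            self.right_arm
        ):
            raise ValueError("anchor_length exceeds an arm length")
        if self.max_arm_mismatches < 0:
            raise ValueError("max_arm_mismatches must be >= 0")

    @property
    def left_anchor(self) -> str:
        return self.left_arm[-self.anchor_length :]

    @property
    def right_anchor(self) -> str:
        return self.right_arm[: self.anchor_length]


@dataclass
class PrepStats:
    """Filter-chain tallies; counters are monotone down the chain."""

    total_reads: int = 0
    arms_found: int = 0
    length_pass: int = 0
    emitted: int = 0


def find_anchor(read: str, anchor: str, max_mismatches: int = 0) -> Optional[int]:
    """Leftmost position where the anchor matches within the mismatch budget.

    Hamming distance over a fixed-length window (no indels).  Returns
    None when no window qualifies.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if len(anchor) > len(read):
        return None
    # exact-match fast path (C-level scan); with a mismatch budget the
    # exact hit only bounds the search, since an earlier window may
    # match within budget
    exact = read.find(anchor)
    if max_mismatches == 0:
        return exact if exact != -1 else None
    n = len(anchor)
    limit = exact if exact != -1 else len(read) - n + 1
    for start in range(limit):
        mismatches = 0
        window = read[start : start + n]
        for a, b in zip(window, anchor):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            return start
    return exact if exact != -1 else None


def extract_insert(
    read: SequenceRecord, spec: ConstructSpec, try_reverse: bool = False
) -> Optional[SequenceRecord]:
    """Cut the insert between the two arm anchors; None when it fails QC.

    The right anchor is searched downstream of the left anchor, and the
    between-sequence must have exactly the designed length.  With
    ``try_reverse`` the reverse complement of the read is rescanned when
    the forward orientation fails (off by default: sequencing primers
    fix the orientation of the construct).
    """
    result = _extract_forward(read.sequence, read.quality, spec)
    if result is None and try_reverse:
        rc = reverse_complement(read.sequence)
        rq = read.quality[::-1] if read.quality is not None else None
        result = _extract_forward(rc, rq, spec)
    if result is None:
        return None
    seq, qual = result
    return SequenceRecord(read.id, seq, qual)


def _extract_forward(
    sequence: str, quality: Optional[str], spec: ConstructSpec
) -> Optional[tuple[str, str | None]]:
    left_pos = find_anchor(sequence, spec.left_anchor, spec.max_arm_mismatches)
    if left_pos is None:
        return None
    insert_start = left_pos + spec.anchor_length
    tail = sequence[insert_start:]
    right_pos = find_anchor(tail, spec.right_anchor, spec.max_arm_mismatches)
    if right_pos is None:
        return None
    if right_pos != spec.insert_length:
        return None  # wrong-length insert
    seq = tail[:right_pos]
    qual = (
        quality[insert_start : insert_start + right_pos]
        if quality is not None
        else None
    )
    return seq, qual


def build_read(
    insert: str,
    spec: ConstructSpec,
    read_id: str = "read",
    quality_char: str = "I",
) -> SequenceRecord:
    """Constructive inverse of :func:`extract_insert` for simulation."""
    seq = spec.left_arm + insert + spec.right_arm
    return SequenceRecord(read_id, seq, quality_char * len(seq))


def prep_library(
    reads: Iterable[SequenceRecord],
    spec: ConstructSpec,
    try_reverse: bool = False,
) -> tuple[list[SequenceRecord], PrepStats]:
    """Extract inserts from a read stream; ids preserved, tallies returned."""
    stats = PrepStats()
    inserts: list[SequenceRecord] = []
    for read in reads:
        stats.total_reads += 1
        left_pos = find_anchor(read.sequence, spec.left_anchor, spec.max_arm_mismatches)
        seq = read.sequence
        qual = read.quality
        if left_pos is None and try_reverse:
            seq = reverse_complement(read.sequence)
            qual = read.quality[::-1] if read.quality is not None else None
            left_pos = find_anchor(seq, spec.left_anchor, spec.max_arm_mismatches)
        if left_pos is None:
            continue
        insert_start = left_pos + spec.anchor_length
        tail = seq[insert_start:]
        right_pos = find_anchor(tail, spec.right_anchor, spec.max_arm_mismatches)
        if right_pos is None:
            continue
        stats.arms_found += 1
        if right_pos != spec.insert_length:
            continue
        stats.length_pass += 1
        insert_qual = (
            qual[insert_start : insert_start + right_pos] if qual is not None else None
        )
        inserts.append(SequenceRecord(read.id, tail[:right_pos], insert_qual))
        stats.emitted += 1
    return inserts, stats
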