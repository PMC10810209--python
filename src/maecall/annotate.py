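"""Interval-overlap classification of called loci.

Covers the downstream questions asked of a set of 25-bp calls: do they
sit in marked chromatin (peak overlap with ±2500 bp padding, since
histone marks decorate nucleosomes flanking the element rather than the
element itself), are they previously catalogued (known vs novel), are
they accessible (open vs closed), which genomic feature do they fall in,
how far from the nearest TSS, and do they coincide with chromatin-loop
anchors.

All overlap predicates are half-open: touching intervals never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from intervaltree import IntervalTree

from .formats import GenomicInterval, PathLike, read_bed


def _build_trees(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(regions):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def merge_intervals(regions: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (not merely touching) intervals per chromosome."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in regions}):
        ivs = sorted(
            (iv for iv in regions if iv.chrom == chrom), key=lambda v: (v.start, v.end)
        )
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


@dataclass
class PeakSet:
    """A named collection of peak intervals with an on-use padding."""

    name: str
    intervals: list[GenomicInterval]
    pad: int = 0

    def __post_init__(self) -> None:
        if self.pad < 0:
            raise ValueError("pad must be non-negative")
        self.intervals = sorted(self.intervals, key=lambda v: (v.chrom, v.start, v.end))

    @classmethod
    def from_bed(cls, name: str, path: PathLike, pad: int = 0) -> "PeakSet":
        return cls(name=name, intervals=read_bed(path), pad=pad)

    def padded_intervals(self, pad: Optional[int] = None) -> list[GenomicInterval]:
        use = self.pad if pad is None else pad
        if use == 0:
            return list(self.intervals)
        padded = [
            GenomicInterval(iv.chrom, max(0, iv.start - use), iv.end + use)
            for iv in self.intervals
        ]
        return merge_intervals(padded)


def extend_peaks(peaks: PeakSet, pad: int = 2500) -> PeakSet:
    """Extend every peak by ±pad bp (clamped at 0) and merge overlaps."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    return PeakSet(name=peaks.name, intervals=peaks.padded_intervals(pad), pad=0)


class OverlapSummary(NamedTuple):
    frac_loci_hit: float
    frac_regions_hit: float


def overlap_any(
    loci: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> tuple[list[bool], OverlapSummary]:
    """Flag each locus that shares ≥1 bp with any region.

    Returns per-locus flags plus both summary directions: the fraction
    of loci hitting at least one region, and the fraction of regions hit
    by at least one locus.
    """
    trees = _build_trees(regions)
    flags: list[bool] = []
    regions_hit: set[int] = set()
    for locus in loci:
        tree = trees.get(locus.chrom)
        hits = tree.overlap(locus.start, locus.end) if tree is not None else set()
        flags.append(bool(hits))
        regions_hit.update(h.data for h in hits)
    summary = OverlapSummary(
        frac_loci_hit=(sum(flags) / len(loci)) if loci else 0.0,
        frac_regions_hit=(len(regions_hit) / len(regions)) if regions else 0.0,
    )
    return flags, summary


def overlap_fraction_threshold(
    loci: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    min_fraction: float,
) -> list[bool]:
    """Flag loci whose covered fraction by the region union meets the bar.

    Coverage is computed against the merged union of regions so stacked
    peaks are not double counted.  Used with 0.3 for ChIP-peak overlap
    and 0.9 for motif-region overlap.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    merged = merge_intervals(regions) if regions else []
    trees = _build_trees(merged)
    flags: list[bool] = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        covered = 0
        if tree is not None:
            for hit in tree.overlap(locus.start, locus.end):
                covered += min(hit.end, locus.end) - max(hit.begin, locus.start)
        flags.append(covered / locus.length >= min_fraction)
    return flags


def classify_known_novel(
    loci: Sequence[GenomicInterval], datasets: Sequence[PeakSet]
) -> tuple[list[str], dict[str, list[bool]]]:
    """Label each locus known (overlaps any evidence set, padded) or novel.

    Evidence sets are typically EnhancerAtlas regions, DNase/ATAC peaks
    and H3K4me1/H3K27ac ChIP peaks with ±2500 bp pads.  Per-dataset hit
    flags are returned alongside the labels.
    """
    if not datasets:
        raise ValueError("at least one evidence dataset is required")
    per_dataset: dict[str, list[bool]] = {}
    for ds in datasets:
        flags, _ = overlap_any(loci, ds.padded_intervals())
        per_dataset[ds.name] = flags
    labels = [
        "known" if any(per_dataset[ds.name][i] for ds in datasets) else "novel"
        for i in range(len(loci))
    ]
    return labels, per_dataset


def classify_accessibility(
    loci: Sequence[GenomicInterval],
    dhs: Optional[PeakSet] = None,
    atac: Optional[PeakSet] = None,
) -> list[str]:
    """Label loci open (overlap unpadded DNase∪ATAC peaks) or closed."""
    if dhs is None and atac is None:
        raise ValueError("at least one accessibility peak set is required")
    union: list[GenomicInterval] = []
    if dhs is not None:
        union.extend(dhs.intervals)
    if atac is not None:
        union.extend(atac.intervals)
    flags, _ = overlap_any(loci, union)
    return ["open" if f else "closed" for f in flags]


@dataclass(frozen=True)
class Transcript:
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[GenomicInterval, ...]
    thick_start: int
    thick_end: int
    name: Optional[str] = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def introns(self) -> list[GenomicInterval]:
        out = []
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return out

    def _utr_intervals(self, five_prime: bool) -> list[GenomicInterval]:
        # UTRs are exonic sequence outside the thick (CDS) region
        if self.thick_start >= self.thick_end:  # non-coding: no UTRs
            return []
        left = five_prime == (self.strand == "+")
        out = []
        for exon in self.exons:
            if left:
                lo, hi = exon.start, min(exon.end, self.thick_start)
            else:
                lo, hi = max(exon.start, self.thick_end), exon.end
            if hi > lo:
                out.append(GenomicInterval(self.chrom, lo, hi))
        return out

    def utr5(self) -> list[GenomicInterval]:
        return self._utr_intervals(five_prime=True)

    def utr3(self) -> list[GenomicInterval]:
        return self._utr_intervals(five_prime=False)


@dataclass
class GeneModel:
    """Transcript models supplying TSS/TTS positions, exons and UTRs."""

    transcripts: list[Transcript] = field(default_factory=list)

    @classmethod
    def from_bed12(cls, path: PathLike) -> "GeneModel":
        """Build from BED12: exon blocks; UTRs derived from thick coords."""
        transcripts = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"line {line_no}: BED12 needs 12 columns")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = [int(s) for s in f[10].rstrip(",").split(",")]
                offsets = [int(s) for s in f[11].rstrip(",").split(",")]
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size)
                    for off, size in zip(offsets, sizes)
                )
                transcripts.append(
                    Transcript(
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        exons=exons,
                        thick_start=thick_start,
                        thick_end=thick_end,
                        name=name,
                    )
                )
        return cls(transcripts=transcripts)


FEATURE_PRIORITY = ("TTS", "5UTR", "3UTR", "exon", "intron", "intergenic")

TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


def _tts_window(t: Transcript) -> GenomicInterval:
    # strand-aware window from -100 bp to +1 kb around the termination site
    if t.strand == "+":
        lo, hi = t.tts - TTS_UPSTREAM, t.tts + TTS_DOWNSTREAM
    else:
        lo, hi = t.tts - TTS_DOWNSTREAM, t.tts + TTS_UPSTREAM
    return GenomicInterval(t.chrom, max(0, lo), max(1, hi))


class FeatureIndex:
    """Prebuilt interval trees for each feature category of a gene model."""

    def __init__(self, model: GeneModel) -> None:
        cats: dict[str, list[GenomicInterval]] = {
            "TTS": [],
            "5UTR": [],
            "3UTR": [],
            "exon": [],
            "intron": [],
        }
        for t in model.transcripts:
            cats["TTS"].append(_tts_window(t))
            cats["5UTR"].extend(t.utr5())
            cats["3UTR"].extend(t.utr3())
            cats["exon"].extend(t.exons)
            cats["intron"].extend(t.introns())
        self._trees = {name: _build_trees(ivs) for name, ivs in cats.items()}

    def annotate(self, locus: GenomicInterval) -> str:
        for category in FEATURE_PRIORITY[:-1]:
            tree = self._trees[category].get(locus.chrom)
            if tree is not None and tree.overlaps(locus.start, locus.end):
                return category
        return "intergenic"


def annotate_feature(locus: GenomicInterval, model: GeneModel) -> str:
    """Feature category of one locus; see :func:`annotate_features` for batches."""
    return FeatureIndex(model).annotate(locus)


def annotate_features(loci: Sequence[GenomicInterval], model: GeneModel) -> list[str]:
    index = FeatureIndex(model)
    return [index.annotate(locus) for locus in loci]


def distance_to_tss(locus: GenomicInterval, model: GeneModel) -> Optional[int]:
    """Distance from the locus midpoint to the nearest TSS on its chromosome.

    Returns None ("unannotated") when the chromosome carries no transcript.
    """
    tss = [t.tss for t in model.transcripts if t.chrom == locus.chrom]
    if not tss:
        return None
    mid = locus.midpoint()
    return min(abs(mid - pos) for pos in tss)


@dataclass
class LoopSet:
    """Chromatin interactions as anchor-interval pairs (BEDPE)."""

    loops: list[tuple[GenomicInterval, GenomicInterval]]

    @classmethod
    def from_bedpe(cls, path: PathLike) -> "LoopSet":
        from .formats import read_bedpe

        return cls(loops=read_bedpe(path))


class AnchorHits(NamedTuple):
    flags: list[bool]
    spans: list[list[int]]  # per locus: midpoint distances of the loops hit
    n_flagged: int


def overlap_loop_anchors(
    loci: Sequence[GenomicInterval], loops: LoopSet
) -> AnchorHits:
    """Flag loci overlapping either anchor of any loop; report loop spans."""
    anchors: list[GenomicInterval] = []
    loop_of_anchor: list[int] = []
    for i, (a, b) in enumerate(loops.loops):
        anchors.extend((a, b))
        loop_of_anchor.extend((i, i))
    trees = _build_trees(anchors)
    spans_by_loop = [
        abs(b.midpoint() - a.midpoint()) if a.chrom == b.chrom else -1
        for a, b in loops.loops
    ]
    flags: list[bool] = []
    spans: list[list[int]] = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        hits = tree.overlap(locus.start, locus.end) if tree is not None else set()
        loop_ids = sorted({loop_of_anchor[h.data] for h in hits})
        flags.append(bool(loop_ids))
        spans.append([spans_by_loop[i] for i in loop_ids])
    return AnchorHits(flags=flags, spans=spans, n_flagged=sum(flags))
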