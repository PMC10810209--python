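"""Annotating called loci against chromatin evidence and gene models.

Classifies three 25-bp loci as known/novel (peak overlap with ±2500 bp
padding), open/closed chromatin (unpadded accessibility peaks), genomic
feature, and distance to the nearest TSS.
"""

from maecall import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    Transcript,
    annotate_features,
    classify_accessibility,
    classify_known_novel,
    distance_to_tss,
)

loci = [
    GenomicInterval("chr1", 10_400, 10_425),   # inside an H3K4me1 peak
    GenomicInterval("chr1", 13_000, 13_025),   # within 2500 bp of the peak
    GenomicInterval("chr1", 40_000, 40_025),   # far from everything
]

h3k4me1 = PeakSet("H3K4me1", [GenomicInterval("chr1", 10_000, 11_000)], pad=2500)
atac = PeakSet("ATAC", [GenomicInterval("chr1", 10_300, 10_600)])

labels, hits = classify_known_novel(loci, [h3k4me1])
chromatin = classify_accessibility(loci, atac=atac)

genes = GeneModel([
    Transcript(
        chrom="chr1", strand="+", start=12_000, end=20_000,
        exons=(GenomicInterval("chr1", 12_000, 12_500),
               GenomicInterval("chr1", 18_000, 20_000)),
        thick_start=12_200, thick_end=19_500, name="geneA",
    )
])
features = annotate_features(loci, genes)

for locus, label, state, feature in zip(loci, labels, chromatin, features):
    d = distance_to_tss(locus, genes)
    print(
        f"{locus.chrom}:{locus.start}-{locus.end}  {label:5s}  {state:6s}  "
        f"{feature:10s}  TSS distance {d} bp"
    )

# "known" means the locus overlaps at least one evidence set after padding;
# "open" means it overlaps an unpadded accessibility peak.
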