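"""The enrichment model on a two-locus toy table, by hand-checkable numbers.

Both libraries have N = 1000 reads, PCR efficiency p = 1 and c = 15
cycles, so the zoom factor is omega = 10^4 and both normalization
coefficients equal 10^4 / (1000 * 15 * ln 2) ~ 0.9618.  One locus is
seen in both libraries (x=2, y=8); the second is absent from the input
(x=0, y=8) and receives the compensation value kappa = coef_in.
"""

from maecall import LibraryStats, LocusKey, PairedRow, build_model, call_enhancers

stats = LibraryStats(total_reads=1000, pcr_efficiency=1.0, pcr_cycles=15)
rows = [
    PairedRow(LocusKey("chr1", 0, 25), x=2, y=8),
    PairedRow(LocusKey("chr1", 100, 125), x=0, y=8),
]

model = build_model(stats, stats)
print(f"omega   = {model.omega:g}")
print(f"coef    = {model.coef_in:.5f}   (same for both libraries here)")
print(f"kappa   = {model.kappa:.5f}   (compensation for input-absent loci)")

for rec in call_enhancers(rows, stats, stats):
    print(
        f"locus {rec.locus.chrom}:{rec.locus.start}-{rec.locus.end} "
        f"x={rec.x} y={rec.y} lambda={rec.lam:.5f} k={rec.k:g} "
        f"p={rec.pvalue:.3g} Q={rec.qvalue:.3g} "
        f"{'(compensated)' if rec.compensated else ''}"
    )

# The compensated locus is far more significant: with no input evidence its
# expected rate is a single normalized read, so eight output reads are a
# strong enrichment signal.
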