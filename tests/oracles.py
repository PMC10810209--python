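"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct summation, all-pairs
scans, literal re-implementations — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def poisson_upper_tail_by_summation(k: int, lam: float) -> float:
    """P(K >= k | lam) = 1 - sum_{j<k} lam^j e^-lam / j!, term by term."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = 0.0
    log_lam = math.log(lam)
    for j in range(k):
        total += math.exp(j * log_lam - lam - math.lgamma(j + 1))
    return max(0.0, 1.0 - total)


def poisson_upper_tail_direct(k: int, lam: float) -> float:
    """Upper tail by summing the tail itself (stable far out)."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    # sum pmf upward from k until terms vanish
    log_term = k * math.log(lam) - lam - math.lgamma(k + 1)
    total = 0.0
    j = k
    while True:
        term = math.exp(log_term)
        total += term
        if term < 1e-300 or (total > 0 and term / total < 1e-17):
            break
        j += 1
        log_term += math.log(lam) - math.log(j)
    return min(1.0, total)


def bh_stepup(pvalues):
    """Literal Benjamini–Hochberg step-up, returned in the input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def intervals_overlap(a, b) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_force_overlap_flags(loci, regions):
    return [any(intervals_overlap(l, r) for r in regions) for l in loci]


def brute_force_region_hits(loci, regions):
    return [any(intervals_overlap(l, r) for l in loci) for r in regions]


def brute_force_covered_bp(locus, regions):
    """Covered base pairs of locus by the union of regions, per-base scan."""
    return sum(
        1
        for pos in range(locus.start, locus.end)
        if any(r.chrom == locus.chrom and r.start <= pos < r.end for r in regions)
    )


def brute_force_merge(regions):
    """Per-base union reconstruction of merged intervals."""
    out = []
    for chrom in sorted({r.chrom for r in regions}):
        positions = set()
        for r in regions:
            if r.chrom == chrom:
                positions.update(range(r.start, r.end))
        if not positions:
            continue
        run_start = None
        prev = None
        for pos in sorted(positions):
            if run_start is None:
                run_start = pos
            elif pos != prev + 1:
                out.append((chrom, run_start, prev + 1))
                run_start = pos
            prev = pos
        out.append((chrom, run_start, prev + 1))
    return out


def naive_occurrences(genome_records, fragment: str) -> int:
    """Sliding-window occurrence scan, both strands, positions deduplicated."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(fragment))
    count = 0
    L = len(fragment)
    for rec in genome_records:
        seq = rec.sequence
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if window == fragment or window == rc:
                count += 1
    return count
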