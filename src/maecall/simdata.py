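"""Synthetic genomes and reporter-screen datasets with known ground truth.

The generator emulates the screen end to end: a pool of distinct 25-bp
genomic fragments cloned upstream of a minimal promoter, branching-PCR
amplification (each molecule duplicates independently with probability
p per cycle, so the expected amplification after c cycles is (1+p)^c —
exactly the factor the normalization model divides out), and
sorting-based enrichment in which fragments overlapping planted
enhancers are over-sampled into the output library by a multiplicative
fold.  Reads are emitted with the real construct arms so the full
prep → align → count → call path can run on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .counting import CountTable, LocusKey
from .calling import LibraryStats
from .formats import GenomicInterval, SequenceRecord, write_fasta, write_fastq, write_bed
from .readprep import DEFAULT_LEFT_ARM, DEFAULT_RIGHT_ARM

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults are the reference conditions used throughout the test
    suite: 5000 distinct fragments, 50 planted enhancers at 20-fold
    enrichment, half a million reads per library, deterministic PCR
    (p = 1) with 15 input and 10 output cycles, on a 200-kb two-
    chromosome genome where 25-mers are effectively unique.

    Both libraries are amplified for the same number of cycles by
    default.  Under the branching-PCR model amplification preserves
    expected fragment frequencies, while the normalization divides by
    c·log(1+p); with unequal cycle counts the normalized output is
    scaled by c_in/c_out relative to the input, which biases the test.
    Matched cycles keep the simulated screen inside the regime the
    model is calibrated for.
    """

    genome_length: int = 200_000
    n_chroms: int = 2
    repeat_fraction: float = 0.0
    repeat_unit_length: int = 200
    n_enhancers: int = 50
    enhancer_length: int = 25
    enrichment_fold: Union[float, tuple[float, float]] = 20.0
    library_complexity: int = 5000
    depth_input: int = 500_000
    depth_output: int = 500_000
    pcr_p: float = 1.0
    pcr_c_in: int = 15
    pcr_c_out: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if self.n_enhancers * self.enhancer_length > self.genome_length:
            raise ValueError("enhancers do not fit in the genome")
        if self.depth_input < 1 or self.depth_output < 1:
            raise ValueError("depths must be >= 1")
        if self.n_enhancers > self.library_complexity:
            raise ValueError("n_enhancers cannot exceed library_complexity")


@dataclass
class SimTruth:
    """Planted enhancers (interval, fold) and the fragment pool."""

    enhancers: list[tuple[GenomicInterval, float]]
    fragments: list[tuple[GenomicInterval, int]]  # pre-PCR molecule count (1 each)


@dataclass
class SimulatedScreen:
    """Everything one simulated screen produced."""

    truth: SimTruth
    input_counts: CountTable
    output_counts: CountTable
    input_stats: LibraryStats
    output_stats: LibraryStats
    input_molecules: np.ndarray  # post-PCR molecules per fragment, input arm
    output_molecules: np.ndarray
    input_fastq: Optional[Path] = None
    output_fastq: Optional[Path] = None


def simulate_genome(
    cfg: SimConfig, seed: Optional[int] = None
) -> tuple[list[SequenceRecord], list[GenomicInterval]]:
    """I.i.d. uniform-base chromosomes, optionally with a planted repeat.

    When ``repeat_fraction`` > 0, the tail fraction of each chromosome
    is overwritten with tandem copies of one shared sampled unit of
    ``repeat_unit_length`` bp, creating non-unique k-mers over that
    fraction of positions; the overwritten regions are returned as a
    repeat annotation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    per_chrom = cfg.genome_length // cfg.n_chroms
    records: list[SequenceRecord] = []
    repeat_bed: list[GenomicInterval] = []
    unit: Optional[str] = None
    for i in range(cfg.n_chroms):
        length = per_chrom if i < cfg.n_chroms - 1 else cfg.genome_length - per_chrom * (
            cfg.n_chroms - 1
        )
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if cfg.repeat_fraction > 0:
            if unit is None:
                start = int(rng.integers(0, max(1, length - cfg.repeat_unit_length)))
                unit = seq[start : start + cfg.repeat_unit_length]
            n_repeat = int(round(length * cfg.repeat_fraction))
            if n_repeat > 0:
                tile = (unit * (n_repeat // len(unit) + 1))[:n_repeat]
                seq = seq[: length - n_repeat] + tile
                repeat_bed.append(GenomicInterval(f"chr{i+1}", length - n_repeat, length))
        records.append(SequenceRecord(f"chr{i+1}", seq))
    return records, repeat_bed


def galton_watson(
    n_fragments: int, p: float, c: int, rng: np.random.Generator
) -> np.ndarray:
    """Molecule counts after c PCR cycles, starting from one molecule each.

    Every molecule duplicates independently with probability p per
    cycle, so E[molecules] = (1+p)^c; p = 1 is the deterministic
    doubling limit (exactly 2^c).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if c < 0:
        raise ValueError("c must be >= 0")
    if p == 1.0:
        return np.full(n_fragments, 2**c, dtype=np.int64)
    m = np.ones(n_fragments, dtype=np.int64)
    for _ in range(c):
        m = m + rng.binomial(m, p)
    return m


def _sample_fragment_positions(
    genome: Sequence[SequenceRecord],
    n: int,
    length: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """n distinct (chrom, offset) windows, uniform over valid positions."""
    chrom_sizes = [(rec.id, len(rec.sequence) - length + 1) for rec in genome]
    chrom_sizes = [(c, s) for c, s in chrom_sizes if s > 0]
    total = sum(s for _, s in chrom_sizes)
    if n > total:
        raise ValueError(f"cannot sample {n} distinct windows from {total} available")
    flat = rng.choice(total, size=n, replace=False)
    out: list[GenomicInterval] = []
    bounds = np.cumsum([s for _, s in chrom_sizes])
    for pos in np.sort(flat):
        idx = int(np.searchsorted(bounds, pos, side="right"))
        offset = int(pos - (bounds[idx - 1] if idx > 0 else 0))
        chrom = chrom_sizes[idx][0]
        out.append(GenomicInterval(chrom, offset, offset + length))
    return out


def simulate_screen(
    cfg: SimConfig,
    genome: Sequence[SequenceRecord],
    seed: Optional[int] = None,
    out_dir: Optional[Union[str, Path]] = None,
    left_arm: str = DEFAULT_LEFT_ARM,
    right_arm: str = DEFAULT_RIGHT_ARM,
) -> SimulatedScreen:
    """Simulate one paired input/output screen over a genome.

    Mechanics: sample ``library_complexity`` distinct 25-bp fragment
    positions; designate ``n_enhancers`` of them enhancers with the
    configured fold; amplify each pool arm independently by branching
    PCR; draw the input library multinomially over input-arm molecule
    counts and the output library over output-arm counts weighted by
    the enhancer folds; record truth and per-locus count tables.  When
    ``out_dir`` is given, construct-flanked FASTQ files (and the truth
    BED) are written so the full read-level pipeline can run.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = cfg.enhancer_length
    fragments = _sample_fragment_positions(genome, cfg.library_complexity, L, rng)
    genome_by_id = {rec.id: rec.sequence for rec in genome}

    enhancer_idx = rng.choice(len(fragments), size=cfg.n_enhancers, replace=False)
    folds = np.ones(len(fragments))
    if isinstance(cfg.enrichment_fold, tuple):
        lo, hi = cfg.enrichment_fold
        folds[enhancer_idx] = rng.uniform(lo, hi, size=cfg.n_enhancers)
    else:
        folds[enhancer_idx] = float(cfg.enrichment_fold)

    input_molecules = galton_watson(len(fragments), cfg.pcr_p, cfg.pcr_c_in, rng)
    output_molecules = galton_watson(len(fragments), cfg.pcr_p, cfg.pcr_c_out, rng)

    w_in = input_molecules / input_molecules.sum()
    w_out = output_molecules * folds
    w_out = w_out / w_out.sum()
    x = rng.multinomial(cfg.depth_input, w_in)
    y = rng.multinomial(cfg.depth_output, w_out)

    input_counts = CountTable(insert_length=L)
    output_counts = CountTable(insert_length=L)
    for frag, xi, yi in zip(fragments, x, y):
        key = LocusKey(frag.chrom, frag.start, frag.end)
        if xi > 0:
            input_counts.add(key, int(xi))
        if yi > 0:
            output_counts.add(key, int(yi))
    input_counts.total_records_seen = int(x.sum())
    output_counts.total_records_seen = int(y.sum())

    truth = SimTruth(
        enhancers=[(fragments[i], float(folds[i])) for i in sorted(enhancer_idx)],
        fragments=[(frag, 1) for frag in fragments],
    )
    screen = SimulatedScreen(
        truth=truth,
        input_counts=input_counts,
        output_counts=output_counts,
        input_stats=LibraryStats(int(x.sum()), cfg.pcr_p, cfg.pcr_c_in),
        output_stats=LibraryStats(int(y.sum()), cfg.pcr_p, cfg.pcr_c_out),
        input_molecules=input_molecules,
        output_molecules=output_molecules,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out_dir / "genome.fa")
        write_bed(
            [
                GenomicInterval(e.chrom, e.start, e.end, name=f"enh_fold{fold:g}")
                for e, fold in truth.enhancers
            ],
            out_dir / "truth.bed",
        )
        for label, reads_per_frag, path_attr in (
            ("input", x, "input_fastq"),
            ("output", y, "output_fastq"),
        ):
            path = out_dir / f"{label}.fq.gz"
            write_fastq(
                _emit_reads(fragments, reads_per_frag, genome_by_id, left_arm, right_arm, label),
                path,
            )
            setattr(screen, path_attr, path)
    return screen


def _emit_reads(fragments, reads_per_frag, genome_by_id, left_arm, right_arm, label):
    for i, (frag, n) in enumerate(zip(fragments, reads_per_frag)):
        if n <= 0:
            continue
        insert = genome_by_id[frag.chrom][frag.start : frag.end]
        seq = left_arm + insert + right_arm
        qual = "I" * len(seq)
        for j in range(int(n)):
            yield SequenceRecord(f"{label}_f{i}_r{j}", seq, qual)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    empirical_fdr: float
    n_called: int
    n_true: int
    n_true_positive: int
    zero_calls: bool


def evaluate_calls(calls, truth: SimTruth) -> EvalResult:
    """Score calls against planted enhancers by exact interval identity.

    With zero calls precision is reported as 1 (nothing wrongly called)
    with the ``zero_calls`` flag set.
    """
    true_set = {
        (iv.chrom, iv.start, iv.end) for iv, _fold in truth.enhancers
    }
    called = [r for r in calls if r.called]
    tp = sum(
        1
        for r in called
        if (r.locus.chrom, r.locus.start, r.locus.end) in true_set
    )
    n_called = len(called)
    precision = tp / n_called if n_called else 1.0
    recall = tp / len(true_set) if true_set else 0.0
    return EvalResult(
        precision=precision,
        recall=recall,
        empirical_fdr=1.0 - precision,
        n_called=n_called,
        n_true=len(true_set),
        n_true_positive=tp,
        zero_calls=n_called == 0,
    )
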