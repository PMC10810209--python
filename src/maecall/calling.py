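"""The enrichment model: normalization, zoom factor, Poisson test, BH selection.

The screen compares an input library (all transfected cells) against an
output library (fluorescence-sorted cells).  Raw counts are not
comparable across libraries because of library size and PCR
amplification, so each count x is normalized as

    f(x) = x * omega / (N * c * log(1 + p))

where N is the library's total read count, p its per-cycle PCR
efficiency, c its cycle number, and omega a zoom factor shared by the
pair that rescales the normalized frequencies back onto a count scale —
a Poisson test on values much below 1 would have no power.

Per locus, the expected count lambda is the normalized input count (or a
compensation value kappa = m * coef_in when the locus is absent from the
input), the observation k is the rounded normalized output count, and
the one-sided upper-tail Poisson p-value P(K >= k | lambda) measures
enrichment.  Benjamini–Hochberg Q-values across all tested loci select
calls at Q < alpha.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .counting import LocusKey, PairedRow
from .formats import GenomicInterval

logger = logging.getLogger(__name__)

OmegaMode = Literal["power", "literal"]
LogBase = Literal["natural", "base10"]
KMode = Literal["rounded", "continuous"]


@dataclass(frozen=True)
class LibraryStats:
    """Per-library sequencing totals and PCR parameters.

    ``pcr_cycles`` is the number of amplification cycles used to build
    the library (15 for a typical input library; outputs are usually
    amplified for 5–15 cycles).  ``pcr_efficiency`` is the per-cycle
    duplication probability, default 1 (every molecule doubles).
    """

    total_reads: int
    pcr_efficiency: float = 1.0
    pcr_cycles: int = 15

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if not 0.0 < self.pcr_efficiency <= 1.0:
            raise ValueError("pcr_efficiency must be in (0, 1]")
        if self.pcr_cycles < 1:
            raise ValueError("pcr_cycles must be >= 1")


def zoom_factor(total_input: int, total_output: int, mode: OmegaMode = "power") -> float:
    """Zoom factor ω from the smaller of the two library totals.

    With d = floor(log10(MIN(totals))) + 1 (the decimal digit count of
    the smaller total), mode "power" gives 10**d — the next power of ten
    above MIN, which puts normalized frequencies back on a count scale —
    while mode "literal" gives 10*d, the formula read literally.
    Symmetric in its arguments.
    """
    if total_input <= 0 or total_output <= 0:
        raise ValueError("library totals must be positive")
    # digit count of the integer avoids float log10 edge cases at powers of 10
    d = len(str(int(min(total_input, total_output))))
    if mode == "power":
        return float(10**d)
    if mode == "literal":
        return float(10 * d)
    raise ValueError(f"unknown omega mode: {mode!r}")


def normalization_coefficient(
    stats_: LibraryStats, omega: float, log_base: LogBase = "natural"
) -> float:
    """coef = ω / (N · c · log(1+p)); normalized count f(x) = x · coef."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    log = math.log if log_base == "natural" else math.log10
    denom_log = log(1.0 + stats_.pcr_efficiency)
    if denom_log == 0.0:
        raise ValueError("log(1+p) is zero; pcr_efficiency must exceed 0")
    return omega / (stats_.total_reads * stats_.pcr_cycles * denom_log)


def normalize_count(x: float, coef: float) -> float:
    """f(x) = x · coef — linear, so f(0)=0 and f(a+b)=f(a)+f(b)."""
    if x < 0:
        raise ValueError("count must be non-negative")
    return x * coef


def poisson_upper_pvalue(k: float, lam: float) -> float:
    """Upper-tail Poisson probability P(K >= k | lambda).

    Computed through the survival function (regularized incomplete
    gamma), not by subtracting a CDF from one, so it stays accurate in
    the far tail.  k = 0 returns 1 for any rate.
    """
    if math.isnan(k) or math.isnan(lam):
        raise ValueError("NaN input to poisson_upper_pvalue")
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k <= 0:
        return 1.0
    # P(K >= k) = Q(floor(k)-1 CDF complement) = gammainc(k, lam) for integer k
    return float(stats.poisson.sf(math.ceil(k) - 1, lam))


def poisson_upper_pvalue_continuous(k: float, lam: float) -> float:
    """Gamma-survival relaxation of the upper tail for non-integer k.

    P(K >= k) = gammainc(k, lam) (regularized lower incomplete gamma),
    which interpolates the integer survival function; used by
    ``k_mode="continuous"`` as a rounding-free sensitivity check.
    """
    if math.isnan(k) or math.isnan(lam):
        raise ValueError("NaN input")
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k <= 0:
        return 1.0
    return float(special.gammainc(k, lam))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up Q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CallingModel:
    """The shared quantities of one calling run, for logging/audit."""

    omega: float
    coef_in: float
    coef_out: float
    kappa: float  # compensation value = multiplier * coef_in
    compensation_multiplier: float
    alpha: float


@dataclass
class CallRecord:
    """Per-locus test result."""

    locus: LocusKey
    x: int
    y: int
    f_in: float
    f_out: float
    lam: float
    k: float
    pvalue: Optional[float]
    qvalue: Optional[float]
    called: bool
    compensated: bool

    def to_row(self) -> dict:
        return {
            "chrom": self.locus.chrom,
            "start": self.locus.start,
            "end": self.locus.end,
            "x": self.x,
            "y": self.y,
            "f_in": self.f_in,
            "f_out": self.f_out,
            "lambda": self.lam,
            "k": self.k,
            "pvalue": self.pvalue if self.pvalue is not None else float("nan"),
            "qvalue": self.qvalue if self.qvalue is not None else float("nan"),
            "called": self.called,
            "compensated": self.compensated,
        }


def build_model(
    input_stats: LibraryStats,
    output_stats: LibraryStats,
    compensation_multiplier: float = 1.0,
    alpha: float = 0.05,
    omega_mode: OmegaMode = "power",
    log_base: LogBase = "natural",
) -> CallingModel:
    omega = zoom_factor(input_stats.total_reads, output_stats.total_reads, omega_mode)
    coef_in = normalization_coefficient(input_stats, omega, log_base)
    coef_out = normalization_coefficient(output_stats, omega, log_base)
    return CallingModel(
        omega=omega,
        coef_in=coef_in,
        coef_out=coef_out,
        kappa=compensation_multiplier * coef_in,
        compensation_multiplier=compensation_multiplier,
        alpha=alpha,
    )


def call_enhancers(
    rows: Sequence[PairedRow],
    input_stats: LibraryStats,
    output_stats: LibraryStats,
    compensation_multiplier: float = 1.0,
    alpha: float = 0.05,
    omega_mode: OmegaMode = "power",
    log_base: LogBase = "natural",
    k_mode: KMode = "rounded",
) -> list[CallRecord]:
    """Run the full enrichment test over paired (locus, x, y) rows.

    Loci absent from the output (y = 0) are not tested — the screen only
    calls positives.  Loci absent from the input (x = 0, y > 0) receive
    the compensation value kappa = multiplier * coef_in as their rate.
    Q-values are BH-adjusted across all tested loci; called means
    Q < alpha.
    """
    model = build_model(
        input_stats,
        output_stats,
        compensation_multiplier,
        alpha,
        omega_mode,
        log_base,
    )
    logger.info(
        "calling model: omega=%g coef_in=%g coef_out=%g kappa=%g",
        model.omega,
        model.coef_in,
        model.coef_out,
        model.kappa,
    )

    x = np.array([r.x for r in rows], dtype=float)
    y = np.array([r.y for r in rows], dtype=float)
    f_in = x * model.coef_in
    f_out = y * model.coef_out
    lam = np.where(x > 0, f_in, model.kappa)
    tested = y > 0
    compensated = (x == 0) & tested

    if k_mode == "rounded":
        k = np.floor(f_out + 0.5)  # half away from zero (counts are >= 0)
        pvals_tested = stats.poisson.sf(k[tested] - 1, lam[tested])
    elif k_mode == "continuous":
        k = f_out
        kt = k[tested]
        pvals_tested = np.where(kt <= 0, 1.0, special.gammainc(np.maximum(kt, 1e-300), lam[tested]))
    else:
        raise ValueError(f"unknown k mode: {k_mode!r}")

    qvals_tested = bh_adjust(pvals_tested) if pvals_tested.size else np.array([])

    records: list[CallRecord] = []
    ti = 0
    for i, row in enumerate(rows):
        if tested[i]:
            pv = float(pvals_tested[ti])
            qv = float(qvals_tested[ti])
            ti += 1
            records.append(
                CallRecord(
                    locus=row.locus,
                    x=row.x,
                    y=row.y,
                    f_in=float(f_in[i]),
                    f_out=float(f_out[i]),
                    lam=float(lam[i]),
                    k=float(k[i]),
                    pvalue=pv,
                    qvalue=qv,
                    called=qv < alpha,
                    compensated=bool(compensated[i]),
                )
            )
        else:
            records.append(
                CallRecord(
                    locus=row.locus,
                    x=row.x,
                    y=row.y,
                    f_in=float(f_in[i]),
                    f_out=0.0,
                    lam=float(lam[i]),
                    k=0.0,
                    pvalue=None,
                    qvalue=None,
                    called=False,
                    compensated=False,
                )
            )
    n_called = sum(r.called for r in records)
    logger.info("tested %d loci, called %d at Q<%g", int(tested.sum()), n_called, alpha)
    return records


@dataclass(frozen=True)
class SweepRow:
    multiplier: float
    n_called: int
    non_overlap_rate: float


def compensation_sweep(
    rows: Sequence[PairedRow],
    input_stats: LibraryStats,
    output_stats: LibraryStats,
    annotated_regions: Sequence[GenomicInterval],
    multipliers: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
    omega_mode: OmegaMode = "power",
    log_base: LogBase = "natural",
    k_mode: KMode = "rounded",
) -> list[SweepRow]:
    """Calibrate the compensation multiplier over a grid (default 0.1–3.0).

    For each multiplier the caller is rerun and two diagnostics recorded:
    the number of surviving calls and the fraction of calls that overlap
    no annotated region.  A higher multiplier makes the test on
    input-absent loci more stringent.
    """
    from .annotate import overlap_any  # local import to avoid a cycle

    if multipliers is None:
        multipliers = [round(0.1 * i, 1) for i in range(1, 31)]
    if len(multipliers) == 0:
        raise ValueError("multiplier list must be non-empty")
    if len(annotated_regions) == 0:
        raise ValueError("annotated_regions must be non-empty")

    out: list[SweepRow] = []
    for m in multipliers:
        records = call_enhancers(
            rows,
            input_stats,
            output_stats,
            compensation_multiplier=m,
            alpha=alpha,
            omega_mode=omega_mode,
            log_base=log_base,
            k_mode=k_mode,
        )
        called = [r.locus.to_interval() for r in records if r.called]
        if not called:
            warnings.warn(f"no calls at multiplier {m}; non_overlap_rate set to 0")
            rate = 0.0
        else:
            flags, _ = overlap_any(called, list(annotated_regions))
            rate = 1.0 - sum(flags) / len(flags)
        out.append(SweepRow(multiplier=float(m), n_called=len(called), non_overlap_rate=rate))
    return out
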