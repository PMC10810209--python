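# Methods

## The screen and its statistical model

A 25-bp reporter screen compares two sequencing libraries built from
the same transfected cell pool: the *input* (all cells, no sorting),
which measures each fragment's abundance in the pool, and the *output*
(fluorescence-sorted cells), in which fragments with enhancer activity
are over-represented. Because a 25-bp fragment maps to an essentially
unique genomic location, identical reads cannot be distinguished from
PCR duplicates, so duplicates are retained and amplification is handled
by the model instead of by deduplication.

Per-library normalization is

    f(x) = x · ω / (N · c · log(1 + p))

with `N` the library's total retained reads, `p` the per-cycle PCR
efficiency (default 1), `c` the number of PCR cycles, and `ω` a zoom
factor shared by the library pair. Per locus, the caller takes
`λ = f_in(x)` as the Poisson rate and `k = round(f_out(y))` as the
observation and computes the one-sided upper tail `P(K ≥ k | λ)` via
the survival function. Loci with `y = 0` are not tested — the screen
only ever calls positives. Loci with `x = 0, y > 0` are tested against
the compensation value `κ = m·coef_in` (the normalized weight of `m`
input reads). Q-values are Benjamini–Hochberg-adjusted across all
tested loci; calls are made at `Q < α` with `α = 0.05`.

### Interpretation choices in the printed formulas

Several aspects of the formulas admit more than one reading; the
package fixes them as follows and exposes each as an option.

- **Zoom factor.** With `d = ⌊log10 MIN(N_in, N_out)⌋ + 1` (the decimal
  digit count of the smaller total), the default `omega_mode="power"`
  uses `ω = 10^d`: the next power of ten above MIN, which is the only
  reading that rescales normalized frequencies (of order x/N) back to
  a count scale where a Poisson test has power. The literal reading
  `ω = 10·d` is retained as `omega_mode="literal"`. The digit count is
  computed from the integer's decimal representation, avoiding float
  log10 edge cases at exact powers of ten.
- **Denominator log.** `log (1+p)^c` is read as `c·log(1+p)` — the log
  of the total amplification factor — since `(log(1+p))^c` would be
  vanishingly small at typical `c = 15`. Natural log is the default;
  base 10 is selectable (`log_base="base10"`).
- **Observation k.** The Poisson test needs an integer observation but
  normalized outputs are real. Default `k_mode="rounded"` rounds half
  away from zero; `k_mode="continuous"` uses the regularized lower
  incomplete gamma `P(k, λ)`, the rounding-free interpolation of the
  integer survival function, as a sensitivity check. The two differ
  noticeably when `f_out` lands near a half-integer (for the toy
  example x=2, y=8 they give 8.6×10⁻⁴ and 1.4×10⁻³ respectively).
- **Test direction.** One-sided, upper tail: the screen calls loci
  *enriched* in the sorted library. Swapping the library labels
  changes the result (tested); ω is invariant under the swap.
- **Compensation.** The multiplier `m` scales `coef_in`, i.e. the
  normalized value of a single input read; `m` is calibrated over the
  grid 0.1–3.0 (step 0.1) against the surviving call count and the
  fraction of calls not overlapping annotated regions. `m = 1` is the
  default operating point.

### Numerical details

- Upper tails come from `scipy.stats.poisson.sf` (survival function),
  never `1 − cdf`, so far-tail p-values keep full relative accuracy;
  tests verify agreement with independent pmf summation to 10⁻¹⁰ over
  λ ≤ 50, k ≤ 200.
- BH adjustment delegates to `statsmodels` (`fdr_bh`) and is checked
  against a literal step-up implementation.
- Rows absent from the output are excluded from the BH family (they
  carry no p-value at all), so the multiplicity burden counts only
  tested loci.
- Coordinates are BED-style 0-based half-open throughout; SAM input is
  converted at parse time. Overlap predicates require ≥ 1 shared base;
  touching half-open intervals never overlap.

## Read preparation and counting

Inserts are located by fixed-length Hamming anchors: the 20-bp suffix
of the left construct arm and 20-bp prefix of the right arm, each
tolerating 1 mismatch by default, with no indels. The between-sequence
is kept only at exactly the designed insert length (25 bp). A
consequence of the construct's mosaic-end symmetry (the right arm's
prefix is the reverse complement of the left anchor region) is that
reverse-strand reads still extract — yielding the reverse-complement
insert, which maps to the same locus once strand is collapsed.

Counting keeps primary alignments with no alternate-hit tag, mapping
quality ≥ 1, reference span exactly equal to the insert length, and
edit distance ≤ 2 (a missing NM tag fails the record unless
`assume_nm0` is set). Loci are keyed by (chrom, start, end) with strand
collapsed, since enhancer activity is orientation-independent.

## Mappability simulation

Fragment-length mappability is measured by exact occurrence counting:
a fragment is uniquely mapping when its sequence (or its reverse
complement; palindromes deduplicated by position) occurs exactly once
in the genome. This is deterministic and verifiable against a
sliding-window scan, unlike wrapping an external aligner; a census
mode enumerates every genomic window exactly. The same index drives
`ExactAligner`, which emits SAM-style records (unique hit → mapq 60;
multiple hits → alternate-hit tag, mapq 0; no hit → unmapped) so the
counting filters are exercised by real pipeline plumbing. The
full-scale design for the length sweep is 20–60 bp at 1-bp steps,
three repetitions of 10⁶ fragments; the package default is 10⁴
fragments per repetition, which resolves rates to about ±0.5%.

## The synthetic-screen generator

`simdata` emulates the screen's data-generating process:

1. **Genome** — i.i.d. uniform bases over `n_chroms` chromosomes;
   optionally the tail `repeat_fraction` of each chromosome is
   overwritten with tandem copies of one shared 200-bp unit, making
   that fraction of positions non-uniquely mappable (census rate
   ≈ 1 − repeat_fraction).
2. **Library** — `library_complexity` distinct 25-bp fragment
   positions sampled uniformly; `n_enhancers` of them are designated
   enhancers with multiplicative sorting weight `enrichment_fold`.
3. **PCR** — each fragment starts as one molecule; every molecule
   duplicates independently with probability `p` per cycle
   (Galton–Watson branching), so mean amplification after `c` cycles
   is `(1+p)^c` — exactly the factor the normalization divides out.
   `p = 1` is the deterministic-doubling limit (`2^c` exactly).
4. **Sequencing** — multinomial draws of `depth_input` and
   `depth_output` reads over the post-PCR molecule counts, the output
   weighted additionally by each fragment's enrichment fold. Reads are
   emitted as left-arm + fragment + right-arm FASTQ with constant
   quality, so the full prep → align → count → call path runs on them.

Reference conditions (the `SimConfig` defaults, used by the test suite
and the acceptance script): 5000 fragments on a 200-kb two-chromosome
genome, 50 enhancers at fold 20, 5 × 10⁵ reads per library, `p = 1`,
15 PCR cycles in both libraries. These sizes run in about a second per
screen while leaving ≈ 100 raw reads per fragment, deep enough that
fold-20 enrichment is unambiguous.

**Matched PCR cycles.** Both libraries default to `c = 15`. Under the
branching model amplification preserves expected fragment frequencies,
while the normalization divides by `c·log(1+p)`; if the two libraries
are amplified for different cycle counts the normalized output scale
is multiplied by `c_in/c_out` relative to the input, which biases the
test (a 15-vs-10 mismatch inflates every normalized output count by
1.5× and floods the null with false calls). This is a property of the
normalization model itself, asserted by a unit test, and the reason
real screens analysed with this model should match amplification
between libraries or fold the scale difference into the compensation
calibration. The generator therefore uses matched cycles as its
reference condition.

**What the generator does not emulate.** No sequencing errors by
default (errors would mostly fail the exact 25-bp match filters and
are orthogonal to the statistics under test); no cell-sorting gate
model (enrichment is a single multiplicative weight); no
transfection copy-number variation; no fragment-composition bias. A
passing recovery test therefore shows the caller is correct *under the
model's own assumptions* — it does not certify performance on real
libraries, where overdispersion beyond Poisson (e.g. from stochastic
PCR with `p < 1`, which the generator can produce but the model does
not account for) will inflate the false-positive rate.

## Evaluation conventions

A call is a true positive only when its interval equals a planted
enhancer fragment exactly. With zero calls, precision is reported as 1
with a `zero_calls` flag (nothing was wrongly called), and recall 0.
The sweep's `non_overlap_rate` over an empty call set is reported as 0
with a warning.

## Known limitations

- The test treats `λ` as known; sampling noise in the input count is
  not propagated, so the test is anti-conservative when per-locus
  input coverage is low and the normalized scale is near raw counts.
  The default power-mode ω keeps the normalized scale well below raw
  counts at realistic library sizes, which makes the test conservative
  in practice.
- No replicate-aware or overdispersed (negative binomial) variant.
- The exact aligner tolerates zero mismatches; mismatch-tolerant
  alignment should be delegated to an external short-read aligner
  emitting SAM, which the counting module consumes directly.
- BED/SAM chromosome naming is compared exactly; use the renaming
  utility rather than relying on implicit "chr" aliasing.
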