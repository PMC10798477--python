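# Methods

This note documents the models, measures and numerical choices behind
`humanrand`: what is computed, under which assumptions, and where the
open design decisions were resolved.

## Algorithmic complexity of short binary strings

The package quantifies the randomness of a binary string by an estimate
of its algorithmic (Kolmogorov–Chaitin) complexity.  For short strings
this is operationalized through the Coding Theorem Method (CTM): over a
large space of small Turing machines, the frequency with which a string
appears as a halting output approximates its algorithmic probability,
and `ctm(s) = -log2(frequency)` its complexity in bits.  Frequent,
compressible outputs (constant strings, strict alternations) score low;
outputs that only idiosyncratic machines produce score high.

### The packaged table

`humanrand.ctm` ships `ctm_b2_d12_synthetic.tsv`, a complexity table for
all 8190 binary strings of lengths 1–12, **computed from scratch for
this package** (the `_synthetic` suffix marks it as a stand-in for the
published 5-state Coding-Theorem table, which is not redistributable
here).  Construction, reproducible via `scripts/build_ctm_table.py`:

1. **Machine formalism.** Busy-beaver-style binary Turing machines: the
   blank symbol doubles as `0`, every transition writes and moves, a
   distinguished halt state terminates the run, and the output is the
   tape segment spanned by every cell the head visited.  Runs start on a
   blank tape.
2. **Frequency estimation.** A seeded Monte-Carlo run over the 5-state
   space (2.5 × 10⁹ uniform machines, step bound 500, fixed seed,
   counts symmetrized over bit complement and reversal — both exact
   symmetries of the space).  This yields direct, unbiased frequency
   estimates with complete coverage of all strings up to length 9; at
   length 6 the rarest string is seen ~10⁵ times, so sampling noise is
   negligible where the package's worked examples live.  The enumeration
   machinery is validated in-repo by an exhaustive run of the 2-state
   space, where a symmetry-reduced accounting must reproduce the
   brute-force full-space counts bit for bit (`tests/test_ctm_table.py`).
   An exhaustive 4-state enumeration (5.1 × 10⁹ effective machines) was
   used as a second methodological check during development; its rank
   ordering agrees with the sampled 5-state values.
3. **Extension to length 12.** Lengths beyond complete coverage are
   scored by the mean table value of their 9-element windows plus a
   per-length offset matching the table's mean growth per symbol (the
   affine part cancels under min–max normalization, so only the
   window-inherited ordering matters).  The rule is applied uniformly
   per length, preserves complement/reversal symmetry, and keeps
   constant strings the strict minima of their class.  A minimal-split
   concatenation bound (`min over s = a+b of ctm(a) + ctm(b)`) was
   evaluated first and rejected: subadditivity is loose exactly for
   incompressible strings, which compresses the upper range of the
   length-11 scale so badly that a strict alternation could outrank
   Bernoulli output — the window-mean rule keeps the chunk measure
   monotone in alternation bias (fair coin ≈ 0.69, 85% alternation
   ≈ 0.47, strict alternation ≈ 0.23, constant 0, as the test suite's
   generators reproduce).

The TSV stores one canonical representative per symmetry class (the
loader expands it), with a SHA-256 manifest checked at load time.
Because the table is a fresh computation rather than the published
5-state table, absolute normalized values can differ from printed
literature values in the third decimal; orderings and all qualitative
behaviour agree (the README's reproduction section shows the computed
worked-example values).

### Derived measures

* **Normalization.** `(raw - min) / (max - min)` within a length class,
  where `min` is the constant string's value and `max` the class
  maximum; a constant string maps to exactly 0, the most complex string
  of that length to 1.  Lengths 1–2 are degenerate (the class collapses
  under complement symmetry) and are rejected.
* **BDM.** Strings longer than 12 elements are decomposed into
  consecutive non-overlapping 12-blocks (trailing remainder discarded,
  matching the reference implementation's boundary default); the
  estimate sums block complexities plus `log2` of block multiplicities.
  The normalization maximum for multi-block strings uses the sum of the
  largest distinct block values — repeating a block can never beat a
  distinct complex block, because a full block complexity (> 10 bits)
  always exceeds a log-multiplicity increment (< 1 bit).
* **Overall complexity** of a series: the mean normalized complexity of
  its length-11 chunks.  Chunks are step-1 *sliding* windows by default
  — consistent with the rolling measure and lossless on 103–120-element
  series; a disjoint-partition mode is available
  (`overall_complexity(..., mode="disjoint")`).
* **Rolling complexity**: normalized complexity in a step-1 moving
  window of `w ∈ {5..9}` elements (the nominal working-memory span
  7 ± 2); analyses default to `w = 7`, the length of the comparison-task
  stimuli.  Profile positions index the window **end** element,
  0-based.

## The generation model

One simulated participant is a loop over prompted elements:

1. **Schema proposal.** With the buffer non-empty, propose an
   alternation of the previous symbol with probability `theta`
   (default 0.65, the centre of the alternation-bias band reported for
   human randomness judgments), else a repetition.  An empty buffer
   proposes uniformly.
2. **Complexity judgment.** With probability `p_t` the judgment is
   veridical: the candidate is accepted iff the working-memory window
   ending in it is at least as complex as the window ending in the
   opposite symbol (ties accept).  With probability `1 - p_t` the
   judgment degrades to a fair coin flip.  A rejected candidate is
   replaced by the opposite symbol unconditionally — with a binary
   alphabet there is no third option, which also guarantees
   termination.
3. **Fatigue.** `p_t = floor + (p0 - floor) · exp(-lambda_eff · t)` with
   `lambda_eff = lambda · (1 + kappa)` in the *invisible* condition and
   `lambda` in the *visible* one: displaying the last 7 produced
   elements relieves the storage component, and the freed attentional
   resource slows the decay of judgment accuracy.  Visibility does not
   change the buffer content itself — in the visible condition the
   displayed elements simply stand in for the memory trace.
4. **Memory update.** The emitted symbol joins the buffer; the oldest
   symbol drops once the buffer exceeds `k` (default 7, range 5–9).
   Early in the series the judgment runs on however many symbols exist.

Omitted stimuli (probability `omission_prob`) advance time and fatigue
without emitting a symbol, reproducing the 103–120-element range of
real series.

Defaults (`ModelParams`): `k = 7`, `p0 = 0.9`, `lambda = 0.01` per
element, `floor = 0`, `kappa = 1`, `theta = 0.65`, 120 elements.  The
floor of zero means fully degraded judgment is a coin flip on the
acceptance decision — the schema bias still operates, which is what
keeps fatigued output *less* random rather than *more*.

A caution established during development: with `p0 = 1` and no fatigue
the accept/reject rule becomes a deterministic argmax on the table and
the process locks onto table-specific periodic orbits.  Capacity
comparisons are meaningful under imperfect judgment (`p0 < 1`), where
proposal noise continually perturbs the trajectory; the tests probe the
capacity–complexity association under the cohort's heterogeneous
parameters, not in the deterministic corner.

## Behavioural instruments

* **Comparison task.** All 64 pairs of 7-element series differing only
  in the last element (one pair per length-6 prefix; the 128 length-7
  strings each appear exactly once).  Side assignment and trial order
  are seeded-random, as on screen.  The correct member is the one with
  the strictly higher table complexity; pairs whose members tie are
  flagged and excluded from the correctness denominator.  Timeouts
  (`None` responses) score as incorrect and stay in the denominator by
  default; both conventions are switchable.  Simulated responders pick
  the correct member with probability
  `expit(alpha + gamma · |complexity gap|)`.
* **Complex span.** Adaptive letter-recall: strings start at 2 letters,
  grow by one per fully correct recall, and the run ends at two
  consecutive failures (or a cap of 25 trials, flagged).  Each letter is
  recalled in position with probability `expit(a · (c - m))` for string
  length `m`.  `partial_span_score` defaults to letter-level partial
  credit (sum of letters-in-position over all trials, the more
  discriminating convention in the span literature); the **pipeline
  scores spans at trial level** (count of fully correct recalls),
  because the published exclusion window (scores below 4 or above 10)
  is only coherent on that scale — letter-level totals of an adaptive
  run reaching length 7 already exceed 25.

## Exclusion rules

Applied in the published order with the published absolute cut-offs,
boundaries inclusive ("less than 103" removes 102, keeps 103):
series shorter than 103 elements, then completion time outside
[7.5, 15] minutes (study 1); distractor accuracy below 85%, then span
score outside [4, 10] (study 2).  A percentile mode re-derives the 10%
cuts from the cohort at hand for non-default cohorts.  Reports
partition the input exactly and filters are idempotent.

## Statistics

* **Rank-sum test** (order effects): Mann–Whitney U with midranks.
  Exact permutation enumeration of U up to a combined n of 16;
  otherwise the tie-corrected normal approximation with continuity
  correction (matching the reference asymptotic implementation to
  1e-8).  W is reported in the U convention of R's `wilcox.test`.
* **Inverse-variance WLS**: closed-form weighted normal equations;
  slope CI from t with n − 2 df; weighted R² around the weighted mean;
  per-participant weights are reciprocal variances of the rolling
  profile, capped at 10× the 99th percentile of finite weights so a
  constant-output participant cannot dominate.
* **Trend model.** Rolling profiles are modelled as
  `y_it = b0 + b1·visible_i + f(t) + f_diff(t)·visible_i + u_i + v_i·t + e_it`
  with invisible as the reference condition.  `f` and `f_diff` are
  cubic B-spline smooths (basis dimension K = 10 by default) penalized
  by the exact integrated squared second derivative — its null space
  contains linear trends exactly, so a straight line is penalty-free.
  `f_diff` additionally carries a small identity shrinkage (1e-2
  relative) because its constant/linear components are only weakly
  separated from the condition offset and the visible subjects' random
  slopes.  Subject intercepts and slopes are ridge-penalized random
  effects.  The four smoothing parameters minimize GCV
  (`n·RSS/(n - edf)²`), seeded on a log grid and refined by
  Nelder-Mead, with log10 bounds [-8, 6] for smooths and [-4, 6] for
  the random-effect ridges (the lower ridge bound keeps subject
  intercepts separated from the global intercept; the ceiling protects
  the conditioning of the normal equations).  Effective df per term is
  the trace of the corresponding block of `(XᵀX + S)⁻¹XᵀX`.
  Marginal/conditional R² follow the mixed-model variance-partition
  convention: fixed-part variance (conditional: plus random-part) over
  fixed + random + residual variance.
* **Permutation inference.** Condition labels are permuted at the
  subject level (the design is between-subject, so exchangeability
  under the null is exact), with smoothing parameters frozen at their
  observed values.  The statistic is the squared norm of the fitted
  condition-difference curve `g(t) = b1 + f_diff(t)` on a uniform grid,
  decomposed into a level term (squared mean of `g`) and a shape term
  (variance of `f_diff`); `p = (1 + #{perm ≥ obs}) / (B + 1)`, B = 199
  by default.  A residual-reduction statistic was considered and
  rejected: with subject random intercepts and slopes in the model, the
  reduced (no-condition) fit absorbs any between-subject contrast into
  the random effects, so removing the condition terms barely changes
  the residual — whereas the fitted difference curve cannot hide there
  and shrinks toward zero under permuted labels.  This replaces
  approximate F tests on smooth terms, whose printed reference values
  are data- and implementation-specific; the operating characteristics
  (type-I error in the nominal band, high power at a strong designed
  effect) are themselves under test in `tests/test_acceptance.py`.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` produce full study datasets with ground
truth.  One latent ability `z_i ~ N(0,1)` per participant loads (with
correlation `rho = 0.7` by default) on working-memory capacity `k`
(quantile-mapped onto {5..9}), comparison discrimination `alpha`, and
span capacity `c`; `p0 ~ Beta(8,2)`, `lambda ~ Gamma(2, 0.005)`,
`theta ~ Beta(6.5, 3.5)` are independent individual traits.  Condition
assignment alternates with participant number (odd numbers visible),
mirroring the id-parity allocation of the original design; study-2
cohorts run everything in the visible configuration.  Completion times
and a short-series-prone subgroup are drawn so the exclusion filters
remove roughly their configured shares (5% and 10%); distractor
accuracies sit mostly above the 85% bar; span-capacity defaults are
calibrated so about a tenth of scores fall below 4 and a tenth above
10, the published trimming window.  Everything is deterministic under
the master seed (child seeds from a `SeedSequence`).

What the generator does **not** emulate: reaction times, sequential
dependencies beyond the model's own memory window (e.g. 1/f structure),
learning or strategy shifts within the task, and any demographic
structure.  Passing tests therefore validate the pipeline's logic and
the model's qualitative predictions, not distributional realism of
human cohorts.

## Parameter recovery

`recover_parameters` scores each observed transition analytically:
given the preceding window, the probability of the emitted symbol is
`(1 - p_t)/2 + p_t · Q_t` with
`Q_t = prop_c·v_c + (1 - prop_c)(1 - v_o)`, where `prop_c` is the
schema probability of the observed symbol and `v_c`, `v_o` indicate
whether the veridical judgment accepts each candidate.  The summed log
pseudo-likelihood is maximized on a grid over `k ∈ {3..11}` and
`lambda ∈ {0, 0.001, ..., 0.1}`, profiling out `theta` (7-point grid)
and `p0` (3-point grid); omissions are ignored (the fatigue clock and
the response index are treated as aligned, an approximation that costs
little at the 3% default omission rate).  Groups are scored separately
per condition, so the recovered `lambda` is the *effective* decay and a
positive storage-load coupling appears as
`lambda_invisible > lambda_visible`.  Confidence intervals are
percentile bootstrap over participants.  Identifiability is
directional, not exact: the tests require the modal recovered `k` to
fall within one unit of truth and the fatigue ordering to be preserved
across replicate cohorts, not pointwise equality.

## Problem sizes in the test suite

The suites run the study conditions at sizes chosen to exercise every
claim with Monte-Carlo margins: condition-dynamics checks use 100-200
agents per condition at full 120-element length; permutation power uses
20 replicate cohorts of 100 subjects per arm (B = 199); type-I
calibration uses
200 replicate null cohorts of 16 subjects with 50-element series —
the operating characteristics of the test are length-invariant, and the
shorter series keep the null ensemble cheap; parameter recovery uses 20
replicate 100-participant cohorts.  All seeds are fixed in the tests.

## Known limitations

* The packaged complexity table is a fresh Coding-Theorem computation,
  not the published 5-state table; normalized values agree closely but
  not to print precision (the README's reproduction section shows the
  computed worked-example values).
* Lengths 10–12 carry window-mean values inherited from the length-9
  frequencies rather than direct estimates, so the chunk-11 measure is
  effectively a smoothed window-9 measure; its ordering is sound but
  its fine-grained scale is not an independent measurement.
* The trend model deliberately omits residual autocorrelation; the
  subject-level permutation keeps inference on condition terms valid
  regardless, but within-subject CIs on the fitted curves would be
  optimistic.
* The judgment operationalization is the minimal two-candidate rule
  consistent with the model sketch; richer prototype comparisons (runs,
  symmetries) would change the fine structure of generated series.
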