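# humanrand

Quantifying the randomness of human-generated binary sequences, and
modelling the working-memory process that produces them.

When people are asked to "imagine a fair coin and report the outcomes",
their series are reliably non-random: they alternate too much, avoid
long runs, and their performance degrades over the task.  `humanrand`
is a Python library for studying this behaviour end to end:

* **Algorithmic complexity of short strings.**  A packaged
  Coding-Theorem table gives complexity values `ctm(s) = -log2 D(s)`
  (bits) for every binary string up to length 12, where `D(s)` is the
  string's output frequency over a space of small Turing machines.
  Min–max normalization within a length class maps a constant string to
  0 and the most complex string of that length to 1.  Series-level
  measures: the *overall* score (mean normalized complexity of sliding
  length-11 chunks) and the *rolling* profile (a moving window of
  5–9 elements, the putative working-memory span; 7 by default).
* **A generation model.**  An agent keeps the last `k` symbols in a
  working-memory buffer, proposes the next element from an
  alternation-biased schema (`P(alternate) = theta ≈ 0.65`), accepts it
  iff the buffer window ending in it is at least as complex as the
  alternative continuation, and executes that judgment correctly with a
  probability that decays exponentially with time on task — faster when
  the produced elements are not displayed, because holding them in
  memory competes with the judgment for the same attentional resource.
* **Behavioural instruments.**  The 64-pair comparison task (all
  7-element series differing in the last element; correctness index =
  share of pairs answered with the more complex member) and the
  adaptive complex-span test (partial span scoring).
* **The statistical layer.**  Published participant-exclusion rules;
  Mann–Whitney rank-sum tests (exact or tie-corrected asymptotic);
  inverse-variance weighted least squares with CIs and weighted R²; and
  a penalized-spline mixed trend model
  `y_it = b0 + b1·visible + f(t) + f_diff(t)·visible + u_i + v_i t + e`
  with GCV-chosen smoothing and subject-level permutation tests of the
  condition terms, plus marginal/conditional R².
* **Synthetic cohorts with ground truth**, so every stage is testable
  without any data download, and grid-search pseudo-likelihood
  **parameter recovery** of capacity `k` and fatigue rate `lambda` from
  series alone.

See `docs/methods.md` for the models, assumptions and numerical
choices, and `examples/` for one runnable script per capability.

## A worked example

```python
from humanrand import load_ctm_table
from humanrand.complexity import normalized_ctm

table = load_ctm_table()
print(round(normalized_ctm("010101", table), 3))   # 0.526
print(round(normalized_ctm("101001", table), 3))   # 0.662
```

Both 6-element strings have three 0s and three 1s, but the strict
alternation compresses better, so its normalized complexity is lower —
the irregular string needs more of its own description.  This single
comparison is the germ of the whole package: the comparison task asks
people to make exactly this call, and the generation model assumes they
make it (fallibly) before every keypress.

A full synthetic study:

```bash
humanrand run-pipeline --outdir study1 --seed 1
```

simulates a 150-participant cohort, applies the exclusion rules, writes
rolling profiles, fits the trend model and the weighted regression of
overall complexity on the correctness index, and records a manifest of
seeds and output checksums (reruns are bit-identical).

## The packaged complexity table

`ctm_b2_d12_synthetic.tsv` is computed from scratch for this package: a
seeded Monte-Carlo Coding-Theorem run over 5-state binary Turing
machines (2.5 × 10⁹ machines; direct frequencies for all strings up to
length 9) extended to length 12 by window-mean scoring at length 9.
The `_synthetic` suffix marks it as a stand-in for the published
5-state table, which cannot be redistributed here; values agree with
published ones in ordering (rank correlation > 0.99) and to within a
few hundredths after normalization — e.g. the printed literature values
for the two strings above are .542 and .647.  `scripts/build_ctm_table.py`
reproduces the table; the enumeration machinery is itself under test
against an exhaustive 2-state run.

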