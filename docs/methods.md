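# Methods

## Model and scope

`blocksurv` fits right-censored survival forests on covariate data whose
columns are partitioned into M named blocks. A data set is a numeric matrix
`X (n × p)`, an outcome `(time > 0, status ∈ {0,1})` and a block structure
whose index lists are disjoint and cover all p columns; one block may be
designated *clinical*. Only numeric covariates are accepted — nominal
clinical variables must be dummy-encoded by the user — and missing values
are a load-time error (imputation is out of scope). Fitting requires at
least one observed event.

All six fitting procedures (`rsf` plus the five block-aware variants) share
the same tree machinery and differ only in candidate generation and
criterion weighting, as summarized in the README table.

## Trees and splitting

**Criterion.** A candidate split is scored by the two-sample log-rank
statistic between the child nodes. Over the distinct pooled event times with
`d_k` events, `n_k` at risk and `n_kL` at risk in the left child:
`O = Σ d_kL`, `E = Σ d_k n_kL / n_k`,
`V = Σ d_k (n_kL/n_k)(1 − n_kL/n_k)(n_k − d_k)/max(n_k − 1, 1)`, and the
score is the squared standardized form `(O − E)²/V`. The squared form is
nonnegative, so multiplicative block weights `w_m ∈ (0, 1]` act
monotonically: down-weighting a block can only demote its proposals.
`V = 0` (no events, or every event at a time where one child holds the whole
risk set) marks the proposal *inadmissible* and it is skipped.

**Split points.** One threshold per candidate variable, drawn uniformly from
the open interval (min, max) of the node's values; `x ≤ threshold` goes
left, so both children are always nonempty. Constant variables yield no
proposal. Among admissible proposals the largest weighted criterion wins;
exact ties keep the first-encountered proposal in the candidate order fixed
by the seeded generator, which makes selection deterministic given a seed.

**Stopping and terminal nodes.** A node becomes terminal when its size is at
most `min_node_size` (default 3), it contains no events, or no admissible
split exists. There is no depth limit. Each terminal node stores the
Nelson–Aalen cumulative hazard `Σ_{t_k ≤ t} d_k/n_k` of its in-bag
observations, evaluated on the pooled training event-time grid so that tree
averages are step functions on a common grid. (The size rule uses "≤", the
convention of the classical fast forest implementations: a node of exactly
`min_node_size` observations is terminal.)

**Variant dispatch per node.**

- `rsf`: `mtry` variables uniform over all p.
- `varprob`: sequential categorical draws with per-variable probability
  `v_m`, rejecting duplicates, until `mtry = Σ⌈√p_m⌉` distinct variables are
  collected. The rejection loop is bounded: after `50·p` consecutive
  duplicates the remaining slots are filled by weighted sampling without
  replacement, which prevents non-termination under extreme `v`.
- `splitweights`: uniform sampling of `Σ⌈√p_m⌉` variables; weights `w_m`.
- `blockvarsel`: `⌈√p_m⌉` variables from every block; weights `w_m`.
- `randomblock`: one block by `b_m`, then `⌈√p_m⌉` variables from it,
  unweighted (no cross-block comparisons occur).
- `blockforest`: each block kept independently with probability ½, the
  all-empty outcome (probability `0.5^M`) redrawn; per-block sampling over
  the kept blocks; weights `w_m`.

`√p_m` is rounded up with a floor of one so every block can always
contribute a candidate. With the optional *mandatory clinical* variation,
the full clinical block is unioned into the candidate set at **every** split
(including `randomblock` splits of non-clinical blocks); clinical variables
keep their block label, so clinical weights still apply where the variant
defines weights.

## Forests, prediction, out-of-bag error

Trees are grown on independent bootstrap samples of size n drawn with
replacement (the OOB machinery presumes bootstrap resampling). Per-tree RNG
streams derive deterministically from `(seed, tree index)` via a seed
sequence, so a forest is reproducible regardless of execution order; tree
growth is serial. A bootstrap sample without events aborts the fit — under
extreme censoring this surfaces as missing cross-validation iterations
rather than silently degenerate trees.

Prediction routes an observation to one terminal cumulative-hazard function
per tree, averages the CHFs, and returns the average summed over the
event-time grid (*ensemble mortality*). Any strictly monotone transform
yields the same concordance, so the contract is a risk ordering and
mortality is the canonical choice. The out-of-bag error aggregates, per
observation, only trees in whose bootstrap sample it does not appear, and
returns `1 − C`; observations that are never out of bag are excluded, and a
non-computable C (no comparable pairs) is reported as *invalid* rather than
coerced to a number.

Forests serialize to a versioned JSON document with base64-encoded arrays.
The writer is byte-deterministic: identical data and seed produce identical
files.

## Tuning

`tune_variant` draws `N_sets` (default 300) random parameter sets, fits a
`num_trees_pre`-tree forest (default 1500) per set and keeps the set with
the smallest OOB error; ties keep the earliest set and invalid errors are
excluded (if all sets are invalid, tuning fails with advice to use more
trees). The generators have full support on each constraint surface:
`v_m = u_m / Σ p_k u_k` with `u ~ U(0,1)` (so `Σ p_m v_m = 1` exactly),
`w_m = a_m / max a_k` with `a ~ U(0,1)` (so `max w_m = 1`), and `b` uniform
on the simplex via normalized standard exponentials (so `Σ b_m = 1`). Any
full-support generator preserves the random search's consistency, since the
selected set's error is a running minimum. Each iteration derives its own
generation and fitting seeds from the tuning seed, so tuning is reproducible
and the candidate forests use independent bootstrap draws. The RSF baseline
grid-searches `mtry` over `{⌈x√p⌉}`, `x ∈ {0.1, 0.25, 0.5, 1, 2}`,
deduplicated and capped at p, with ties toward the smaller `mtry`.

## Evaluation

**Harrell's C** uses the standard tie conventions: pairs with distinct times
are comparable iff the shorter time is an event; equal times with both
events are comparable and credit ½ regardless of risks; equal times with
exactly one event treat the event as earlier; tied risks credit ½. Zero
comparable pairs → *not computable*.

**Screening** ranks columns by the univariate Cox partial-likelihood score
test at β = 0 with Breslow tie handling — `U = Σ_events (x_i − mean over the
risk set)`, `V = Σ_events (risk-set variance)`, statistic `U²/V ~ χ²₁`. The
score test needs no iterative fitting, and its ranking agrees asymptotically
with Wald/likelihood-ratio rankings from fitted Cox models (verified against
fitted models in the tests). Constant columns get statistic 0 (p = 1) and
rank last; p-value ties break toward the smaller column index. Blocks at or
under the cap (default 2500) pass through unchanged.

**Repeated CV** draws a fresh k-fold partition per repetition (k = 5, 5
repetitions by default), with fold sizes differing by at most one and no
stratification by event status. Screening and tuning run on the training
folds only; the final forest uses the configured tree count; the C index is
computed on the left-out fold. Iterations that fail (no events in a training
bootstrap, non-computable C on the test fold) are recorded as missing and
excluded from averages — with heavily censored data whole iterations can go
missing, which is the expected behavior, not an error.

## Synthetic data

The generator emulates multi-omics cohorts: q shared latent factors
`Z ~ N(0, I)`; each block's informative variables are `loading · Z_f` plus
unit noise, with factor indices assigned round-robin, so informative
variables of different blocks correlate (unit loadings give cross-block
correlation 0.5) — the information-overlap feature that motivates
randomizing block choice. The linear predictor sums each block's informative
factor components scaled by the block effect `β_m`; event times are
exponential with rate `λ₀ exp(η)` (baseline `λ₀ = 0.1`). Censoring times are
exponential and independent of the covariates, with the rate calibrated by
bisection on `E[c/(c + λ_i)]` (100 steps, tolerance 0.02 on the expected
censoring fraction). The five-block fixture uses the canonical block roster
and size ordering (clinical < miRNA < mutation < RNA < CNV) at two scales,
tiny (n = 60, p = 200) and small (n = 300, p ≈ 3000).

What the generator does **not** emulate: real marginal distributions of
omics measurements (counts, CNV segmentation), covariate-dependent
censoring, nominal clinical variables, or batch effects. Tests passing on
this generator therefore demonstrate the algorithmic contracts and the
relative behavior of the variants under block-structured signal, not
absolute performance on real cohorts.

## Problem sizes in the test and acceptance runs

The statistical checks run at deliberately scaled-down study sizes, chosen
once as representative of the regimes of interest: null calibration at
n = 150, p = 200 in 3 blocks with 20 replicate 100-tree fits;
informative-block recovery at n = 200 with a 50-variable signal block
(10 informative, β = 0.5) against 500 noise variables, tuning 30 sets of
100-tree forests over 10 seeds; and the variant-vs-baseline comparison at
n = 200 with a 30-variable signal block against 1000 noise variables, using
5-fold CV with 15 tuning sets of 100 trees and 300-tree final forests over
5 seeds. Frequency laws use 10⁵ draws; constraint checks 10⁴ draws per
variant.

## Known limitations

- Survival outcomes only. The architecture keeps outcome handling in the
  criterion and terminal-node estimators, so categorical/continuous variants
  are not precluded, but none are implemented.
- No variable importance, proximity matrices, case weights or competing
  risks.
- Tree growth is serial; the per-tree seed derivation would make concurrent
  growth deterministic, but no parallel executor is wired in (`--threads` is
  accepted and currently documents this contract).
- With one tuning parameter per block, heavily censored small data sets can
  overfit the OOB criterion during tuning; the symptom is unstable selected
  parameters rather than silent failure.
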