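# blocksurv

Random survival forests for **block-structured covariate data** — data sets
whose covariates partition into blocks of different types, typically a small
clinical block plus several high-dimensional omics blocks (miRNA, mutation,
CNV, RNA) measured on the same patients. Standard random survival forests
(RSF) ignore this structure: a 5-variable clinical block is almost never
sampled next to 20 000 CNV columns, even when it carries most of the
prognostic signal, and a large noise block wins splits by sheer chance.

`blocksurv` implements a family of five forest variants that modify only the
split-point selection to respect the block structure, each governed by one
tuning parameter per block:

| variant | candidate generation | criterion weighting |
|---|---|---|
| `varprob` | sample all `mtry` candidates with per-block probabilities `v_m`, `Σ p_m v_m = 1` | — |
| `splitweights` | uniform sampling over all variables | weights `w_m ∈ (0,1]`, `max w_m = 1` |
| `blockvarsel` | `⌈√p_m⌉` variables from *every* block | weights `w_m` |
| `randomblock` | draw one block with probabilities `b_m`, `Σ b_m = 1`, then `⌈√p_m⌉` variables from it | — |
| `blockforest` | keep each block with probability ½ (redraw if empty), then `⌈√p_m⌉` variables per kept block | weights `w_m` |
| `rsf` | uniform sampling (block-agnostic baseline) | — |

Splits are scored by the two-sample log-rank statistic `(O−E)²/V` between the
child nodes, evaluated at **one uniformly drawn split point** per candidate
(the extremely-randomized-trees construction — exhaustively scanning split
points with log-rank tests is too expensive in high dimensions). Terminal
nodes store Nelson–Aalen cumulative hazards on the training event-time grid;
the ensemble risk score is the tree-averaged cumulative hazard summed over
the grid ("mortality").

The block parameters are optimized by **random search against the out-of-bag
error** `1 − C` (Harrell's concordance index): draw `N_sets = 300` random
parameter sets, fit a 1500-tree forest per set, keep the set with the
smallest OOB error, then fit the final 2000-tree forest. The RSF baseline
instead grid-searches `mtry ∈ {⌈x√p⌉ | x ∈ {0.1, 0.25, 0.5, 1, 2}}`. The
package also ships the surrounding evaluation machinery — Harrell's C with
the standard tie rules, repeated k-fold cross-validation with train-fold-only
univariate Cox-score screening (cap 2500 variables per block), and a
synthetic multi-omics data generator with shared latent factors and
calibrated censoring — so every component is testable without external data.

The optimized `randomblock` selection probabilities `b_m` double as block
importances: blocks that add little predictive information given the others
receive small `b_m`.

## Worked example

```python
import numpy as np
from blocksurv import (
    SimSpec, TuningConfig, fit_forest, oob_error, predict_mortality,
    simulate_blocked_survival, tune_variant,
)

spec = SimSpec(
    n=200, block_sizes=(5, 30, 500), n_informative=(2, 10, 0),
    beta=(0.5, 0.4, 0.0), censoring=0.3,
    block_names=("clinical", "rna", "cnv"), clinical_block="clinical", seed=1,
)
data = simulate_blocked_survival(spec)   # n=200, p=535, 145 events

params, trace = tune_variant(
    data, "blockforest", TuningConfig(n_sets=30, num_trees_pre=100, seed=1)
)
print("tuned block weights:", np.round(params.values, 3),
      "| tuning OOB error:", round(trace.best_error, 3))

forest = fit_forest(data, params, num_trees=500, seed=2)
print("final OOB C index:", round(1 - oob_error(forest, data), 3))
print("mortality of first 5 patients:",
      np.round(predict_mortality(forest, data.X[:5]), 2))
```

Output:

```
tuned block weights: [1.    0.432 0.072] | tuning OOB error: 0.219
final OOB C index: 0.779
mortality of first 5 patients: [120.99  34.85 104.03  45.56  78.96]
```

The tuned weights tell the story: the dense clinical block keeps full weight
1.0, the partially informative RNA block gets 0.43, and the 500-column noise
block is demoted to 0.07 — so its lucky splits rarely beat genuine ones. The
OOB C of 0.78 means 78% of comparable patient pairs are ranked correctly by
the predicted mortality (0.5 would be chance).

The same workflow is available from the shell:

```sh
blocksurv simulate --scale tiny --seed 3 --out data/
blocksurv fit --data data/matrix.csv --outcome data/outcome.csv \
    --blocks data/blocks.json --variant block_forest --seed 1 --out run/
blocksurv predict --model run/forest.json --data data/matrix.csv --out scores.csv
blocksurv cv --data data/matrix.csv --outcome data/outcome.csv \
    --blocks data/blocks.json --variant rsf --k 5 --reps 5 --out cv_rsf/
blocksurv summarize cv_rsf/cv_results.csv
```

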