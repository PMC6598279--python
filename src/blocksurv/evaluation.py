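"""Harrell's C index, univariate Cox-score screening and repeated CV.

The concordance index is the proportion of comparable observation pairs
whose predicted risk ordering agrees with the observed survival ordering.
Tie conventions (the standard Harrell rules):

* pairs with distinct times are comparable iff the shorter time is an
  event; concordant when that member has the higher risk; risk ties count
  one half;
* pairs with equal times and both events are comparable and count one half
  for any risk ordering;
* pairs with equal times and exactly one event treat the event as earlier.

When no pair is comparable (e.g. a fold with only censored observations)
the index is "not computable" and ``None`` is returned; cross-validation
records such iterations as missing and excludes them from averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BlockedDataset,
    BlocksurvError,
    SurvivalOutcome,
    VariantParams,
    as_generator,
    canonical_variant,
)
from .forest import fit_forest, predict_mortality

__all__ = [
    "harrell_c",
    "cox_score_screen",
    "cox_score_test",
    "MethodSpec",
    "CVResult",
    "repeated_cv",
    "make_folds",
    "summarize_cv_results",
]


def harrell_c(
    risk: Sequence[float], times: Sequence[float], status: Sequence[int]
) -> Optional[float]:
    """Harrell's concordance index in [0, 1], or ``None`` if no pair of
    observations is comparable."""
    r = np.asarray(risk, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    s = np.asarray(status)
    if not (r.size == t.size == s.size):
        raise BlocksurvError("risk, times and status must have equal lengths")
    if r.size < 2:
        raise BlocksurvError("at least two observations are required")
    ev = s == 1
    ti, tj = t[:, None], t[None, :]
    ri, rj = r[:, None], r[None, :]
    evi, evj = ev[:, None], ev[None, :]
    credit = (ri > rj) + 0.5 * (ri == rj)
    # distinct times: i strictly earlier and an event (each unordered pair
    # appears in exactly one orientation)
    m1 = (ti < tj) & evi
    # equal times, exactly one event: the event plays the earlier role
    m2 = (ti == tj) & evi & ~evj
    comparable = int(m1.sum() + m2.sum())
    concordant = float(credit[m1].sum() + credit[m2].sum())
    # equal times, both events: one half regardless of the risk ordering
    m3 = np.triu((ti == tj) & evi & evj, k=1)
    n3 = int(m3.sum())
    comparable += n3
    concordant += 0.5 * n3
    if comparable == 0:
        return None
    return concordant / comparable


# ---------------------------------------------------------------------------
# univariate Cox-score screening
# ---------------------------------------------------------------------------


def cox_score_test(X: np.ndarray, outcome: SurvivalOutcome) -> np.ndarray:
    """Per-column Cox partial-likelihood score statistic at beta = 0 with
    Breslow tie handling; returns the chi-square(1) statistic per column.

    ``U = sum_{events} (x_i - mean of x over the risk set at t_i)`` and
    ``V = sum_{events} (risk-set variance of x at t_i)``; the statistic is
    ``U^2 / V`` (0 for a constant column, which has V = 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != outcome.n:
        raise BlocksurvError("covariate rows must match the outcome length")
    n, p = X.shape
    order = np.argsort(outcome.time, kind="mergesort")
    t = outcome.time[order]
    s = outcome.status[order]
    Xs = X[order]
    # suffix sums over the risk set {j : t_j >= t}; each tie group's risk
    # set starts at the group's first index
    S1 = np.cumsum(Xs[::-1], axis=0)[::-1]
    S2 = np.cumsum((Xs * Xs)[::-1], axis=0)[::-1]
    is_start = np.concatenate([[True], t[1:] != t[:-1]])
    gstart = np.maximum.accumulate(np.where(is_start, np.arange(n), 0))
    ev = np.flatnonzero(s == 1)
    g = gstart[ev]
    nk = (n - g).astype(np.float64)[:, None]
    mean = S1[g] / nk
    var = S2[g] / nk - mean * mean
    U = (Xs[ev] - mean).sum(axis=0)
    V = np.maximum(var, 0.0).sum(axis=0)
    stat = np.zeros(p)
    ok = V > 1e-12
    stat[ok] = U[ok] * U[ok] / V[ok]
    return stat


def cox_score_screen(
    X_block: np.ndarray, outcome: SurvivalOutcome, cap: int = 2500
) -> np.ndarray:
    """Indices of the ``cap`` columns with the smallest univariate Cox score
    p-values (all columns when the block has at most ``cap``); p-value ties
    are broken toward the smaller column index.  The returned indices are
    sorted so the block's column order is preserved."""
    X_block = np.atleast_2d(np.asarray(X_block, dtype=np.float64))
    cap = int(cap)
    if cap < 1:
        raise BlocksurvError("cap must be >= 1")
    p = X_block.shape[1]
    if p <= cap:
        return np.arange(p, dtype=np.int64)
    stat = cox_score_test(X_block, outcome)
    pvals = stats.chi2.sf(stat, df=1)
    chosen = np.lexsort((np.arange(p), pvals))[:cap]
    return np.sort(chosen).astype(np.int64)


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethodSpec:
    """Bundle describing one method run inside cross-validation."""

    variant: str = "blockforest"
    n_sets: int = 300
    num_trees_pre: int = 1500
    num_trees_final: int = 2000
    screen_cap: Optional[int] = 2500
    mandatory_block: bool = False
    min_node_size: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", canonical_variant(self.variant))


@dataclass(frozen=True)
class CVResult:
    """Per-iteration C index values of a repeated k-fold cross-validation.

    ``table`` has one row per (repetition, fold) with the column
    ``c_index`` holding NaN for missing iterations (failed fits or
    non-computable C); missing iterations are excluded from the mean.
    """

    table: pd.DataFrame
    method: str = ""
    dataset: str = ""

    @property
    def mean_c(self) -> Optional[float]:
        vals = self.table["c_index"].to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            return None
        return float(np.nanmean(vals))

    @property
    def n_missing(self) -> int:
        return int(self.table["c_index"].isna().sum())

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out.insert(0, "method", self.method)
        out.insert(0, "data_set", self.dataset)
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CVResult":
        df = pd.read_csv(path)
        method = str(df["method"].iloc[0]) if "method" in df else ""
        dataset = str(df["data_set"].iloc[0]) if "data_set" in df else ""
        table = df[["repetition", "fold", "c_index"]].copy()
        return cls(table, method, dataset)


def make_folds(n: int, k: int, rng: np.random.Generator) -> list:
    """One random k-fold partition: every observation in exactly one fold,
    fold sizes differing by at most one."""
    if k < 2 or k > n:
        raise BlocksurvError("k must satisfy 2 <= k <= n")
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def _screen_columns(
    train: BlockedDataset, cap: Optional[int]
) -> Optional[np.ndarray]:
    """Global column indices surviving per-block screening, or ``None`` when
    no block exceeds the cap."""
    if cap is None or all(s <= cap for s in train.structure.sizes):
        return None
    kept = []
    for cols in train.structure.columns:
        if cols.size <= cap:
            kept.append(cols)
        else:
            local = cox_score_screen(train.X[:, cols], train.outcome, cap)
            kept.append(cols[local])
    return np.concatenate(kept)


def _fit_tuned(
    train: BlockedDataset, spec: MethodSpec, seed: int
):
    from .tuning import TuningConfig, tune_rsf_mtry, tune_variant

    tcfg = TuningConfig(
        n_sets=spec.n_sets, num_trees_pre=spec.num_trees_pre, seed=seed
    )
    if spec.variant == "rsf":
        mtry, _ = tune_rsf_mtry(train, tcfg, min_node_size=spec.min_node_size)
        params = VariantParams("rsf", [mtry])
    else:
        params, _ = tune_variant(
            train,
            spec.variant,
            tcfg,
            min_node_size=spec.min_node_size,
            mandatory_block=spec.mandatory_block,
        )
    return fit_forest(
        train,
        params,
        num_trees=spec.num_trees_final,
        min_node_size=spec.min_node_size,
        seed=seed + 1,
    )


def repeated_cv(
    data: BlockedDataset,
    spec: MethodSpec,
    k: int = 5,
    reps: int = 5,
    seed: int = 0,
    dataset_label: str = "",
) -> CVResult:
    """k-fold cross-validation repeated ``reps`` times.

    Each repetition draws a fresh random partition.  Per iteration,
    screening (blocks above the cap) and tuning run on the training folds
    only, the final forest is fitted with ``spec.num_trees_final`` trees,
    and the C index is computed on the left-out fold.  Failed iterations
    (fitting errors, non-computable C) are recorded as missing and the run
    continues.
    """
    rng = as_generator(seed)
    ss = np.random.SeedSequence(int(seed) if not isinstance(seed, np.random.Generator) else 0)
    iter_seeds = (ss.generate_state(reps * k) & 0x3FFFFFFF).astype(np.int64)
    rows = []
    it = 0
    for rep in range(reps):
        folds = make_folds(data.n, k, rng)
        for fold_i, test_rows in enumerate(folds):
            c: Optional[float] = None
            try:
                mask = np.ones(data.n, dtype=bool)
                mask[test_rows] = False
                train_rows = np.flatnonzero(mask)
                train = data.subset_rows(train_rows)
                cols = _screen_columns(train, spec.screen_cap)
                if cols is not None:
                    train = train.subset_columns(cols)
                    X_test = data.X[test_rows][:, cols]
                else:
                    X_test = data.X[test_rows]
                forest = _fit_tuned(train, spec, int(iter_seeds[it]))
                risk = predict_mortality(forest, X_test)
                c = harrell_c(
                    risk,
                    data.outcome.time[test_rows],
                    data.outcome.status[test_rows],
                )
            except BlocksurvError:
                c = None
            rows.append(
                {
                    "repetition": rep + 1,
                    "fold": fold_i + 1,
                    "c_index": np.nan if c is None else c,
                }
            )
            it += 1
    return CVResult(pd.DataFrame(rows), method=spec.variant, dataset=dataset_label)


def summarize_cv_results(results: Sequence[CVResult]) -> tuple:
    """Mean-C table (data sets x methods) and the per-data-set method ranks
    (rank 1 = highest mean C)."""
    records = {}
    for res in results:
        records.setdefault(res.dataset, {})[res.method] = res.mean_c
    mean_c = pd.DataFrame(records).T.sort_index()
    mean_c.index.name = "data_set"
    ranks = mean_c.rank(axis=1, ascending=False)
    return mean_c, ranks
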