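"""Random-search tuning of block-specific parameters by out-of-bag error.

Each variant carries one tuning parameter per block.  Tuning draws
``n_sets`` random parameter sets (by default 300), fits a forest with
``num_trees_pre`` trees (by default 1500) for each, records its out-of-bag
error (one minus Harrell's C) and keeps the set with the smallest error.
The random search is inefficient but consistent: with more sets the
selected error approaches the optimum achievable under the OOB criterion.

The random generators have full support on each variant's constraint set:

* ``varprob``: v_m = u_m / sum_k p_k u_k with u_m ~ U(0,1), which enforces
  sum_m p_m v_m = 1 by construction;
* block weights: w_m = a_m / max_k a_k with a_m ~ U(0,1), so max w_m = 1;
* ``randomblock``: b uniform on the simplex (normalized standard
  exponentials), so sum_m b_m = 1.

The RSF baseline instead grid-searches mtry over {ceil(x * sqrt(p))} for
x in {0.1, 0.25, 1/2, 1, 2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .data_model import (
    BlockedDataset,
    BlocksurvError,
    BlockStructure,
    VariantParams,
    as_generator,
    canonical_variant,
)
from .forest import fit_forest, oob_error

__all__ = [
    "TuningConfig",
    "TuningError",
    "TuningTrace",
    "generate_param_set",
    "tune_variant",
    "tune_rsf_mtry",
    "rsf_mtry_grid",
]


class TuningError(BlocksurvError):
    """No parameter set yielded a computable out-of-bag error."""


@dataclass(frozen=True)
class TuningConfig:
    """Random-search settings: number of candidate sets, trees per
    candidate forest, and the seed driving generation and fitting."""

    n_sets: int = 300
    num_trees_pre: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise BlocksurvError("n_sets must be >= 1")
        if self.num_trees_pre < 1:
            raise BlocksurvError("num_trees_pre must be >= 1")


@dataclass(frozen=True)
class TuningTrace:
    """All evaluated parameter sets with their OOB errors (``None`` =
    invalid) and the index of the selected optimum."""

    evaluated: tuple
    selected: int

    def __post_init__(self) -> None:
        errors = [e for _, e in self.evaluated if e is not None]
        if not errors:
            raise TuningError("a trace needs at least one valid entry")
        sel_err = self.evaluated[self.selected][1]
        if sel_err is None or sel_err > min(errors):
            raise BlocksurvError("selected entry must hold the minimal valid error")

    @property
    def best_params(self) -> VariantParams:
        return self.evaluated[self.selected][0]

    @property
    def best_error(self) -> float:
        return float(self.evaluated[self.selected][1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (params, err) in enumerate(self.evaluated):
            row = {"iteration": i + 1}
            for m, v in enumerate(params.values):
                row[f"param_{m + 1}"] = v
            row["oob_error"] = np.nan if err is None else err
            row["selected"] = i == self.selected
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# parameter-set generation
# ---------------------------------------------------------------------------


def generate_param_set(
    variant: str,
    structure: BlockStructure,
    rng: Union[int, np.random.Generator, None] = None,
    mandatory_block: bool = False,
) -> VariantParams:
    """Draw one random tuning parameter set satisfying the variant's
    constraint (see module docstring for the constructions)."""
    variant = canonical_variant(variant)
    rng = as_generator(rng)
    M = structure.M
    if variant == "varprob":
        u = rng.uniform(size=M)
        u = np.maximum(u, 1e-300)
        v = u / float((structure.sizes * u).sum())
        values = v
    elif variant in ("splitweights", "blockvarsel", "blockforest"):
        a = rng.uniform(size=M)
        a = np.maximum(a, 1e-300)
        values = a / a.max()
    elif variant == "randomblock":
        e = rng.standard_exponential(size=M)
        e = np.maximum(e, 1e-300)
        values = e / e.sum()
    else:
        raise BlocksurvError("rsf is tuned with tune_rsf_mtry, not random sets")
    return VariantParams(variant, values, mandatory_block=mandatory_block)


# ---------------------------------------------------------------------------
# random-search tuning
# ---------------------------------------------------------------------------

Evaluator = Callable[[VariantParams], Optional[float]]


def _argmin_valid(errors: List[Optional[float]]) -> int:
    best = -1
    best_err = math.inf
    for i, e in enumerate(errors):
        if e is not None and e < best_err:  # strict: ties keep the earlier set
            best = i
            best_err = e
    if best < 0:
        raise TuningError(
            "no parameter set produced a computable out-of-bag error; "
            "try more trees or check that the data contain comparable pairs"
        )
    return best


def tune_variant(
    data: BlockedDataset,
    variant: str,
    tconfig: TuningConfig = TuningConfig(),
    min_node_size: int = 3,
    mandatory_block: bool = False,
    evaluator: Optional[Evaluator] = None,
) -> Tuple[VariantParams, TuningTrace]:
    """Random-search optimization of a variant's block parameters.

    For each of ``tconfig.n_sets`` iterations a random parameter set is
    generated and scored by the out-of-bag error of a ``num_trees_pre``-tree
    forest; the set with the smallest valid error wins (ties keep the
    earliest set; invalid errors are excluded).  ``evaluator`` overrides the
    scoring function, e.g. for testing or custom error measures.
    """
    variant = canonical_variant(variant)
    if variant == "rsf":
        raise BlocksurvError("use tune_rsf_mtry for the rsf baseline")
    ss = np.random.SeedSequence(int(tconfig.seed))
    gen_seeds = ss.generate_state(2 * tconfig.n_sets) & 0x3FFFFFFF
    entries = []
    errors: List[Optional[float]] = []
    for it in range(tconfig.n_sets):
        params = generate_param_set(
            variant,
            data.structure,
            rng=int(gen_seeds[2 * it]),
            mandatory_block=mandatory_block,
        )
        if evaluator is not None:
            err = evaluator(params)
        else:
            forest = fit_forest(
                data,
                params,
                num_trees=tconfig.num_trees_pre,
                min_node_size=min_node_size,
                seed=int(gen_seeds[2 * it + 1]),
            )
            err = oob_error(forest, data)
        entries.append((params, err))
        errors.append(err)
    selected = _argmin_valid(errors)
    trace = TuningTrace(tuple(entries), selected)
    return trace.best_params, trace


def rsf_mtry_grid(p: int) -> List[int]:
    """The mtry grid {ceil(x * sqrt(p))} for x in {0.1, 0.25, 0.5, 1, 2},
    deduplicated, floored at 1 and capped at p."""
    if p < 1:
        raise BlocksurvError("p must be >= 1")
    grid = sorted(
        {min(p, max(1, math.ceil(x * math.sqrt(p)))) for x in (0.1, 0.25, 0.5, 1.0, 2.0)}
    )
    return grid


def tune_rsf_mtry(
    data: BlockedDataset,
    tconfig: TuningConfig = TuningConfig(),
    min_node_size: int = 3,
    evaluator: Optional[Callable[[int], Optional[float]]] = None,
) -> Tuple[int, TuningTrace]:
    """Grid-search the RSF baseline's mtry by out-of-bag error; ties keep
    the smallest mtry.  Returns the winning mtry and the evaluation trace."""
    grid = rsf_mtry_grid(data.p)
    ss = np.random.SeedSequence(int(tconfig.seed))
    seeds = ss.generate_state(len(grid)) & 0x3FFFFFFF
    entries = []
    errors: List[Optional[float]] = []
    for i, mtry in enumerate(grid):
        params = VariantParams("rsf", [mtry])
        if evaluator is not None:
            err = evaluator(mtry)
        else:
            forest = fit_forest(
                data,
                params,
                num_trees=tconfig.num_trees_pre,
                min_node_size=min_node_size,
                seed=int(seeds[i]),
            )
            err = oob_error(forest, data)
        entries.append((params, err))
        errors.append(err)
    selected = _argmin_valid(errors)
    trace = TuningTrace(tuple(entries), selected)
    return grid[selected], trace
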