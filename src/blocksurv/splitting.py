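"""Split criterion and the variant-specific candidate-generation procedures.

Split scoring uses the squared standardized log-rank statistic
``(O - E)^2 / V`` comparing the two child nodes, with a single random
split point per candidate variable (the extremely-randomized-trees
construction): evaluating every possible cut point with a log-rank test is
too expensive in high dimensions, and a single uniform draw in the open
interval of the node's observed values has been found competitive.

The five block-aware procedures differ only in how the candidate variables
for a split are generated and whether block weights multiply the criterion:

* ``varprob``     -- all variables, block-specific selection probabilities v_m;
* ``splitweights``-- standard uniform sampling, criterion weighted by w_m;
* ``blockvarsel`` -- ceil(sqrt(p_m)) variables from every block, weighted;
* ``randomblock`` -- one block drawn with probabilities b_m, unweighted;
* ``blockforest`` -- each block kept with probability 1/2 (redraw if the
  subset is empty), per-block sampling, weighted.

All randomness flows through an injected seeded ``numpy.random.Generator``;
each public function seeds the compiled engine from it so that the exact
code path used inside tree growth is exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import _engine
from .data_model import (
    BlockedDataset,
    BlocksurvError,
    BlockStructure,
    as_generator,
    block_mtry,
)

__all__ = [
    "CandidateSet",
    "SplitProposal",
    "logrank_statistic",
    "draw_split_point",
    "sample_candidates_standard",
    "sample_candidates_varprob",
    "sample_candidates_per_block",
    "select_block_randomblock",
    "select_blocks_blockforest",
    "best_weighted_split",
    "augment_mandatory_block",
]

RngLike = Union[int, np.random.Generator, None]


def _engine_seed(rng: RngLike) -> int:
    return int(as_generator(rng).integers(0, 2**31))


@dataclass(frozen=True)
class CandidateSet:
    """Distinct candidate variables for one split, with their block labels."""

    variables: np.ndarray
    blocks: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        var = np.asarray(self.variables, dtype=np.int64)
        blk = np.asarray(self.blocks, dtype=np.int64)
        if var.size != np.unique(var).size:
            raise BlocksurvError("candidate variables must be distinct")
        if var.shape != blk.shape:
            raise BlocksurvError("one block label per candidate variable is required")
        object.__setattr__(self, "variables", var)
        object.__setattr__(self, "blocks", blk)

    def __len__(self) -> int:
        return int(self.variables.size)


@dataclass(frozen=True)
class SplitProposal:
    """A scored split: variable, threshold and (weighted) criterion value."""

    variable: int
    threshold: float
    raw_criterion: float
    weighted_criterion: float
    block: int


# ---------------------------------------------------------------------------
# criterion
# ---------------------------------------------------------------------------


def logrank_statistic(
    times_left: Sequence[float],
    status_left: Sequence[int],
    times_right: Sequence[float],
    status_right: Sequence[int],
) -> Optional[float]:
    """Squared standardized log-rank statistic ``(O - E)^2 / V`` between two
    nonempty groups; larger values indicate better separation.

    Over the distinct event times of the pooled sample, ``O`` is the
    observed number of left-group events, ``E`` the expectation under the
    null of equal hazards and ``V`` the hypergeometric variance.  Returns
    ``None`` ("inadmissible") when ``V = 0``, e.g. when no events occur.
    """
    tl = np.asarray(times_left, dtype=np.float64)
    tr = np.asarray(times_right, dtype=np.float64)
    sl = np.asarray(status_left, dtype=np.int8)
    sr = np.asarray(status_right, dtype=np.int8)
    if tl.size == 0 or tr.size == 0:
        raise BlocksurvError("both children must be nonempty")
    t = np.concatenate([tl, tr])
    s = np.concatenate([sl, sr])
    left = np.zeros(t.size, dtype=bool)
    left[: tl.size] = True
    order = np.argsort(t, kind="mergesort")
    stat = _engine.logrank_pass(t[order], s[order], left[order])
    return None if stat < 0 else float(stat)


def draw_split_point(values_in_node: Sequence[float], rng: RngLike = None) -> Optional[float]:
    """One threshold drawn uniformly from the open interval (min, max) of a
    candidate variable's values in the node; observations with value <=
    threshold go left.  Returns ``None`` for a constant variable."""
    v = np.asarray(values_in_node, dtype=np.float64)
    mn, mx = float(v.min()), float(v.max())
    if mx <= mn:
        return None
    return float(as_generator(rng).uniform(mn, mx))


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------


def _wrap(structure: BlockStructure, variables: np.ndarray, provenance: str) -> CandidateSet:
    blocks = structure.block_of_var[variables]
    return CandidateSet(variables, blocks, provenance)


def sample_candidates_standard(
    structure: BlockStructure, mtry: int, rng: RngLike = None
) -> CandidateSet:
    """mtry distinct variables drawn uniformly without replacement from all
    p variables (the block-agnostic baseline)."""
    p = structure.p
    mtry = int(mtry)
    if mtry < 1:
        raise BlocksurvError("mtry must be >= 1")
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds p={p}; capped at p", stacklevel=2)
        mtry = p
    cand = np.empty(p, dtype=np.int64)
    _engine.seed_engine(_engine_seed(rng))
    k = _engine.sample_ids(p, mtry, cand, 0)
    return _wrap(structure, cand[:k], "standard")


def sample_candidates_varprob(
    structure: BlockStructure,
    v: Sequence[float],
    mtry: Optional[int] = None,
    rng: RngLike = None,
) -> CandidateSet:
    """Sequential categorical draws with per-variable probability ``v_m``
    (the variable's block), rejecting duplicates until mtry distinct
    variables are collected.  ``mtry`` defaults to sum_m ceil(sqrt(p_m))."""
    v = np.asarray(v, dtype=np.float64)
    if v.size != structure.M:
        raise BlocksurvError("one selection probability per block is required")
    if mtry is None:
        _, mtry = block_mtry(structure)
    mtry = min(int(mtry), structure.p)
    prob = v[structure.block_of_var]
    cum = np.cumsum(prob)
    cand = np.empty(structure.p, dtype=np.int64)
    _engine.seed_engine(_engine_seed(rng))
    k = _engine.sample_varprob(cum, mtry, cand)
    return _wrap(structure, cand[:k], "varprob")


def sample_candidates_per_block(
    structure: BlockStructure,
    rng: RngLike = None,
    selected_blocks: Optional[Sequence[int]] = None,
) -> CandidateSet:
    """ceil(sqrt(p_m)) distinct variables drawn uniformly within each
    selected block (all blocks by default)."""
    M = structure.M
    if selected_blocks is None:
        selected = list(range(M))
    else:
        selected = sorted(int(m) for m in selected_blocks)
        if not selected:
            raise BlocksurvError("at least one block must be selected")
        if selected[0] < 0 or selected[-1] >= M:
            raise BlocksurvError("selected block index out of range")
    kms, _ = block_mtry(structure)
    block_cols, block_off = _block_layout(structure)
    cand = np.empty(structure.p, dtype=np.int64)
    _engine.seed_engine(_engine_seed(rng))
    pos = 0
    for m in selected:
        pos = _engine.sample_block(
            block_cols, block_off[m], block_off[m + 1] - block_off[m], kms[m], cand, pos
        )
    return _wrap(structure, cand[:pos], "per_block")


def select_block_randomblock(b: Sequence[float], rng: RngLike = None) -> int:
    """One categorical draw over blocks with selection probabilities b."""
    b = np.asarray(b, dtype=np.float64)
    if abs(b.sum() - 1.0) > 1e-10:
        raise BlocksurvError("block selection probabilities must sum to 1")
    _engine.seed_engine(_engine_seed(rng))
    return int(_engine.select_randomblock(np.cumsum(b)))


def select_blocks_blockforest(M: int, rng: RngLike = None) -> np.ndarray:
    """Nonempty block subset: each block kept independently with probability
    0.5; the all-empty outcome triggers a redraw."""
    M = int(M)
    if M < 1:
        raise BlocksurvError("M must be >= 1")
    selected = np.empty(M, dtype=np.bool_)
    _engine.seed_engine(_engine_seed(rng))
    _engine.select_blocks_half(M, selected)
    return np.flatnonzero(selected)


def _block_layout(structure: BlockStructure):
    block_cols = np.concatenate(structure.columns)
    block_off = np.concatenate([[0], np.cumsum(structure.sizes)]).astype(np.int64)
    return block_cols, block_off


# ---------------------------------------------------------------------------
# split selection
# ---------------------------------------------------------------------------


def best_weighted_split(
    data: BlockedDataset,
    rows: np.ndarray,
    candidates: CandidateSet,
    w: Optional[Sequence[float]] = None,
    rng: RngLike = None,
) -> Optional[SplitProposal]:
    """Draw one split point per candidate, score each with the log-rank
    criterion, multiply by the block weight ``w_m`` (1 if ``w`` is None) and
    return the proposal with the largest weighted criterion.

    Returns ``None`` when every proposal is inadmissible or no candidate is
    splittable.  Ties keep the first-encountered proposal in the candidate
    order fixed by the seeded rng.
    """
    if len(candidates) == 0:
        return None
    rows = np.asarray(rows, dtype=np.int64)
    if rows.size < 2:
        raise BlocksurvError("a node needs at least two observations to split")
    time = data.outcome.time
    status = data.outcome.status
    order = np.argsort(time[rows], kind="mergesort")
    orows = rows[order]
    t_s = time[orows]
    s_s = status[orows]
    cand = candidates.variables
    if w is None:
        wts = np.ones(cand.size)
    else:
        w = np.asarray(w, dtype=np.float64)
        wts = w[candidates.blocks]
    _engine.seed_engine(_engine_seed(rng))
    bj, thr, raw, wcrit = _engine.best_split(
        data.X, orows, t_s, s_s, cand, wts, cand.size
    )
    if bj < 0:
        return None
    return SplitProposal(
        variable=int(cand[bj]),
        threshold=float(thr),
        raw_criterion=float(raw),
        weighted_criterion=float(wcrit),
        block=int(candidates.blocks[bj]),
    )


def augment_mandatory_block(
    candidates: CandidateSet, structure: BlockStructure
) -> CandidateSet:
    """Union the candidate set with all variables of the designated clinical
    block (duplicates removed, block labels retained)."""
    ci = structure.clinical_index
    if ci is None:
        raise BlocksurvError(
            "mandatory inclusion requires a designated clinical block"
        )
    clin = structure.columns[ci]
    extra = clin[~np.isin(clin, candidates.variables)]
    variables = np.concatenate([candidates.variables, extra])
    blocks = np.concatenate([candidates.blocks, np.full(extra.size, ci, np.int64)])
    return CandidateSet(variables, blocks, candidates.provenance + "+mandatory")
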