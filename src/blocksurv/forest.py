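"""Survival forest fitting, prediction and out-of-bag error.

Trees are grown on bootstrap samples (size n, with replacement) by
recursive partitioning with a single random split point per candidate
variable.  Terminal nodes store the Nelson-Aalen cumulative hazard of
their in-bag observations, evaluated on the pooled training event-time
grid so tree averages are step functions on a common grid.  The ensemble
risk score of an observation is its "mortality": the tree-averaged
cumulative hazard summed over the grid.  Any strictly monotone transform
of the score yields the same concordance, so mortality is used purely as a
risk ordering.

Per-tree RNG streams are derived deterministically from ``(seed, tree
index)``, so results do not depend on execution order.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import _engine
from .data_model import (
    BlockedDataset,
    BlocksurvError,
    BlockStructure,
    FitError,
    VariantParams,
    as_generator,
    block_mtry,
)

__all__ = [
    "SurvivalTree",
    "SurvivalForest",
    "grow_tree",
    "fit_forest",
    "predict_mortality",
    "oob_error",
    "save_forest",
    "load_forest",
]


@dataclass(frozen=True)
class SurvivalTree:
    """One fitted tree: split nodes, terminal-node CHFs, in-bag counts."""

    feature: np.ndarray      # per node: split variable, -1 for terminal
    threshold: np.ndarray    # per node: split point ("<= goes left")
    left: np.ndarray         # per node: left child id, -1 for terminal
    right: np.ndarray        # per node: right child id, -1 for terminal
    leaf_slot: np.ndarray    # per node: row into leaf_chf, -1 for internal
    leaf_chf: np.ndarray     # (n_leaves, grid size) cumulative hazards
    inbag_count: np.ndarray  # per training observation: bootstrap multiplicity

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    @property
    def n_leaves(self) -> int:
        return int(self.leaf_chf.shape[0])

    @property
    def leaf_mortality(self) -> np.ndarray:
        """Sum of each terminal CHF over the event-time grid."""
        return self.leaf_chf.sum(axis=1)


@dataclass(frozen=True)
class SurvivalForest:
    """A collection of survival trees sharing one event-time grid."""

    trees: tuple
    structure: BlockStructure
    params: VariantParams
    event_time_grid: np.ndarray
    min_node_size: int
    seed: int

    @property
    def num_trees(self) -> int:
        return len(self.trees)

    @property
    def n_train(self) -> int:
        return int(self.trees[0].inbag_count.size)


# ---------------------------------------------------------------------------
# kernel argument marshalling
# ---------------------------------------------------------------------------


def _kernel_args(structure: BlockStructure, params: VariantParams, n_events_total: int):
    params.validate_for(structure)
    variant = _engine.VARIANT_CODES[params.variant]
    kms, total_k = block_mtry(structure)
    block_cols = np.concatenate(structure.columns)
    block_off = np.concatenate([[0], np.cumsum(structure.sizes)]).astype(np.int64)
    block_of_var = structure.block_of_var
    p = structure.p
    mtry_rsf = params.mtry if params.variant == "rsf" else 0
    if params.variant == "varprob":
        var_cum_prob = np.cumsum(params.values[block_of_var])
    else:
        var_cum_prob = np.zeros(0)
    if params.variant in ("splitweights", "blockvarsel", "blockforest"):
        weights = params.values.copy()
        use_weights = True
    else:
        weights = np.ones(structure.M)
        use_weights = False
    if params.variant == "randomblock":
        cum_b = np.cumsum(params.values)
    else:
        cum_b = np.ones(structure.M)
    if params.mandatory_block:
        mandatory = structure.columns[structure.clinical_index].astype(np.int64)
    else:
        mandatory = np.zeros(0, dtype=np.int64)
    return (
        variant,
        mtry_rsf,
        total_k,
        kms,
        block_cols,
        block_off,
        block_of_var,
        var_cum_prob,
        weights,
        use_weights,
        cum_b,
        mandatory,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def grow_tree(
    data: BlockedDataset,
    inbag: np.ndarray,
    params: VariantParams,
    min_node_size: int = 3,
    rng: Union[int, np.random.Generator, None] = None,
    event_time_grid: Optional[np.ndarray] = None,
) -> SurvivalTree:
    """Grow a single survival tree on the given in-bag index multiset.

    A node becomes terminal when its size is at most ``min_node_size``, it
    contains no events, or no admissible split exists; its CHF is the
    Nelson-Aalen estimate over the node's in-bag observations on the
    forest's event-time grid (all distinct training event times by
    default).
    """
    inbag = np.asarray(inbag, dtype=np.int64)
    time = data.outcome.time
    status = data.outcome.status
    if status[inbag].sum() == 0:
        raise FitError("the in-bag sample contains no observed events")
    if event_time_grid is None:
        event_time_grid = np.unique(time[status == 1])
    args = _kernel_args(data.structure, params, data.outcome.n_events)
    seed = int(as_generator(rng).integers(0, 2**31))
    _engine.seed_engine(seed)
    feature, thresh, left, right, leaf_slot, chf = _engine.grow_tree_kernel(
        data.X, time, status, event_time_grid, inbag, *args, int(min_node_size)
    )
    counts = np.bincount(inbag, minlength=data.n).astype(np.int32)
    return SurvivalTree(feature, thresh, left, right, leaf_slot, chf, counts)


def fit_forest(
    data: BlockedDataset,
    params: VariantParams,
    num_trees: int = 2000,
    min_node_size: int = 3,
    seed: Union[int, np.random.Generator, None] = 0,
) -> SurvivalForest:
    """Fit a survival forest: ``num_trees`` trees on independent bootstrap
    samples, deterministic given ``seed``."""
    if num_trees < 1:
        raise BlocksurvError("num_trees must be >= 1")
    if data.outcome.n_events == 0:
        raise FitError("model fitting requires at least one observed event")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(0, 2**31))
    seed = int(seed)
    time = data.outcome.time
    status = data.outcome.status
    grid = np.unique(time[status == 1])
    args = _kernel_args(data.structure, params, data.outcome.n_events)
    tree_seeds = np.random.SeedSequence(seed).generate_state(num_trees) & 0x7FFFFFFF
    n = data.n
    trees = []
    for t in range(num_trees):
        _engine.seed_engine(int(tree_seeds[t]))
        inbag, counts = _engine.bootstrap_inbag(n)
        if status[inbag].sum() == 0:
            raise FitError(
                f"bootstrap sample of tree {t + 1} contains no observed events"
            )
        feature, thresh, left, right, leaf_slot, chf = _engine.grow_tree_kernel(
            data.X, time, status, grid, inbag, *args, int(min_node_size)
        )
        trees.append(
            SurvivalTree(feature, thresh, left, right, leaf_slot, chf, counts)
        )
    return SurvivalForest(
        tuple(trees), data.structure, params, grid, int(min_node_size), seed
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_mortality(forest: SurvivalForest, X_new: np.ndarray) -> np.ndarray:
    """Ensemble mortality per new observation: route each observation to a
    terminal CHF in every tree, average the CHFs across trees, and sum the
    averaged CHF over the event-time grid.  Higher = higher predicted risk.
    """
    X_new = np.ascontiguousarray(np.asarray(X_new, dtype=np.float64))
    if X_new.ndim != 2 or X_new.shape[1] != forest.structure.p:
        raise BlocksurvError(
            f"expected {forest.structure.p} columns, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else 'non-matrix input'}"
        )
    scores = np.zeros(X_new.shape[0])
    for tree in forest.trees:
        slots = _engine.route(
            X_new, tree.feature, tree.threshold, tree.left, tree.right, tree.leaf_slot
        )
        scores += tree.leaf_mortality[slots]
    return scores / forest.num_trees


def predict_cumulative_hazard(forest: SurvivalForest, X_new: np.ndarray) -> np.ndarray:
    """Tree-averaged cumulative hazard function per new observation, as an
    (n_new, grid size) step-function matrix on ``forest.event_time_grid``."""
    X_new = np.ascontiguousarray(np.asarray(X_new, dtype=np.float64))
    out = np.zeros((X_new.shape[0], forest.event_time_grid.size))
    for tree in forest.trees:
        slots = _engine.route(
            X_new, tree.feature, tree.threshold, tree.left, tree.right, tree.leaf_slot
        )
        out += tree.leaf_chf[slots]
    return out / forest.num_trees


def oob_error(forest: SurvivalForest, data: BlockedDataset) -> Optional[float]:
    """Out-of-bag prediction error ``1 - Harrell's C``.

    Each observation's risk score aggregates only the trees in whose
    bootstrap sample it does not appear; observations that are in-bag in
    every tree are excluded.  Returns ``None`` ("invalid") when the C index
    is not computable for the OOB scores (no comparable pairs).
    """
    from .evaluation import harrell_c  # local import avoids a module cycle

    n = data.n
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=np.int64)
    for tree in forest.trees:
        oob = np.flatnonzero(tree.inbag_count == 0)
        if oob.size == 0:
            continue
        slots = _engine.route(
            data.X[oob], tree.feature, tree.threshold, tree.left, tree.right, tree.leaf_slot
        )
        acc[oob] += tree.leaf_mortality[slots]
        cnt[oob] += 1
    have = cnt > 0
    if not np.any(have):
        return None
    scores = acc[have] / cnt[have]
    c = harrell_c(scores, data.outcome.time[have], data.outcome.status[have])
    if c is None:
        return None
    return 1.0 - c


# ---------------------------------------------------------------------------
# serialization (versioned JSON with base64 arrays; byte-deterministic)
# ---------------------------------------------------------------------------

_FORMAT = "blocksurv-forest"
_VERSION = 1


def _enc(arr: np.ndarray) -> dict:
    arr = np.ascontiguousarray(arr)
    return {
        "dtype": str(arr.dtype),
        "shape": list(arr.shape),
        "data": base64.b64encode(arr.tobytes()).decode("ascii"),
    }


def _dec(obj: dict) -> np.ndarray:
    raw = base64.b64decode(obj["data"])
    return np.frombuffer(raw, dtype=np.dtype(obj["dtype"])).reshape(obj["shape"]).copy()


def forest_to_json(forest: SurvivalForest) -> str:
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "structure": forest.structure.to_dict(),
        "variant": forest.params.variant,
        "values": list(map(float, forest.params.values)),
        "mandatory_block": forest.params.mandatory_block,
        "min_node_size": forest.min_node_size,
        "seed": forest.seed,
        "event_time_grid": _enc(forest.event_time_grid),
        "trees": [
            {
                "feature": _enc(t.feature),
                "threshold": _enc(t.threshold),
                "left": _enc(t.left),
                "right": _enc(t.right),
                "leaf_slot": _enc(t.leaf_slot),
                "leaf_chf": _enc(t.leaf_chf),
                "inbag_count": _enc(t.inbag_count),
            }
            for t in forest.trees
        ],
    }
    return json.dumps(doc, separators=(",", ":"), sort_keys=True)


def save_forest(forest: SurvivalForest, path: Union[str, Path]) -> None:
    Path(path).write_text(forest_to_json(forest))


def load_forest(path: Union[str, Path]) -> SurvivalForest:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _FORMAT:
        raise BlocksurvError(f"{path} is not a blocksurv forest file")
    if doc.get("version") != _VERSION:
        raise BlocksurvError(f"unsupported forest file version {doc.get('version')}")
    blocks = doc["structure"]["blocks"]
    structure = BlockStructure(
        tuple(blocks.keys()),
        tuple(np.asarray(c, dtype=np.int64) for c in blocks.values()),
        doc["structure"].get("clinical"),
    )
    params = VariantParams(doc["variant"], np.asarray(doc["values"]), doc["mandatory_block"])
    trees = tuple(
        SurvivalTree(
            _dec(t["feature"]),
            _dec(t["threshold"]),
            _dec(t["left"]),
            _dec(t["right"]),
            _dec(t["leaf_slot"]),
            _dec(t["leaf_chf"]),
            _dec(t["inbag_count"]),
        )
        for t in doc["trees"]
    )
    return SurvivalForest(
        trees,
        structure,
        params,
        _dec(doc["event_time_grid"]),
        int(doc["min_node_size"]),
        int(doc["seed"]),
    )
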