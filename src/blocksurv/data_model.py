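"""Domain types and I/O for block-structured survival data.

A multi-omics data set is a single numeric covariate matrix ``X`` (n x p)
whose columns are partitioned into M named blocks (clinical, miRNA,
mutation, CNV, RNA, ...), together with a right-censored survival outcome
``(time, status)``.  All downstream components (splitting rules, forests,
tuning, cross-validation) operate on the :class:`BlockedDataset` container
defined here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "BlocksurvError",
    "OutcomeError",
    "StructureError",
    "LoadError",
    "FitError",
    "SurvivalOutcome",
    "BlockStructure",
    "BlockedDataset",
    "VariantParams",
    "VARIANTS",
    "block_mtry",
    "load_blocked_dataset",
    "save_blocked_dataset",
]


class BlocksurvError(ValueError):
    """Base class for all validation and fitting errors raised by blocksurv."""


class OutcomeError(BlocksurvError):
    """Invalid survival outcome (non-positive time, status outside {0,1}, ...)."""


class StructureError(BlocksurvError):
    """Invalid block structure (overlapping, missing or unassigned columns)."""


class LoadError(BlocksurvError):
    """A data file could not be parsed into a valid dataset."""


class FitError(BlocksurvError):
    """Model fitting was rejected (e.g. no observed events)."""


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome.

    Parameters
    ----------
    time : array of float
        Observed follow-up time per observation; strictly positive.
    status : array of int
        Event indicator per observation: 1 = event observed, 0 = censored.
    """

    time: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        time = np.ascontiguousarray(np.asarray(self.time, dtype=np.float64))
        status = np.ascontiguousarray(np.asarray(self.status))
        if time.ndim != 1 or status.ndim != 1:
            raise OutcomeError("time and status must be one-dimensional")
        if time.shape[0] != status.shape[0]:
            raise OutcomeError(
                f"time has length {time.shape[0]} but status has length {status.shape[0]}"
            )
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise OutcomeError("all survival/censoring times must be finite and > 0")
        if not np.all(np.isin(status, (0, 1))):
            raise OutcomeError("status values must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int8))

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, rows: np.ndarray) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[rows], self.status[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "status": self.status.astype(int)})


# ---------------------------------------------------------------------------
# block structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockStructure:
    """Partition of the p covariate columns into M named blocks.

    ``columns[m]`` holds the 0-based column indices of block ``m`` in the
    concatenated covariate matrix.  The index lists must be disjoint and
    cover 0..p-1 exactly.  ``clinical_block`` optionally designates the block
    whose variables may be included mandatorily at every split.
    """

    names: tuple
    columns: tuple
    clinical_block: Optional[str] = None

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        cols = tuple(
            np.ascontiguousarray(np.asarray(c, dtype=np.int64)) for c in self.columns
        )
        if len(names) == 0:
            raise StructureError("at least one block is required")
        if len(names) != len(set(names)):
            raise StructureError("block names must be distinct")
        if len(names) != len(cols):
            raise StructureError("one column index list per block name is required")
        for name, c in zip(names, cols):
            if c.size == 0:
                raise StructureError(f"block '{name}' is empty")
        allcols = np.concatenate(cols)
        p = allcols.size
        seen = np.bincount(allcols[allcols >= 0], minlength=max(p, 1))
        if np.any(allcols < 0) or np.any(allcols >= p) or np.any(seen > 1) or np.any(
            seen[:p] == 0
        ):
            # pinpoint the offending column for the error message
            counts = {}
            for c in allcols:
                counts[int(c)] = counts.get(int(c), 0) + 1
            for j, k in counts.items():
                if k > 1:
                    raise StructureError(f"column {j + 1} assigned to more than one block")
            for j in range(p):
                if j not in counts:
                    raise StructureError(f"column {j + 1} unassigned")
            raise StructureError("block column indices must partition 1..p")
        if self.clinical_block is not None and self.clinical_block not in names:
            raise StructureError(
                f"clinical block '{self.clinical_block}' is not among the block names"
            )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "columns", cols)

    @classmethod
    def from_sizes(
        cls,
        sizes: Sequence[int],
        names: Optional[Sequence[str]] = None,
        clinical_block: Optional[str] = None,
    ) -> "BlockStructure":
        """Contiguous structure with the given block sizes, in order."""
        sizes = [int(s) for s in sizes]
        if names is None:
            names = [f"block{m + 1}" for m in range(len(sizes))]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        cols = [np.arange(offs[m], offs[m + 1], dtype=np.int64) for m in range(len(sizes))]
        return cls(tuple(names), tuple(cols), clinical_block)

    @property
    def M(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.columns], dtype=np.int64)

    @property
    def p(self) -> int:
        return int(self.sizes.sum())

    @property
    def block_of_var(self) -> np.ndarray:
        """Array of length p mapping each column to its block index."""
        out = np.empty(self.p, dtype=np.int64)
        for m, c in enumerate(self.columns):
            out[c] = m
        return out

    @property
    def clinical_index(self) -> Optional[int]:
        if self.clinical_block is None:
            return None
        return self.names.index(self.clinical_block)

    def to_dict(self) -> dict:
        d: dict = {name: [int(j) for j in c] for name, c in zip(self.names, self.columns)}
        return {"blocks": d, "clinical": self.clinical_block}


def block_mtry(structure: BlockStructure) -> tuple:
    """Per-block candidate counts ``k_m = ceil(sqrt(p_m))`` and their total.

    Every block contributes at least one candidate; ``k_m`` never exceeds
    ``p_m``.  The total is the number of candidate variables drawn per split
    by the variants that sample from all blocks.
    """
    sizes = structure.sizes
    k = np.maximum(1, np.ceil(np.sqrt(sizes)).astype(np.int64))
    k = np.minimum(k, sizes)
    return k, int(k.sum())


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockedDataset:
    """Covariate matrix, survival outcome and block structure, validated."""

    X: np.ndarray
    outcome: SurvivalOutcome
    structure: BlockStructure
    var_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float64))
        if X.ndim != 2:
            raise LoadError("covariate matrix must be two-dimensional")
        n, p = X.shape
        if n < 2:
            raise LoadError("at least two observations are required")
        if p != self.structure.p:
            raise StructureError(
                f"matrix has {p} columns but the block structure covers {self.structure.p}"
            )
        if n != self.outcome.n:
            raise OutcomeError(
                f"matrix has {n} rows but the outcome has {self.outcome.n}"
            )
        bad = np.argwhere(~np.isfinite(X))
        if bad.size:
            i, j = bad[0]
            raise LoadError(
                f"missing or non-finite value at row {i + 1}, column {j + 1}"
            )
        if self.var_names is not None:
            names = tuple(str(v) for v in self.var_names)
            if len(names) != p:
                raise StructureError("one variable name per column is required")
            object.__setattr__(self, "var_names", names)
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, rows: np.ndarray) -> "BlockedDataset":
        rows = np.asarray(rows, dtype=np.int64)
        return BlockedDataset(
            self.X[rows], self.outcome.subset(rows), self.structure, self.var_names
        )

    def subset_columns(self, cols: np.ndarray) -> "BlockedDataset":
        """Restrict to a subset of columns, keeping block order and labels.

        ``cols`` are global column indices; blocks that lose all their
        columns are dropped from the structure.
        """
        cols = np.asarray(cols, dtype=np.int64)
        keep = np.zeros(self.p, dtype=bool)
        keep[cols] = True
        new_names = []
        new_cols = []
        order = []
        pos = 0
        for name, c in zip(self.structure.names, self.structure.columns):
            kept = c[keep[c]]
            if kept.size == 0:
                continue
            new_names.append(name)
            new_cols.append(np.arange(pos, pos + kept.size, dtype=np.int64))
            order.append(kept)
            pos += kept.size
        order_all = np.concatenate(order)
        clinical = self.structure.clinical_block
        if clinical is not None and clinical not in new_names:
            clinical = None
        names = (
            tuple(self.var_names[j] for j in order_all) if self.var_names else None
        )
        return BlockedDataset(
            self.X[:, order_all],
            self.outcome,
            BlockStructure(tuple(new_names), tuple(new_cols), clinical),
            names,
        )


# ---------------------------------------------------------------------------
# variant parameters
# ---------------------------------------------------------------------------

VARIANTS = ("varprob", "splitweights", "blockvarsel", "randomblock", "blockforest", "rsf")

_VARIANT_ALIASES = {
    "varprob": "varprob",
    "var_prob": "varprob",
    "splitweights": "splitweights",
    "split_weights": "splitweights",
    "blockvarsel": "blockvarsel",
    "block_var_sel": "blockvarsel",
    "randomblock": "randomblock",
    "random_block": "randomblock",
    "blockforest": "blockforest",
    "block_forest": "blockforest",
    "rsf": "rsf",
}


def canonical_variant(name: str) -> str:
    key = str(name).strip().lower()
    if key not in _VARIANT_ALIASES:
        raise BlocksurvError(
            f"unknown variant '{name}'; expected one of {sorted(set(_VARIANT_ALIASES))}"
        )
    return _VARIANT_ALIASES[key]


@dataclass(frozen=True)
class VariantParams:
    """Block-specific tuning parameters of one forest variant.

    The interpretation of ``values`` depends on the variant:

    * ``varprob`` -- per-block variable selection probabilities v_m with
      sum_m p_m * v_m = 1;
    * ``splitweights`` / ``blockvarsel`` / ``blockforest`` -- block weights
      w_m in (0, 1] with max_m w_m = 1;
    * ``randomblock`` -- block selection probabilities b_m with sum_m b_m = 1;
    * ``rsf`` -- a single integer mtry (the baseline ignores blocks).
    """

    variant: str
    values: np.ndarray
    mandatory_block: bool = False

    _TOL = 1e-10

    def __post_init__(self) -> None:
        variant = canonical_variant(self.variant)
        values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        if values.ndim != 1 or values.size == 0:
            raise BlocksurvError("parameter values must be a non-empty vector")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise BlocksurvError("parameter values must be finite and nonnegative")
        if variant == "rsf":
            if values.size != 1 or values[0] < 1 or values[0] != np.floor(values[0]):
                raise BlocksurvError("rsf takes a single integer mtry >= 1")
        elif variant in ("splitweights", "blockvarsel", "blockforest"):
            if np.any(values <= 0) or np.any(values > 1):
                raise BlocksurvError("block weights must lie in (0, 1]")
            if abs(values.max() - 1.0) > self._TOL:
                raise BlocksurvError("the largest block weight must equal 1")
        elif variant == "randomblock":
            if abs(values.sum() - 1.0) > self._TOL:
                raise BlocksurvError("block selection probabilities must sum to 1")
        object.__setattr__(self, "variant", variant)
        object.__setattr__(self, "values", values)

    def validate_for(self, structure: BlockStructure) -> None:
        """Check the structure-dependent constraints."""
        if self.variant == "rsf":
            return
        if self.values.size != structure.M:
            raise BlocksurvError(
                f"{self.variant} needs one value per block "
                f"({structure.M}), got {self.values.size}"
            )
        if self.variant == "varprob":
            total = float((structure.sizes * self.values).sum())
            if abs(total - 1.0) > self._TOL:
                raise BlocksurvError(
                    "variable selection probabilities must satisfy sum_m p_m v_m = 1 "
                    f"(got {total:.6g})"
                )
        if self.mandatory_block and structure.clinical_block is None:
            raise BlocksurvError(
                "mandatory clinical inclusion requires a designated clinical block"
            )

    @property
    def mtry(self) -> int:
        if self.variant != "rsf":
            raise BlocksurvError("mtry is only defined for the rsf variant")
        return int(self.values[0])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise LoadError(f"could not read {path}: {exc}") from exc


_RANGE_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


def _resolve_block_columns(
    entry: Sequence, colnames: Sequence[str]
) -> np.ndarray:
    """Resolve a block-spec entry (column names or 1-based "a-b" ranges)."""
    name_to_idx = {c: i for i, c in enumerate(colnames)}
    out = []
    for item in entry:
        if isinstance(item, str):
            m = _RANGE_RE.match(item)
            if m and item not in name_to_idx:
                a, b = int(m.group(1)), int(m.group(2))
                if a < 1 or b > len(colnames) or a > b:
                    raise StructureError(f"index range '{item}' is out of bounds")
                out.extend(range(a - 1, b))
                continue
            if item not in name_to_idx:
                raise StructureError(f"unknown column '{item}' in block spec")
            out.append(name_to_idx[item])
        else:
            j = int(item)
            if j < 1 or j > len(colnames):
                raise StructureError(f"column index {j} is out of bounds")
            out.append(j - 1)
    return np.asarray(out, dtype=np.int64)


def load_blocked_dataset(
    matrix_path: Union[str, Path],
    outcome_path: Union[str, Path],
    blocks_config: Union[str, Path, Mapping],
) -> BlockedDataset:
    """Load a covariate matrix, outcome table and block spec from disk.

    The matrix is delimited text with a header row of variable names; the
    outcome table has columns ``time`` and ``status``.  The block spec is a
    JSON object mapping block names to lists of column names (or 1-based
    ``"start-end"`` ranges), with an optional reserved key ``"clinical"``
    naming the clinical block.  Rows align positionally unless both files
    carry an ``id`` column, in which case ids must match as sets and the
    outcome is reordered to the matrix order.
    """
    mat = _read_table(matrix_path)
    out = _read_table(outcome_path)

    if isinstance(blocks_config, (str, Path)):
        with open(blocks_config) as fh:
            spec = json.load(fh)
    else:
        spec = dict(blocks_config)
    if "blocks" in spec and isinstance(spec["blocks"], Mapping):
        clinical = spec.get("clinical")
        spec = spec["blocks"]
    else:
        clinical = spec.pop("clinical", None)

    # optional id-based row alignment
    if "id" in mat.columns and "id" in out.columns:
        mids, oids = list(mat["id"]), list(out["id"])
        if set(mids) != set(oids) or len(set(mids)) != len(mids):
            raise LoadError("id columns of matrix and outcome do not match as sets")
        out = out.set_index("id").loc[mids].reset_index()
        mat = mat.drop(columns=["id"])
        out = out.drop(columns=[c for c in ("id",) if c in out.columns])
    colnames = [str(c) for c in mat.columns]

    for col in ("time", "status"):
        if col not in out.columns:
            raise OutcomeError(f"outcome table lacks a '{col}' column")
    outcome = SurvivalOutcome(
        out["time"].to_numpy(dtype=np.float64), out["status"].to_numpy()
    )

    values = mat.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise LoadError(
            f"missing or non-numeric value at row {i + 1}, column '{colnames[j]}' "
            f"(column {j + 1})"
        )

    names = []
    col_lists = []
    for bname, entry in spec.items():
        names.append(str(bname))
        col_lists.append(_resolve_block_columns(entry, colnames))

    # reorder columns so the matrix follows the config's block order
    assigned = np.concatenate(col_lists) if col_lists else np.empty(0, np.int64)
    counts = np.bincount(assigned, minlength=len(colnames)) if assigned.size else np.zeros(len(colnames), int)
    for j, k in enumerate(counts):
        if k > 1:
            raise StructureError(f"column {j + 1} ('{colnames[j]}') assigned to more than one block")
    for j, k in enumerate(counts):
        if k == 0:
            raise StructureError(f"column {j + 1} ('{colnames[j]}') unassigned")
    order = np.concatenate(col_lists)
    sizes = [c.size for c in col_lists]
    structure = BlockStructure.from_sizes(sizes, names, clinical)
    var_names = tuple(colnames[j] for j in order)
    return BlockedDataset(values[:, order], outcome, structure, var_names)


def save_blocked_dataset(
    data: BlockedDataset,
    matrix_path: Union[str, Path],
    outcome_path: Union[str, Path],
    blocks_path: Union[str, Path],
) -> None:
    """Write the matrix / outcome / block-spec file triple read back by
    :func:`load_blocked_dataset` (bit-exact round trip)."""
    var_names = data.var_names or tuple(
        f"v{j + 1}" for j in range(data.p)
    )
    df = pd.DataFrame(data.X, columns=list(var_names))
    df.to_csv(matrix_path, index=False, float_format="%.17g")
    data.outcome.to_frame().to_csv(outcome_path, index=False, float_format="%.17g")
    spec = {
        "blocks": {
            name: [var_names[j] for j in cols]
            for name, cols in zip(data.structure.names, data.structure.columns)
        },
        "clinical": data.structure.clinical_block,
    }
    with open(blocks_path, "w") as fh:
        json.dump(spec, fh, indent=1)


def as_generator(rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    """Normalize a seed or Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
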