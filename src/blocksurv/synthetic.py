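"""Synthetic block-structured survival data.

The generator emulates the structure of multi-omics cancer cohorts: a
small clinical block plus several high-dimensional omics blocks whose
predictive information overlaps.  Shared latent factors ``Z`` drive the
informative variables of every block, so two blocks loading on the same
factors carry correlated, partially redundant signal -- the feature that
motivates randomizing the block choice during split selection.

Survival times follow a proportional-hazards model with an exponential
baseline hazard: the linear predictor collects each block's informative
factor components scaled by a per-block effect size, and the censoring
rate is calibrated by bisection so the expected censoring fraction matches
a target.  The baseline shape is immaterial for rank-based methods and
Harrell's C, so the simplest closed-form inversion is used.  Censoring is
independent of the covariates, matching the assumptions of Harrell's C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .data_model import (
    BlockedDataset,
    BlocksurvError,
    BlockStructure,
    SurvivalOutcome,
    as_generator,
)

__all__ = ["SimSpec", "simulate_blocked_survival", "make_multiomics_fixture"]


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one synthetic block-structured survival data set.

    Parameters
    ----------
    n : number of observations.
    block_sizes : variables per block, p_1..p_M.
    n_informative : informative variables per block (<= p_m each).
    beta : per-block effect size on the log-hazard scale.
    n_factors : number of shared latent factors q; informative variables of
        every block load on these same factors, which creates overlapping
        predictive information across blocks.
    loadings : per-block loading of informative variables on their factor
        (default 1.0 each); the remaining variance is independent noise.
    baseline_hazard : exponential baseline rate lambda_0.
    censoring : target expected censoring fraction in [0, 1).
    block_names / clinical_block : optional labels.
    seed : RNG seed.
    """

    n: int
    block_sizes: Tuple[int, ...]
    n_informative: Tuple[int, ...]
    beta: Tuple[float, ...]
    n_factors: int = 2
    loadings: Optional[Tuple[float, ...]] = None
    baseline_hazard: float = 0.1
    censoring: float = 0.3
    block_names: Optional[Tuple[str, ...]] = None
    clinical_block: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        M = len(self.block_sizes)
        if M == 0 or any(p < 1 for p in self.block_sizes):
            raise BlocksurvError("every block needs at least one variable")
        if len(self.n_informative) != M or len(self.beta) != M:
            raise BlocksurvError("n_informative and beta need one entry per block")
        if any(s < 0 or s > p for s, p in zip(self.n_informative, self.block_sizes)):
            raise BlocksurvError("informative counts must lie in [0, p_m]")
        if self.loadings is not None and len(self.loadings) != M:
            raise BlocksurvError("loadings need one entry per block")
        if not (0 <= self.censoring < 1):
            raise BlocksurvError("target censoring must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise BlocksurvError("baseline hazard must be positive")
        if self.n_factors < 1:
            raise BlocksurvError("at least one latent factor is required")
        if self.n < 2:
            raise BlocksurvError("n must be >= 2")

    @property
    def M(self) -> int:
        return len(self.block_sizes)


def _calibrate_censoring_rate(
    hazard: np.ndarray, target: float, max_steps: int = 100
) -> float:
    """Censoring rate c with mean_i c / (c + lambda_i) = target, by
    bisection on log(c).  P(censored | lambda_i) = c / (c + lambda_i) for
    independent exponential event and censoring times."""

    def frac(logc: float) -> float:
        c = np.exp(logc)
        return float(np.mean(c / (c + hazard)))

    lo, hi = -40.0, 40.0
    if frac(lo) > target or frac(hi) < target:
        raise BlocksurvError("censoring calibration failed: target out of range")
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(frac(mid) - target) > 0.02:
        raise BlocksurvError("censoring calibration did not converge")
    return float(np.exp(mid))


def simulate_blocked_survival(spec: SimSpec) -> BlockedDataset:
    """Generate one data set according to ``spec`` (deterministic given
    ``spec.seed``)."""
    rng = as_generator(spec.seed)
    n, q, M = spec.n, spec.n_factors, spec.M
    loadings = spec.loadings or tuple(1.0 for _ in range(M))

    Z = rng.standard_normal((n, q))
    blocks = []
    eta = np.zeros(n)
    for m in range(M):
        pm = spec.block_sizes[m]
        s = spec.n_informative[m]
        Xm = rng.standard_normal((n, pm))
        if s > 0:
            factors = np.arange(s) % q
            signal = loadings[m] * Z[:, factors]
            Xm[:, :s] += signal
            eta += spec.beta[m] * signal.sum(axis=1)
        blocks.append(Xm)
    X = np.concatenate(blocks, axis=1)

    lam = spec.baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0, size=n) / lam
    if spec.censoring > 0:
        c = _calibrate_censoring_rate(lam, spec.censoring)
        C = rng.exponential(1.0 / c, size=n)
        time = np.minimum(T, C)
        status = (T <= C).astype(np.int8)
    else:
        time = T
        status = np.ones(n, dtype=np.int8)

    structure = BlockStructure.from_sizes(
        spec.block_sizes, spec.block_names, spec.clinical_block
    )
    names = []
    for bname, pm, s in zip(structure.names, spec.block_sizes, spec.n_informative):
        names += [
            f"{bname}_{'inf' if j < s else 'noise'}{j + 1}" for j in range(pm)
        ]
    return BlockedDataset(X, SurvivalOutcome(time, status), structure, tuple(names))


_FIXTURE_SCALES = {
    # block sizes follow the typical multi-omics ordering:
    # clinical < miRNA < mutation < RNA < CNV
    "tiny": dict(n=60, sizes=(5, 15, 40, 60, 80)),
    "small": dict(n=300, sizes=(8, 100, 600, 900, 1400)),
}


def make_multiomics_fixture(scale: str = "tiny", seed: int = 0) -> BlockedDataset:
    """A five-block data set with the canonical multi-omics block roster
    (clinical, miRNA, mutation, RNA, CNV) and size ordering, scaled down
    for tests and demos.  Deterministic given ``scale`` and ``seed``."""
    if scale not in _FIXTURE_SCALES:
        raise BlocksurvError(f"scale must be one of {sorted(_FIXTURE_SCALES)}")
    cfg = _FIXTURE_SCALES[scale]
    sizes = cfg["sizes"]
    spec = SimSpec(
        n=cfg["n"],
        block_sizes=sizes,
        # clinical information is dense; mutation and RNA carry overlapping
        # signal; miRNA and CNV are mostly noise
        n_informative=(2, 1, 4, 4, 2),
        beta=(0.5, 0.1, 0.3, 0.3, 0.1),
        n_factors=2,
        censoring=0.3,
        block_names=("clinical", "mirna", "mutation", "rna", "cnv"),
        clinical_block="clinical",
        seed=seed,
    )
    return simulate_blocked_survival(spec)
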