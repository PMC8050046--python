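"""Colony-screening statistics: library coverage and signal thresholding.

Picking transformant colonies at random from a plated library is modeled as
i.i.d. multinomial sampling of library members (the coupon-collector setting).
Given per-variant abundances this module answers: how many distinct members
does a pick of *n* colonies see in expectation, what is the chance of seeing
them all, and how many picks guarantee full coverage at a target confidence?
It also does the bookkeeping of luminescence-thresholded screening hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .library_design import LibrarySpec, variant_codon_multiplicities

__all__ = [
    "AbundanceModel",
    "CoverageReport",
    "PlateReadout",
    "coverage",
    "draws_for_full_coverage",
    "simulate_coverage",
    "threshold_hits",
    "functional_fraction",
    "DEFAULT_MC_SEED",
    "EXACT_P_FULL_MAX_K",
]

#: Default seed of the optional Monte-Carlo coverage verifier.
DEFAULT_MC_SEED = 20210415

#: Largest k for which p_full uses exact inclusion-exclusion (2^k subset
#: sums for general weights; beyond this the Poissonized product is used).
EXACT_P_FULL_MAX_K = 25


@dataclass(frozen=True)
class AbundanceModel:
    """Relative abundances of the k distinct protein variants of a library."""

    weights: np.ndarray = field(hash=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return int(self.weights.size)

    @classmethod
    def uniform(cls, k: int) -> "AbundanceModel":
        if k < 1:
            raise ValueError("k must be >= 1")
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def codon_weighted(
        cls, specs: "LibrarySpec | Sequence[LibrarySpec]"
    ) -> "AbundanceModel":
        """Weights proportional to per-variant concrete-codon multiplicity.

        For a pool, sublibraries are combined equimolarly: each sublibrary
        receives equal total weight, distributed within it by codon
        multiplicity over its stop-free DNA variants.  (Stop-containing DNA
        variants yield no protein and are excluded before normalization.)
        """
        if isinstance(specs, LibrarySpec):
            specs = [specs]
        if not specs:
            raise ValueError("need at least one spec")
        parts = []
        for spec in specs:
            mult = variant_codon_multiplicities(spec)
            w = np.array(sorted(mult.values()), dtype=float)
            # variants are distinct across sublibraries (different lengths)
            parts.append(w / w.sum() / len(specs))
        return cls(np.concatenate(parts))


@dataclass(frozen=True)
class CoverageReport:
    """Expected coverage of a k-variant library by n random colony picks."""

    n_draws: int
    k: int
    expected_distinct: float
    expected_missing: float
    p_full: float
    p_full_method: str  # "inclusion-exclusion" | "poissonized"


def _p_full_exact(weights: np.ndarray, n: int) -> float:
    """P(all variants seen) by inclusion-exclusion over weight subsets.

    Cost is 2^k; callers gate on k <= EXACT_P_FULL_MAX_K.
    """
    sums = np.zeros(1)
    signs = np.ones(1)
    for w in weights:
        sums = np.concatenate([sums, sums + w])
        signs = np.concatenate([signs, -signs])
    miss = np.clip(1.0 - sums, 0.0, 1.0)
    return float(np.dot(signs, miss**n))


def _p_full_poissonized(weights: np.ndarray, n: int) -> float:
    """Independence (Poissonization) approximation prod_i (1 - (1-w_i)^n)."""
    log_terms = np.log1p(-np.power(1.0 - weights, n))
    return float(np.exp(log_terms.sum()))


def coverage(model: AbundanceModel, n_draws: int) -> CoverageReport:
    """Closed-form coverage of ``model`` after ``n_draws`` i.i.d. picks.

    ``expected_missing`` is the exact sum_i (1 - w_i)^n.  ``p_full`` is exact
    inclusion-exclusion for k <= 25 and the Poissonized product otherwise
    (the report says which); it is pinned to 0 whenever n < k.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    w = model.weights
    expected_missing = float(np.power(1.0 - w, n_draws).sum())
    expected_distinct = model.k - expected_missing
    if n_draws < model.k:
        p_full, method = 0.0, "exact-zero"
    elif model.k <= EXACT_P_FULL_MAX_K:
        p_full = min(1.0, max(0.0, _p_full_exact(w, n_draws)))
        method = "inclusion-exclusion"
    else:
        p_full = _p_full_poissonized(w, n_draws)
        method = "poissonized"
    return CoverageReport(
        n_draws=n_draws,
        k=model.k,
        expected_distinct=expected_distinct,
        expected_missing=expected_missing,
        p_full=p_full,
        p_full_method=method,
    )


def draws_for_full_coverage(model: AbundanceModel, p_target: float) -> int:
    """Smallest n with p_full(n) >= p_target, by bisection (p_full is monotone)."""
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must lie strictly between 0 and 1")
    lo, hi = model.k, max(2 * model.k, 2)
    while coverage(model, hi).p_full < p_target:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if coverage(model, mid).p_full >= p_target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def simulate_coverage(
    model: AbundanceModel,
    n_draws: int,
    replicates: int = 10_000,
    seed: int = DEFAULT_MC_SEED,
) -> Tuple[float, float]:
    """Monte-Carlo cross-check of coverage: (mean, SE) of distinct counts."""
    rng = np.random.default_rng(seed)
    distinct = np.empty(replicates, dtype=np.int64)
    chunk = max(1, min(replicates, int(5e7 // max(model.k, 1))))
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        counts = rng.multinomial(n_draws, model.weights, size=m)
        distinct[done : done + m] = np.count_nonzero(counts, axis=1)
        done += m
    mean = float(distinct.mean())
    se = float(distinct.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
    return mean, se


# ---------------------------------------------------------------------------
# plate readouts


@dataclass(frozen=True)
class PlateReadout:
    """Per-well luminescence (RLU) plus the plate's background statistics."""

    rlu: np.ndarray = field(hash=False)
    background_mean: float = 0.0
    background_sd: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.rlu, dtype=float)
        if values.ndim != 1:
            raise ValueError("rlu must be a 1-D vector of well readings")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("RLU values must be finite and non-negative")
        if not (math.isfinite(self.background_mean) and math.isfinite(self.background_sd)):
            raise ValueError("background statistics must be finite")
        object.__setattr__(self, "rlu", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"well": np.arange(self.rlu.size), "rlu": self.rlu})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "PlateReadout":
        return cls(rlu=frame["rlu"].to_numpy(dtype=float), **kwargs)


def threshold_hits(plate: PlateReadout, threshold: float) -> List[Tuple[int, float]]:
    """Wells strictly above ``threshold``, as (well index, RLU) pairs.

    Sorted by descending RLU with ties broken by ascending well index; an
    empty readout yields an empty list.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = [(i, float(v)) for i, v in enumerate(plate.rlu) if v > threshold]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return hits


def functional_fraction(n_nns_codons: int) -> float:
    """Stop-free fraction (31/32)^n of DNA variants carrying n NNS codons.

    NNS encodes exactly one stop (TAG) among its 32 concrete codons.
    """
    if n_nns_codons < 0:
        raise ValueError("codon count must be >= 0")
    return (31.0 / 32.0) ** n_nns_codons
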