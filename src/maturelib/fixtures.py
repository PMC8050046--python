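"""Seeded synthetic-data generators emulating the screening and assay data.

These generators make every analytic module testable without instrument
files: clonal-array plate readouts (background luminescence plus planted
high-signal clones), competitive-ELISA dose-response tables from a known 4PL
curve, and Scatchard bound/free tables from single-site mass action at a
known K_a.  All are pure functions of their configuration and seed.

Defaults mirror the screening campaign they emulate: 96-well plates with 94
colony wells and 2 background wells, a background RLU of 2758 +/- 1909
(substitution-library plates), a 100,000-RLU hit threshold, four replicates
per ELISA dose, and a wild-type midpoint of 706 pg/assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .binding import DoseResponseDataset, ScatchardDataset
from .screening_stats import PlateReadout

__all__ = [
    "PlateConfig",
    "DoseResponseConfig",
    "ScatchardConfig",
    "generate_plate",
    "generate_doseresponse",
    "generate_scatchard",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20210415


@dataclass(frozen=True)
class PlateConfig:
    """One screening microplate: 94 colony wells + 2 background wells.

    Background RLU is drawn from a normal truncated at zero (reported
    dispersions are of the same order as the means, so negative luminescence
    must be cut off).  Positives are planted at a fixed signal level.
    """

    n_colony_wells: int = 94
    n_background_wells: int = 2
    background_mean: float = 2758.0
    background_sd: float = 1909.0
    n_positives: int = 0
    positive_rlu: float = 500_000.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_colony_wells < self.n_positives:
            raise ValueError("cannot plant more positives than colony wells")
        if self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("background statistics must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) conditioned on >= 0, by resampling."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))


def generate_plate(config: PlateConfig = PlateConfig()) -> PlateReadout:
    """Simulate one plate readout; deterministic for a given config and seed.

    The first ``n_positives`` colony wells carry the planted signal on top of
    background; the trailing ``n_background_wells`` wells are pure background
    and define the plate's background statistics.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_colony_wells + config.n_background_wells
    rlu = _truncated_normal(rng, config.background_mean, config.background_sd,
                            n_total)
    rlu[: config.n_positives] += config.positive_rlu
    background = rlu[config.n_colony_wells:]
    return PlateReadout(
        rlu=rlu,
        background_mean=float(background.mean()),
        background_sd=float(background.std(ddof=1)) if background.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class DoseResponseConfig:
    """A competitive-ELISA curve sampled at log-spaced doses.

    Responses follow a 4PL with multiplicative Gaussian noise of coefficient
    of variation ``cv``; ten zero-dose (B0) wells anchor normalization, with
    their own CV (``b0_cv``, defaulting to ``cv``).
    """

    midpoint: float = 706.0
    top: float = 100.0
    bottom: float = 0.0
    slope: float = 1.0
    dose_min: float = 1.0
    dose_max: float = 100_000.0
    n_doses: int = 8
    replicates: int = 4
    n_b0: int = 10
    cv: float = 0.0
    b0_cv: Optional[float] = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.midpoint <= 0 or self.top <= self.bottom:
            raise ValueError("need midpoint > 0 and top > bottom")
        if self.n_doses < 4:
            raise ValueError("need >= 4 doses")
        if self.cv < 0 or (self.b0_cv is not None and self.b0_cv < 0):
            raise ValueError("noise CV must be non-negative")


def generate_doseresponse(
    config: DoseResponseConfig = DoseResponseConfig(),
) -> DoseResponseDataset:
    """Sample a dose-response table (responses on the B/B0-like raw scale).

    With ``cv=0`` the output is noise-free and seed-independent.  Zero-dose
    wells are generated at the ``top`` level so that normalization against
    their mean reproduces the configured curve.
    """
    rng = np.random.default_rng(config.seed)
    doses = np.geomspace(config.dose_min, config.dose_max, config.n_doses)
    doses = np.repeat(doses, config.replicates)
    clean = config.bottom + (config.top - config.bottom) / (
        1.0 + (doses / config.midpoint) ** config.slope
    )
    b0_cv = config.cv if config.b0_cv is None else config.b0_cv
    b0 = np.full(config.n_b0, config.top)
    if b0_cv > 0:
        b0 = b0 * (1.0 + b0_cv * rng.standard_normal(config.n_b0))
    if config.cv > 0:
        clean = clean * (1.0 + config.cv * rng.standard_normal(clean.size))
    return DoseResponseDataset(
        doses=np.concatenate([np.zeros(config.n_b0), doses]),
        responses=np.concatenate([b0, clean]),
        normalized=False,
    )


@dataclass(frozen=True)
class ScatchardConfig:
    """Single-site mass-action binding sampled across free-tracer levels.

    ``ka`` is the association constant (M^-1); ``sites_total`` the binding
    site concentration (M).  Free concentrations are log-spaced around 1/K_a
    so bound/free varies over the informative range.  Noise is multiplicative
    Gaussian on the bound values.
    """

    ka: float = 3.6e8
    sites_total: float = 1e-9
    n_points: int = 6
    span_decades: float = 1.5
    cv: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.sites_total <= 0:
            raise ValueError("ka and sites_total must be positive")
        if self.n_points < 3:
            raise ValueError("need >= 3 points")
        if self.cv < 0:
            raise ValueError("noise CV must be non-negative")


def generate_scatchard(
    config: ScatchardConfig = ScatchardConfig(),
) -> ScatchardDataset:
    """Sample bound/free pairs: B = K_a F R_t / (1 + K_a F), plus noise."""
    rng = np.random.default_rng(config.seed)
    half = config.span_decades / 2.0
    free = np.geomspace(10.0**-half, 10.0**half, config.n_points) / config.ka
    bound = config.ka * free * config.sites_total / (1.0 + config.ka * free)
    if config.cv > 0:
        bound = bound * (1.0 + config.cv * rng.standard_normal(bound.size))
        bound = np.clip(bound, 1e-30, None)
    return ScatchardDataset(bound=bound, free=free)
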