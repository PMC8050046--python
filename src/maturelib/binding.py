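"""Binding characterization arithmetic for ranking affinity-matured scFvs.

Covers the quantitative toolchain of a competitive hapten ELISA and a
radioligand equilibrium assay:

* four-parameter-logistic (4PL) fitting of dose-response curves
  [log(analyte dose) vs B/B0 %] with midpoint (IC50) extraction;
* limit of detection as the dose whose signal equals the zero-dose mean minus
  two standard deviations;
* cross-reactivity as the IC50 ratio analyte/analog, in percent;
* the assay unit conversions between pg/assay, in-well pg/mL and pmol/L, and
  serum-equivalent ng/mL;
* Scatchard estimation of the equilibrium association constant K_a
  (bound/free vs bound regression, K_a = -slope) and fold-improvement display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CORTISOL_MOLAR_MASS",
    "DoseResponseDataset",
    "FourPLFit",
    "AssayConfig",
    "UnitConversion",
    "ScatchardDataset",
    "AffinityResult",
    "LodResult",
    "FoldResult",
    "DegenerateDataError",
    "fit_4pl",
    "lod",
    "cross_reactivity",
    "convert_units",
    "scatchard_ka",
    "fold_improvement",
]

#: Molar mass of cortisol (g/mol).
CORTISOL_MOLAR_MASS = 362.46


class DegenerateDataError(ValueError):
    """The data carry no dose-response information (e.g. all-equal responses)."""


@dataclass(frozen=True)
class DoseResponseDataset:
    """Competitive-ELISA dose-response table.

    ``doses`` are analyte amounts in pg/assay (zero allowed, marking B0
    wells); ``responses`` are bound signals, either raw (normalized internally
    against the zero-dose mean) or already expressed as B/B0 %.
    """

    doses: np.ndarray = field(hash=False)
    responses: np.ndarray = field(hash=False)
    normalized: bool = False  # True when responses are already B/B0 %

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("doses and responses must be equal-length vectors")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if len(set(d[d > 0])) < 4:
            raise ValueError("need >= 4 distinct non-zero doses for fitting")
        if not self.normalized and not np.any(d == 0):
            raise ValueError("raw responses need >= 1 zero-dose (B0) well")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)

    def b0_responses(self) -> np.ndarray:
        return self.responses[self.doses == 0]

    def percent_b_b0(self, background: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
        """(non-zero doses, responses as B/B0 %) after background subtraction."""
        mask = self.doses > 0
        if self.normalized:
            return self.doses[mask], self.responses[mask]
        b0 = float(self.b0_responses().mean()) - background
        if b0 <= 0:
            raise DegenerateDataError("zero-dose mean does not exceed background")
        return self.doses[mask], 100.0 * (self.responses[mask] - background) / b0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_pg_per_assay": self.doses, "response": self.responses}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = False
                   ) -> "DoseResponseDataset":
        return cls(
            doses=frame["dose_pg_per_assay"].to_numpy(dtype=float),
            responses=frame["response"].to_numpy(dtype=float),
            normalized=normalized,
        )


@dataclass(frozen=True)
class FourPLFit:
    """A fitted four-parameter logistic curve.

    ``midpoint`` is the IC50 in pg/assay.  ``slope`` follows the convention
    that a positive slope gives a response decreasing in dose (competitive
    displacement).
    """

    top: float
    bottom: float
    midpoint: float
    slope: float
    residual_rms: float
    converged: bool
    message: str = ""
    n_points: int = 0

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, dose / self.midpoint, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio**self.slope)

    def invert(self, response: float) -> float:
        """Dose producing ``response``; raises when outside (bottom, top)."""
        if not (min(self.bottom, self.top) < response < max(self.bottom, self.top)):
            raise ValueError(
                f"response {response} outside the fitted range "
                f"({self.bottom:.3g}, {self.top:.3g})"
            )
        return self.midpoint * ((self.top - self.bottom) / (response - self.bottom)
                                - 1.0) ** (1.0 / self.slope)


def _four_pl(log_dose, top, bottom, log_mid, slope):
    return bottom + (top - bottom) / (1.0 + np.exp(slope * (log_dose - log_mid)))


def fit_4pl(data: DoseResponseDataset, background: float = 0.0) -> FourPLFit:
    """Least-squares 4PL fit of B/B0 % against log dose.

    Responses are normalized to B/B0 % with the zero-dose mean (unless the
    dataset is already normalized).  Damped least squares (Levenberg-
    Marquardt) with quantile-based initialization: top = max response,
    bottom = min, midpoint = dose nearest the half-response, slope = 1.
    Non-convergence is flagged on the result, never silent.
    """
    doses, resp = data.percent_b_b0(background)
    if np.allclose(resp, resp[0]):
        raise DegenerateDataError("all responses equal; no curve to fit")
    log_dose = np.log(doses)
    top0, bottom0 = float(resp.max()), float(resp.min())
    half = (top0 + bottom0) / 2.0
    mid0 = float(log_dose[np.argmin(np.abs(resp - half))])
    p0 = (top0, bottom0, mid0, 1.0)
    try:
        with warnings.catch_warnings():
            # noiseless data fits perfectly; the unused covariance is singular
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            params, _, info, message, status = optimize.curve_fit(
                _four_pl, log_dose, resp, p0=p0, method="lm",
                maxfev=500 * (len(p0) + 1), xtol=1e-10, ftol=1e-10,
                full_output=True,
            )
        converged = status in (1, 2, 3, 4)
    except RuntimeError as err:  # exceeded maxfev without converging
        params, converged, message = p0, False, str(err)
        info = {"fvec": _four_pl(log_dose, *p0) - resp}
    top, bottom, log_mid, slope = (float(v) for v in params)
    if slope < 0:  # equivalent curve with the competitive-orientation sign
        top, bottom, slope = bottom, top, -slope
    rms = float(np.sqrt(np.mean(np.square(info["fvec"]))))
    return FourPLFit(
        top=top, bottom=bottom, midpoint=float(np.exp(log_mid)), slope=slope,
        residual_rms=rms, converged=converged, message=str(message),
        n_points=len(resp),
    )


@dataclass(frozen=True)
class LodResult:
    """Limit of detection in pg/assay, or flagged undefined."""

    dose: Optional[float]
    threshold_percent: float
    defined: bool
    note: str = ""


def lod(data: DoseResponseDataset, fit: FourPLFit,
        background: float = 0.0) -> LodResult:
    """LOD: the dose whose fitted signal is 2 SD below the zero-dose mean.

    Zero-dose replicates are expressed on the same B/B0 % scale as the fit.
    With zero B0 variance the rule degenerates to the dose where the curve
    first drops below the B0 mean (dose 0 when the mean is at/above the
    fitted top).  A threshold below the fitted bottom is flagged undefined.
    """
    b0 = data.b0_responses()
    if b0.size < 2:
        raise ValueError("need >= 2 zero-dose replicates for an LOD")
    if data.normalized:
        b0_pct = b0
    else:
        mean_raw = float(b0.mean()) - background
        if mean_raw <= 0:
            raise DegenerateDataError("zero-dose mean does not exceed background")
        b0_pct = 100.0 * (b0 - background) / mean_raw
    threshold = float(b0_pct.mean() - 2.0 * b0_pct.std(ddof=1))
    hi, lo = max(fit.top, fit.bottom), min(fit.top, fit.bottom)
    if threshold >= hi:
        return LodResult(dose=0.0, threshold_percent=threshold, defined=True,
                         note="threshold at or above the fitted top; LOD -> 0")
    if threshold <= lo:
        return LodResult(dose=None, threshold_percent=threshold, defined=False,
                         note="threshold below the fitted bottom")
    return LodResult(dose=float(fit.invert(threshold)),
                     threshold_percent=threshold, defined=True)


def cross_reactivity(midpoint_analyte: float, midpoint_analog: float) -> float:
    """Cross-reactivity % = 100 x IC50(analyte) / IC50(analog)."""
    if midpoint_analyte <= 0 or midpoint_analog <= 0:
        raise ValueError("midpoints must be positive")
    return 100.0 * midpoint_analyte / midpoint_analog


@dataclass(frozen=True)
class AssayConfig:
    """Volumes and constants tying pg/assay to concentrations.

    ``total_volume_ul`` is the final incubation volume (the pg/assay amount
    is dissolved in it); ``standard_volume_ul`` is the analyte-standard
    aliquot, the basis of serum-equivalent concentrations together with the
    specimen ``dilution_factor``.
    """

    total_volume_ul: float = 150.0
    standard_volume_ul: float = 50.0
    dilution_factor: float = 10.0
    analyte_molar_mass: float = CORTISOL_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.total_volume_ul <= 0 or self.standard_volume_ul <= 0:
            raise ValueError("volumes must be positive")
        if self.standard_volume_ul > self.total_volume_ul:
            raise ValueError("standard volume cannot exceed total volume")
        if self.analyte_molar_mass <= 0 or self.dilution_factor <= 0:
            raise ValueError("molar mass and dilution factor must be positive")


@dataclass(frozen=True)
class UnitConversion:
    """pg/assay re-expressed as in-well and serum-equivalent concentrations."""

    pg_per_assay: float
    pg_per_ml: float
    pmol_per_l: float
    serum_ng_per_ml: float


def convert_units(amount_pg_per_assay: float,
                  config: AssayConfig = AssayConfig()) -> UnitConversion:
    """Convert a pg/assay amount to concentrations.

    * in-well pg/mL: amount / total volume (mL);
    * in-well pmol/L: pg/mL / molar mass (g/mol) x 1000;
    * serum-equivalent ng/mL: amount / standard volume (mL) x dilution / 1000
      (the concentration a specimen must have had before dilution for its
      aliquot to carry this amount).
    """
    if amount_pg_per_assay < 0:
        raise ValueError("amount must be non-negative")
    pg_per_ml = amount_pg_per_assay / (config.total_volume_ul / 1000.0)
    pmol_per_l = pg_per_ml / config.analyte_molar_mass * 1000.0
    serum = (amount_pg_per_assay / (config.standard_volume_ul / 1000.0)
             * config.dilution_factor / 1000.0)
    return UnitConversion(
        pg_per_assay=amount_pg_per_assay,
        pg_per_ml=pg_per_ml,
        pmol_per_l=pmol_per_l,
        serum_ng_per_ml=serum,
    )


# ---------------------------------------------------------------------------
# Scatchard analysis


@dataclass(frozen=True)
class ScatchardDataset:
    """Bound and free tracer concentrations (consistent molar units)."""

    bound: np.ndarray = field(hash=False)
    free: np.ndarray = field(hash=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.bound, dtype=float)
        f = np.asarray(self.free, dtype=float)
        if b.shape != f.shape or b.ndim != 1:
            raise ValueError("bound and free must be equal-length vectors")
        if b.size < 3:
            raise ValueError("Scatchard analysis needs >= 3 points")
        if np.any(b <= 0) or np.any(f <= 0):
            raise ValueError("bound and free must be strictly positive")
        object.__setattr__(self, "bound", b)
        object.__setattr__(self, "free", f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bound": self.bound, "free": self.free})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScatchardDataset":
        return cls(bound=frame["bound"].to_numpy(dtype=float),
                   free=frame["free"].to_numpy(dtype=float))


@dataclass(frozen=True)
class AffinityResult:
    """Equilibrium association constant estimate from a Scatchard plot."""

    ka: float  # M^-1; NaN when the fit is invalid
    sites_total: float  # x-intercept estimate of total binding sites
    r_squared: float
    valid: bool
    note: str = ""


def scatchard_ka(data: ScatchardDataset) -> AffinityResult:
    """OLS of bound/free against bound; K_a = -slope (M^-1).

    Single-site mass action gives B/F = K_a (R_t - B), a line of slope -K_a
    and x-intercept R_t.  A non-negative slope (no displacement signal) is
    flagged invalid rather than raised.
    """
    ratio = data.bound / data.free
    fit = stats.linregress(data.bound, ratio)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    if slope >= 0:
        return AffinityResult(ka=float("nan"), sites_total=float("nan"),
                              r_squared=r2, valid=False,
                              note="non-negative Scatchard slope")
    ka = -slope
    return AffinityResult(ka=ka, sites_total=intercept / ka, r_squared=r2,
                          valid=True)


@dataclass(frozen=True)
class FoldResult:
    """Affinity or sensitivity improvement ratio plus its display form."""

    ratio: float
    display: int  # nearest integer, half away from zero

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.display}-fold"


def fold_improvement(value_mutant: float, value_reference: float) -> FoldResult:
    """Ratio mutant/reference; display rounds half away from zero.

    Used both for K_a fold-increases and for midpoint (sensitivity) folds.
    """
    if value_mutant <= 0 or value_reference <= 0:
        raise ValueError("both values must be positive")
    ratio = value_mutant / value_reference
    display = int(math.floor(ratio + 0.5))
    return FoldResult(ratio=ratio, display=display)
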