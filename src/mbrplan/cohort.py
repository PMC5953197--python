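"""Cohort-level statistics: dose-variability measures, correlations, fits.

Quantifies how the spread of absorbed doses across a patient's lesions
drives the dose needed for metastatic control: variability measures per
patient, Pearson correlation between planning outputs and those measures,
power-law / linear regression with 95% mean-response confidence bands,
and median/IQR summaries of a cohort's planning results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .burden import PlanningResult
from .errors import ValidationError

__all__ = [
    "VariabilityRecord",
    "CohortSummary",
    "FitResult",
    "variability_measures",
    "pearson_r",
    "fit_relationship",
    "summarize_cohort",
]


@dataclass(frozen=True)
class VariabilityRecord:
    """Measures of spread of one patient's lesion absorbed doses.

    ``range = max - min``; ``cv = sd / mean``; ``max_min_ratio = max/min``
    and ``range_over_min = (max - min)/min = max_min_ratio - 1`` require a
    strictly positive minimum and are NaN (with ``ratio_defined=False``)
    otherwise. Sample (n-1) variance; a single dose has variance 0.
    """

    patient_id: str
    n: int
    min_dose: float
    max_dose: float
    range: float
    variance: float
    sd: float
    cv: float
    range_over_min: float
    max_min_ratio: float
    ratio_defined: bool = True


def variability_measures(doses: Sequence[float], patient_id: str = "") -> VariabilityRecord:
    """Compute all dose-variability measures for one patient."""
    d = np.asarray(list(doses), dtype=float)
    if d.size == 0:
        raise ValidationError("at least one dose is required")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValidationError("doses must be finite and non-negative")
    dmin = float(d.min())
    dmax = float(d.max())
    variance = float(d.var(ddof=1)) if d.size > 1 else 0.0
    sd = math.sqrt(variance)
    mean = float(d.mean())
    cv = sd / mean if mean > 0 else 0.0
    if dmin > 0:
        ratio = dmax / dmin
        return VariabilityRecord(patient_id, d.size, dmin, dmax, dmax - dmin,
                                 variance, sd, cv, ratio - 1.0, ratio, True)
    return VariabilityRecord(patient_id, d.size, dmin, dmax, dmax - dmin,
                             variance, sd, cv, math.nan, math.nan, False)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient with a two-sided p-value.

    The p-value is from the exact t-transform ``t = r*sqrt(n-2)/sqrt(1-r^2)``
    on n-2 degrees of freedom. Requires n >= 3 and non-constant inputs.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d sequences")
    if xa.size < 3:
        raise ValidationError("at least 3 observations are required")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValidationError("correlation is undefined for constant input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of y on x, linear or power-law.

    For ``form='linear'`` the model is ``y = intercept + slope*x``; for
    ``form='power'`` it is ``y = amplitude * x**exponent``, fitted by OLS
    on (ln x, ln y). ``r`` is the Pearson correlation on the fitted scale
    (log-log for the power form). ``band_halfwidth`` gives 95% confidence
    half-widths for the mean response at each input x, on the fitted scale.
    """

    form: str
    coefficients: dict[str, float]
    r: float
    p_value: float
    band_halfwidth: np.ndarray

    def predict(self, x) -> np.ndarray:
        xa = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c["intercept"] + c["slope"] * xa
        return c["amplitude"] * xa ** c["exponent"]


def fit_relationship(x: Sequence[float], y: Sequence[float],
                     form: str = "linear") -> FitResult:
    """Fit a linear or power-law relationship with 95% confidence bands."""
    if form not in ("linear", "power"):
        raise ValidationError(f"form must be 'linear' or 'power', got {form!r}")
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValidationError("x and y must be equal-length sequences of length >= 3")
    if form == "power":
        if np.any(xa <= 0) or np.any(ya <= 0):
            raise ValidationError("power-law fit requires strictly positive x and y")
        fx, fy = np.log(xa), np.log(ya)
    else:
        fx, fy = xa, ya

    model = sm.OLS(fy, sm.add_constant(fx)).fit()
    ci = model.get_prediction(sm.add_constant(fx)).conf_int(alpha=0.05)
    half = (ci[:, 1] - ci[:, 0]) / 2.0
    r, p = pearson_r(fx, fy)

    b0, b1 = model.params
    if form == "power":
        coeff = {"amplitude": float(np.exp(b0)), "exponent": float(b1)}
    else:
        coeff = {"intercept": float(b0), "slope": float(b1)}
    return FitResult(form, coeff, r, p, half)


@dataclass(frozen=True)
class CohortSummary:
    """Median and IQR of the cohort's delivered and planned PMADs."""

    table: pd.DataFrame
    median_pmad_delivered: float
    iqr_pmad_delivered: tuple[float, float]
    median_pmad_mcp: float
    iqr_pmad_mcp: tuple[float, float]
    median_pmad_mbr: float
    iqr_pmad_mbr: tuple[float, float]


def _median_iqr(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return math.nan, (math.nan, math.nan)
    q1, med, q3 = np.quantile(finite, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), (float(q1), float(q3))


def summarize_cohort(results: Iterable[PlanningResult]) -> CohortSummary:
    """Median/IQR summary of per-patient planning results.

    Quantiles use linear interpolation between order statistics; the table
    is ordered by patient id; non-finite (unreachable-target) values are
    excluded from the summaries but kept in the table with their flags.
    """
    rows = sorted(results, key=lambda r: r.patient_id)
    if not rows:
        raise ValidationError("at least one planning result is required")
    table = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "pmad_delivered_gy": [r.pmad_delivered for r in rows],
            "pmad_mcp_gy": [r.pmad_mcp for r in rows],
            "pmad_mbr_gy": [r.pmad_mbr for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )
    med_del, iqr_del = _median_iqr(table["pmad_delivered_gy"].to_numpy())
    med_mcp, iqr_mcp = _median_iqr(table["pmad_mcp_gy"].to_numpy())
    med_mbr, iqr_mbr = _median_iqr(table["pmad_mbr_gy"].to_numpy())
    return CohortSummary(table, med_del, iqr_del, med_mcp, iqr_mcp, med_mbr, iqr_mbr)
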