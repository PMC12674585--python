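"""Chemometric model-evaluation metrics.

The suite computed for every calibration/validation partition:

* ``r`` — Pearson correlation between observed and predicted values;
* ``r2`` — by default the square of Pearson r (the convention matching
  reported R/R2 pairs such as 0.97/0.94); the 1 - SSE/SST definition is
  available via ``r2_method="explained_variance"``;
* ``rmse`` — root mean squared error, in trait-percent units;
* ``bias_additive`` — mean(predicted - observed). "Bias" is ambiguous in
  chemometric reporting: calibration biases often quoted near 1 are
  slope-like, validation biases near 0 are additive. Both candidates are
  therefore computed: this additive one, and ``slope``;
* ``slope`` — OLS slope of predicted on observed (the slope-like bias);
* ``rpd`` — sd(observed, n-1 denominator) / rmse;
* ``rpiq`` — (Q3 - Q1 of observed, type-7 interpolation) / rmse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DegenerateInputError, SizingError

RPD_CUTS = (1.5, 2.0, 3.0)


@dataclass(frozen=True)
class MetricSet:
    r: float
    r2: float
    rmse: float
    bias_additive: float
    slope: float
    rpd: float
    rpiq: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    observed, predicted, r2_method: str = "pearson_squared"
) -> MetricSet:
    """Evaluate predictions against reference values.

    Raises on zero observed variance (correlation undefined); a perfect fit
    (rmse = 0) reports infinite RPD/RPIQ with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise SizingError("observed and predicted must be equal-length vectors")
    n = obs.size
    if n < 2:
        raise SizingError("need at least 2 observations")
    obs_c = obs - obs.mean()
    sxx = float(obs_c @ obs_c)
    if sxx == 0:
        raise DegenerateInputError("observed values have zero variance")
    pred_c = pred - pred.mean()
    sxy = float(obs_c @ pred_c)
    syy = float(pred_c @ pred_c)
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    if r2_method == "pearson_squared":
        r2 = r * r
    elif r2_method == "explained_variance":
        sse = float(((obs - pred) ** 2).sum())
        r2 = 1.0 - sse / sxx
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    rmse = math.sqrt(float(((pred - obs) ** 2).mean()))
    bias = float((pred - obs).mean())
    slope = sxy / sxx
    sd_obs = math.sqrt(sxx / (n - 1))
    iqr = float(np.percentile(obs, 75) - np.percentile(obs, 25))
    if rmse == 0:
        warnings.warn("rmse is zero; RPD/RPIQ reported as +inf")
        rpd = rpiq = math.inf
    else:
        rpd = sd_obs / rmse
        rpiq = iqr / rmse
    return MetricSet(
        r=r, r2=r2, rmse=rmse, bias_additive=bias, slope=slope,
        rpd=rpd, rpiq=rpiq, n=n,
    )


def interpret_rpd(rpd: float, cuts: tuple = RPD_CUTS) -> str:
    """Qualitative RPD category at left-closed cut points (reporting aid)."""
    lo, mid, hi = cuts
    if rpd < lo:
        return "poor"
    if rpd < mid:
        return "fair"
    if rpd < hi:
        return "good"
    return "excellent"
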