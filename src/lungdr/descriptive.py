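"""Univariable descriptive analyses of cohort tables.

Patient-number-weighted least-squares gradients with F-tests (for OS
against dose, dose-per-fraction or duration, and for calibration of
predicted against observed survival) and Wilcoxon rank-sum comparisons of
schedule characteristics between cohort groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohorts import Cohort
from .exceptions import LungDRError
from .fitting import OSModel, OSResults


@dataclass(frozen=True)
class WeightedFit:
    """Patient-weighted least-squares line with an F-test on the slope."""

    slope: float
    intercept: float
    slope_p_value: float
    f_statistic: float
    n: int


def weighted_linear_fit(x: Sequence[float], y: Sequence[float],
                        w: Sequence[float]) -> WeightedFit:
    """Weighted least-squares line of y on x.

    Weights are patient numbers (any positive rescaling gives the same
    fit).  The slope's significance is the F-test of the single regressor,
    i.e. the square of its t-statistic on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) < 3:
        raise LungDRError(f"need at least 3 points, got {len(x)}")
    if np.any(w <= 0):
        raise LungDRError("weights must be positive")
    if np.ptp(x) == 0:
        raise LungDRError("zero variance in x: slope undefined")
    if np.ptp(y) == 0:  # flat response: slope exactly 0, nothing to test
        return WeightedFit(slope=0.0, intercept=float(y[0]),
                           slope_p_value=1.0, f_statistic=0.0, n=len(x))
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    t = res.tvalues[1]
    if not np.isfinite(t):  # e.g. identical y: zero residual and zero slope
        return WeightedFit(slope=float(res.params[1]),
                           intercept=float(res.params[0]),
                           slope_p_value=1.0, f_statistic=0.0, n=len(x))
    f = float(t ** 2)
    p = float(stats.f.sf(f, 1, len(x) - 2))
    return WeightedFit(slope=float(res.params[1]),
                       intercept=float(res.params[0]),
                       slope_p_value=p, f_statistic=f, n=len(x))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    normal approximation with midrank tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise LungDRError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
        correction = False
    else:
        method = "asymptotic"
        correction = True
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=correction)
    return float(min(res.pvalue, 1.0))


def calibration_table(cohorts: Sequence[Cohort],
                      fits: Sequence[OSResults]) -> pd.DataFrame:
    """Predicted vs observed OS per cohort for each fitted model.

    Long-format table with one row per (model, cohort): observed and
    predicted OS%, patient weight, and the model's weighted calibration
    line (observed regressed on predicted) with its residual weighted MSE.
    A perfectly calibrated model has slope 1 and intercept 0.  Models for
    which the calibration slope is undefined (constant predictions) carry
    the error message instead of slope columns.
    """
    obs = np.array([c.os2_observed for c in cohorts])
    w = np.array([c.n_patients for c in cohorts], dtype=float)
    frames = []
    for fit in fits:
        pred = 100.0 * OSModel(cohorts, fit.spec).predict_from_values(fit.values)
        frame = pd.DataFrame({
            "model": fit.spec.name,
            "cohort_id": [c.id for c in cohorts],
            "n_patients": w.astype(int),
            "observed_os_pct": obs,
            "predicted_os_pct": pred,
        })
        try:
            line = weighted_linear_fit(pred, obs, w)
            frame["calib_slope"] = line.slope
            frame["calib_intercept"] = line.intercept
            frame["calib_slope_p"] = line.slope_p_value
            frame["calib_error"] = ""
        except LungDRError as exc:
            frame["calib_slope"] = np.nan
            frame["calib_intercept"] = np.nan
            frame["calib_slope_p"] = np.nan
            frame["calib_error"] = str(exc)
        frame["weighted_mse"] = float(np.sum(w * (obs - pred) ** 2) / np.sum(w))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
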