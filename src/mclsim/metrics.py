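"""Evaluation statistics and the standardized water stress index (sWSI).

RMSE, mean residual error (a signed percentage), weighted RMSE, the
coefficient of variation, and the sWSI — the z-score of growing-season
transpiration minus precipitation (WS = Ta - p, mm yr-1), positive in
drier-than-average years.  The weighted RMSE is reported with the square
root applied so it carries the data's units (kg ha-1 for yields); passing
``apply_root=False`` gives the plain weighted mean of squared errors.

Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class DegenerateSeriesError(ValueError):
    """A statistic is undefined for this input (zero spread or zero mean)."""


def _pair(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 1:
        raise ValueError("need at least one pair")
    return p, o


def rmse(predicted, observed) -> float:
    """Root mean squared error, in the data's units."""
    p, o = _pair(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mean_residual_error(simulated: float, observed: float) -> float:
    """Signed percentage difference (S - O) / O * 100."""
    if observed == 0:
        raise DegenerateSeriesError("mean residual error undefined for O = 0")
    return (simulated - observed) / observed * 100.0


def wrmse(predicted, observed, weights, *, apply_root: bool = True) -> float:
    """Weighted RMSE: sqrt(sum w_i (P_i - O_i)^2 / sum w_i).

    With ``apply_root=False`` the square root is omitted and the statistic is
    the weighted mean of squared errors (squared units).
    """
    p, o = _pair(predicted, observed)
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights must match the data length")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    value = float(np.sum(w * (p - o) ** 2) / np.sum(w))
    return float(np.sqrt(value)) if apply_root else value


def cv(series) -> float:
    """Coefficient of variation in percent: sample sd / mean * 100."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("cv needs at least two values")
    m = x.mean()
    if m == 0:
        raise DegenerateSeriesError("cv undefined for zero mean")
    return float(x.std(ddof=1) / m * 100.0)


def swsi(annual_ta, annual_p) -> np.ndarray:
    """Standardized water stress index per year.

    WS_t = Ta_t - p_t (growing-season transpiration minus precipitation,
    mm yr-1); sWSI_t = (WS_t - mean(WS)) / sd(WS) over the baseline years.
    Positive values mark drier-than-average (higher-stress) years.
    """
    ta = np.asarray(annual_ta, dtype=float)
    p = np.asarray(annual_p, dtype=float)
    if ta.shape != p.shape:
        raise ValueError("Ta and p must have equal length")
    if ta.size < 2:
        raise ValueError("sWSI needs at least two years")
    ws = ta - p
    sd = ws.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("sWSI undefined: zero interannual WS spread")
    return (ws - ws.mean()) / sd


def correlate_with_swsi(outcome, swsi_series) -> tuple[float, float, bool]:
    """Pearson correlation of an annual outcome with the sWSI.

    Returns (r, two-sided p from the t distribution with n-2 df, p < 0.05).
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(swsi_series, dtype=float)
    if y.shape != s.shape:
        raise ValueError("series must have equal length")
    if y.size < 3:
        raise ValueError("correlation needs at least three years")
    if y.std() == 0 or s.std() == 0:
        raise DegenerateSeriesError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(y, s)
    return float(r), float(p), bool(p < 0.05)
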