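"""Growth-parameter extraction from OD600 time series.

Four parameters summarize a 24-h plate-reader curve sampled every 4 minutes:

* **max_rate** — largest OLS slope of ln(OD) over a 15-point (1 h) sliding
  window, in h^-1;
* **lag** — time coordinate where the line fitted to the first 15 ln(OD)
  points meets the maximum-rate line;
* **auc** — trapezoidal integral of ln(OD) over time with the rectangle
  under the smallest measured ln(OD) removed;
* **capacity** — highest OD reached within the recording window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "max_growth_rate",
    "lag_time",
    "auc",
    "carrying_capacity",
    "fit_growth",
]

DEFAULT_WINDOW = 15  # points; 1 h at the 4-min sampling interval


@dataclass
class GrowthCurve:
    """One well's OD600 trace; times in hours, strictly increasing, OD > 0."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("od values must be positive (blank-corrected, floored)")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GrowthParams:
    """The four growth parameters plus bookkeeping for the fitted windows."""

    max_rate: float
    rate_window_start: int
    lag: float
    lag_defined: bool
    auc: float
    capacity: float
    lag_suspicious: bool = False


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y on t in every contiguous window, via cumulative sums."""
    n = len(t)
    k = window
    ct, cy = np.concatenate([[0.0], np.cumsum(t)]), np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    i = np.arange(n - k + 1)
    st, sy = ct[i + k] - ct[i], cy[i + k] - cy[i]
    stt, sty = ctt[i + k] - ctt[i], cty[i + k] - cty[i]
    return (k * sty - st * sy) / (k * stt - st * st)


def max_growth_rate(curve: GrowthCurve, window: int = DEFAULT_WINDOW):
    """Maximum sliding-window slope of ln(OD) vs time.

    Returns ``(rate, start_index)``; ties go to the earliest window.
    """
    if len(curve) < window:
        raise ValueError(f"curve has {len(curve)} points; window needs {window}")
    slopes = _window_slopes(curve.times, np.log(curve.od), window)
    i = int(np.argmax(slopes))
    return float(slopes[i]), i


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, y)
    return float(res.intercept), float(res.slope)


def lag_time(
    curve: GrowthCurve, window: int = DEFAULT_WINDOW, slope_tol: float = 1e-6
):
    """Lag from the intersection of the baseline and maximum-rate lines.

    The baseline line is fitted to the first ``window`` ln(OD) points; the
    growth line is the maximum-rate window's fit.  Returns
    ``(lag_hours, defined, suspicious)``: ``defined`` is False (lag NaN) when
    the two lines are parallel within ``slope_tol`` (e.g. a pure exponential
    growing from t = 0), and ``suspicious`` flags a lag earlier than one hour
    before the first sample.
    """
    rate, i0 = max_growth_rate(curve, window)
    logod = np.log(curve.od)
    a1, b1 = _line_fit(curve.times[:window], logod[:window])
    a2, b2 = _line_fit(curve.times[i0:i0 + window], logod[i0:i0 + window])
    if abs(b2 - b1) < slope_tol:
        return float("nan"), False, False
    lag = (a1 - a2) / (b2 - b1)
    return float(lag), True, bool(lag < curve.times[0] - 1.0)


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area of ln(OD) above the smallest measured ln(OD)."""
    if len(curve) < 2:
        raise ValueError("need at least 2 points for an area")
    logod = np.log(curve.od)
    area = float(np.trapezoid(logod, curve.times))
    base = float(logod.min()) * (curve.times[-1] - curve.times[0])
    return area - base


def carrying_capacity(curve: GrowthCurve) -> float:
    """Highest OD600 achieved within the recording window."""
    return float(curve.od.max())


def fit_growth(curve: GrowthCurve, window: int = DEFAULT_WINDOW) -> GrowthParams:
    """All four growth parameters for one curve."""
    rate, i0 = max_growth_rate(curve, window)
    lag, defined, suspicious = lag_time(curve, window)
    return GrowthParams(
        max_rate=rate,
        rate_window_start=i0,
        lag=lag,
        lag_defined=defined,
        auc=auc(curve),
        capacity=carrying_capacity(curve),
        lag_suspicious=suspicious,
    )
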