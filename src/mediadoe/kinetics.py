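"""Growth-curve characterisation: Delta-OD600, Hill-slope curve fits,
log-phase doubling times and one-way ANOVA for between-block controls.

The endpoint response of the pipeline is the change in optical density at
600 nm from time 0 (Delta-OD600).  Whole curves are summarised by a
saturating Hill-shaped fit y(t) = top * t^h / (t50^h + t^h) — time as the
independent variable, a curve-shape borrowing from one-site specific
binding — and by the log-linear specific growth rate over an exponential
window, reported as a doubling time in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "GrowthCurve",
    "HillFit",
    "RateEstimate",
    "ANOVAResult",
    "delta_od",
    "fit_hill",
    "doubling_time",
    "find_log_window",
    "one_way_anova",
]

logger = logging.getLogger(__name__)


@dataclass
class GrowthCurve:
    """OD600 readings along strictly increasing times (hours)."""

    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty growth curve")
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def delta_od600(self) -> np.ndarray:
        return self.od600 - self.od600[0]


def delta_od(curve: GrowthCurve, endpoint_h: float = 24.0):
    """Baseline-subtracted series and the endpoint nearest ``endpoint_h``.

    The earliest reading is the baseline; if it is not at t = 0 this is
    logged and the earliest time is used as time zero.
    """
    if curve.times[0] != 0.0:
        logger.info("first reading at t=%.3g h used as baseline", curve.times[0])
    series = curve.delta_od600
    i = int(np.argmin(np.abs(curve.times - endpoint_h)))
    return series, float(series[i])


@dataclass
class HillFit:
    top: float
    t50: float
    hill: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = self.top * t ** self.hill / (self.t50 ** self.hill + t ** self.hill)
        return np.nan_to_num(y, nan=0.0)


def _hill(t, top, t50, hill):
    with np.errstate(divide="ignore", invalid="ignore"):
        y = top * t ** hill / (t50 ** hill + t ** hill)
    return np.nan_to_num(y, nan=0.0)


def fit_hill(curve: GrowthCurve) -> HillFit:
    """Least-squares Hill-slope fit of the Delta-OD600 series vs time.

    Initialization: top = max(y), t50 = interpolated time at half-max,
    hill = 2; all parameters bounded positive with t50 capped at twice the
    final time.  Non-convergence returns ``converged=False`` with the
    solver message rather than raising.
    """
    t = curve.times
    y = curve.delta_od600
    pos = y > 0
    if pos.sum() < 4 or np.ptp(y[pos]) <= 0:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False,
                       "need >= 4 points with positive spread")
    top0 = float(y.max())
    half = top0 / 2.0
    above = np.flatnonzero(y >= half)
    if len(above) and above[0] > 0:
        i = above[0]
        t50_0 = float(np.interp(half, [y[i - 1], y[i]], [t[i - 1], t[i]]))
    else:
        t50_0 = float(t[len(t) // 2]) or 1.0
    t50_0 = max(t50_0, 1e-6)
    try:
        popt, _ = scipy.optimize.curve_fit(
            _hill, t, y, p0=[top0, t50_0, 2.0],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, 2.0 * t[-1], np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    rss = float(((y - _hill(t, *popt)) ** 2).sum())
    return HillFit(float(popt[0]), float(popt[1]), float(popt[2]), rss, True)


@dataclass
class RateEstimate:
    mu: float                 # specific growth rate, per minute
    doubling_time: float      # ln 2 / mu, minutes
    window: tuple[float, float]  # hours
    r2: float
    no_growth: bool = False


def find_log_window(curve: GrowthCurve, min_points: int = 4) -> tuple[float, float]:
    """Automatic exponential-phase window: the sliding window of at least
    ``min_points`` consecutive readings with OD > 0 that maximizes the r^2
    of the log-linear fit among windows with positive slope."""
    t, od = curve.times, curve.od600
    best = None
    n = len(t)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            seg_t, seg_od = t[i:j + 1], od[i:j + 1]
            if np.any(seg_od <= 0):
                continue
            slope, _, r, _, _ = scipy.stats.linregress(seg_t, np.log(seg_od))
            if slope <= 0:
                continue
            r2 = r * r
            if best is None or r2 > best[0]:
                best = (r2, (float(seg_t[0]), float(seg_t[-1])))
    if best is None:
        raise ValueError("no positive-slope log-linear window found")
    return best[1]


def doubling_time(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> RateEstimate:
    """Log-phase doubling time from a log-linear fit of ln(OD600) vs time.

    ``window`` is (start, end) in hours; omitted, it is chosen
    automatically by :func:`find_log_window`.  The rate is reported per
    minute and the doubling time as ln2/mu in minutes.
    """
    if window is None:
        window = find_log_window(curve)
    t0, t1 = window
    mask = (curve.times >= t0) & (curve.times <= t1)
    t = curve.times[mask]
    od = curve.od600[mask]
    if len(t) < 3:
        raise ValueError("need >= 3 points in the window")
    if np.any(od <= 0):
        raise ValueError("window contains non-positive OD600 readings")
    minutes = t * 60.0
    slope, _, r, _, _ = scipy.stats.linregress(minutes, np.log(od))
    if slope <= 0:
        return RateEstimate(mu=float(slope), doubling_time=np.nan,
                            window=window, r2=float(r * r), no_growth=True)
    return RateEstimate(
        mu=float(slope), doubling_time=float(np.log(2.0) / slope),
        window=window, r2=float(r * r),
    )


@dataclass
class ANOVAResult:
    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(groups: list) -> ANOVAResult:
    """Classical one-way ANOVA (between/within decomposition).

    Used for the batch-effect check on per-block positive controls.
    Identical groups give F = 0, p = 1; zero within-group variance with
    real between-group differences gives F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return ANOVAResult(F=0.0, p=1.0, df_between=dfb, df_within=dfw)
        return ANOVAResult(F=np.inf, p=0.0, df_between=dfb, df_within=dfw)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(scipy.stats.f.sf(F, dfb, dfw))
    return ANOVAResult(F=float(F), p=p, df_between=dfb, df_within=dfw)
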