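"""Event-aligned rate-of-change analysis of weather around stopover edges.

For each stopover start (or end), the hourly change of each weather
variable is extracted in a window from 7 h before to 7 h after the event.
Curves are averaged in two stages — stopovers within individual, then
across individuals — smoothed with a loess, and summarized by the lag of
the peak rate of change relative to the event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AlignedChangeCurve:
    variable: str
    offsets_h: np.ndarray          # -before .. +after, integers
    mean_change: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_individuals: int
    smoothed: np.ndarray | None = None


@dataclass
class PeakLag:
    variable: str
    event_kind: str  # "start" | "end"
    lag_h: int
    peak_sign: str   # "max" | "min"
    at_boundary: bool = False


def hourly_change(series: np.ndarray) -> np.ndarray:
    """First difference aligned to t: delta[t] = x[t] - x[t-1]; NaN leads."""
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    if len(x) >= 2:
        out[1:] = x[1:] - x[:-1]
    return out


def extract_event_window(series: np.ndarray, times: np.ndarray, event_time,
                         before_h: int = 7, after_h: int = 7) -> np.ndarray:
    """Values of an hourly series at offsets -before_h..+after_h of an event.

    ``event_time`` is rounded to the nearest hour before alignment;
    offsets outside the series are NaN.
    """
    t = pd.Timestamp(event_time).round("h")
    ts = np.asarray(times, dtype="datetime64[s]")
    x = np.asarray(series, dtype=float)
    out = np.full(before_h + after_h + 1, np.nan)
    base = np.datetime64(t, "s")
    for k, off in enumerate(range(-before_h, after_h + 1)):
        want = base + np.timedelta64(int(off * 3600), "s")
        i = np.searchsorted(ts, want)
        if i < len(ts) and ts[i] == want:
            out[k] = x[i]
    return out


def average_curves(windows: list[np.ndarray], individual_ids: list[str],
                   variable: str = "", before_h: int = 7, after_h: int = 7,
                   ) -> AlignedChangeCurve:
    """Two-stage mean with a normal-approximation 95 % CI across individuals.

    Per offset: mean over stopovers within each individual, then mean over
    individuals.  CI = mean +/- 1.96 * sd(individual means)/sqrt(n);
    offsets with < 2 contributing individuals get a missing CI.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    if len(windows) != len(individual_ids):
        raise ValueError("windows and individual_ids must align")
    width = before_h + after_h + 1
    arr = np.vstack([np.asarray(w, dtype=float) for w in windows])
    if arr.shape[1] != width:
        raise ValueError(f"windows must have {width} offsets")

    ids = np.asarray(individual_ids)
    uniq = pd.unique(ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        ind_means = np.vstack([np.nanmean(arr[ids == u], axis=0) for u in uniq])
        mean = np.nanmean(ind_means, axis=0)
        n_per_offset = np.sum(np.isfinite(ind_means), axis=0)
        sd = np.nanstd(ind_means, axis=0, ddof=1)
    se = np.where(n_per_offset >= 2, sd / np.sqrt(np.maximum(n_per_offset, 1)),
                  np.nan)
    ci_low = mean - 1.96 * se
    ci_high = mean + 1.96 * se
    return AlignedChangeCurve(
        variable=variable,
        offsets_h=np.arange(-before_h, after_h + 1),
        mean_change=mean, ci_low=ci_low, ci_high=ci_high,
        n_individuals=int(len(uniq)))


def loess_smooth(curve: AlignedChangeCurve, span: float = 0.5,
                 degree: int = 2) -> AlignedChangeCurve:
    """Loess (local polynomial, tricube weights) over the window offsets.

    With fewer than 5 finite points the raw curve is passed through with a
    warning.  Returns the same curve object with ``smoothed`` set.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    x = curve.offsets_h.astype(float)
    y = curve.mean_change
    finite = np.isfinite(y)
    if finite.sum() < 5:
        warnings.warn("too few finite points for loess; passthrough")
        curve.smoothed = y.copy()
        return curve
    xf, yf = x[finite], y[finite]
    k = max(degree + 1, int(np.ceil(span * len(xf))))
    k = min(k, len(xf))
    smoothed = np.full_like(y, np.nan)
    for i, xi in enumerate(x):
        d = np.abs(xf - xi)
        h = np.sort(d)[k - 1]
        if h == 0:
            h = 1e-9
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        deg = min(degree, use.sum() - 1)
        try:
            coeffs = np.polyfit(xf[use] - xi, yf[use], deg, w=np.sqrt(w[use]))
            smoothed[i] = coeffs[-1]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate weights
            smoothed[i] = y[i]
    curve.smoothed = smoothed
    return curve


def peak_lag(curve: AlignedChangeCurve, event_kind: str) -> PeakLag:
    """Offset of the extremum with the largest absolute smoothed change.

    Ties break toward offset 0, then toward negative offsets.  The result
    is flagged when the extremum sits on the window boundary.
    """
    y = curve.smoothed if curve.smoothed is not None else curve.mean_change
    finite = np.isfinite(y)
    if not finite.any():
        raise ValueError("all-missing curve")
    offs = curve.offsets_h
    candidates = sorted(
        ((float(abs(y[i])), abs(int(offs[i])), int(offs[i]), i)
         for i in np.flatnonzero(finite)),
        key=lambda c: (-c[0], c[1], c[2]))
    _, _, lag, i = candidates[0]
    sign = "max" if y[i] >= 0 else "min"
    boundary = lag in (int(offs[0]), int(offs[-1]))
    return PeakLag(variable=curve.variable, event_kind=event_kind,
                   lag_h=lag, peak_sign=sign, at_boundary=boundary)


def curves_to_frame(curves: list[AlignedChangeCurve]) -> pd.DataFrame:
    """Long-format export of aligned curves."""
    rows = []
    for c in curves:
        sm = c.smoothed if c.smoothed is not None else np.full_like(c.mean_change,
                                                                    np.nan)
        for k in range(len(c.offsets_h)):
            rows.append({
                "variable": c.variable, "offset_h": int(c.offsets_h[k]),
                "mean_change": c.mean_change[k], "ci_low": c.ci_low[k],
                "ci_high": c.ci_high[k], "smoothed": sm[k],
                "n_individuals": c.n_individuals,
            })
    return pd.DataFrame(rows)


def lags_to_frame(lags: list[PeakLag]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": p.variable, "event_kind": p.event_kind, "lag_h": p.lag_h,
        "peak_sign": p.peak_sign, "at_boundary": p.at_boundary,
    } for p in lags])
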