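"""Lag-domain analysis of dyadic velocity series.

Series are linearly resampled onto a regular 0.1-s grid (0–120 s inclusive,
1201 points for a full trial), cross-correlated with lags up to +/-10 s
(per-lag Pearson coefficient over the overlapping segment), averaged across
trials and dyads, and summarised by the absolute lag of the peak
coefficient per body-part combination.  Vision and No Vision peak-lag
distributions are compared with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CrossCorrFunction:
    """A cross-correlation function on the regular lag grid."""

    label: str
    lags: np.ndarray          # seconds, symmetric about 0
    coefficients: np.ndarray  # per-lag correlation, NaN where overlap too short

    @property
    def peak_lag(self) -> float:
        """Absolute lag (s) of the highest coefficient; ties break toward 0."""
        return peak_lag(self.lags, self.coefficients)

    @property
    def peak_value(self) -> float:
        return float(np.nanmax(self.coefficients))


def regularize(values: np.ndarray, frame_rate: float, t0: float = 0.0,
               t1: float = 120.0, step: float = 0.1) -> np.ndarray:
    """Resample a frame-indexed series onto the regular grid
    ``t0, t0+step, ..., t1`` (inclusive) by linear interpolation.

    Sample ``i`` of the input is taken at time ``i / frame_rate``.  If the
    series ends before ``t1`` the grid is truncated (with a warning).
    """
    values = np.asarray(values, dtype=float)
    times = np.arange(values.shape[0]) / frame_rate
    grid = t0 + step * np.arange(int(round((t1 - t0) / step)) + 1)
    if times[-1] < t1 - 1e-9:
        grid = grid[grid <= times[-1] + 1e-9]
        warnings.warn(f"series ends at {times[-1]:.2f}s; grid truncated to "
                      f"{len(grid)} points")
    if values.ndim == 1:
        return np.interp(grid, times, values)
    return np.stack([np.interp(grid, times, values[:, j])
                     for j in range(values.shape[1])], axis=1)


def lag_grid(max_lag: float = 10.0, step: float = 0.1) -> np.ndarray:
    k = int(round(max_lag / step))
    return step * np.arange(-k, k + 1)


def xcorr(x: np.ndarray, y: np.ndarray, max_lag: float = 10.0,
          step: float = 0.1, min_overlap: int = 10,
          label: str = "") -> CrossCorrFunction:
    """Cross-correlation function of two regularised series.

    At lag ``L`` (in grid steps) the coefficient is the Pearson correlation
    of ``x[t]`` with ``y[t + L]`` over the overlapping segment, so a
    positive peak lag means ``y`` lags ``x``.  Lags whose overlap falls
    below ``min_overlap`` samples are NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = x.size
    k = int(round(max_lag / step))
    lags = lag_grid(max_lag, step)
    coef = np.full(lags.size, np.nan)
    for i, shift in enumerate(range(-k, k + 1)):
        if shift >= 0:
            xs, ys = x[: n - shift], y[shift:]
        else:
            xs, ys = x[-shift:], y[: n + shift]
        if xs.size < min_overlap:
            continue
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        coef[i] = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return CrossCorrFunction(label=label, lags=lags, coefficients=coef)


def xcorr_columns(x: np.ndarray, y: np.ndarray, max_lag: float = 10.0,
                  step: float = 0.1, min_overlap: int = 10) -> np.ndarray:
    """Column-wise cross-correlation: ``out[l, j] = xcorr(x[:, j], y[:, j])``
    at lag index ``l`` — the vectorised path for many combinations at once."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.shape
    k = int(round(max_lag / step))
    out = np.full((2 * k + 1, m), np.nan)
    for i, shift in enumerate(range(-k, k + 1)):
        if shift >= 0:
            xs, ys = x[: n - shift], y[shift:]
        else:
            xs, ys = x[-shift:], y[: n + shift]
        if xs.shape[0] < min_overlap:
            continue
        sx, sy = xs.std(axis=0), ys.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = ((xs - xs.mean(axis=0)) * (ys - ys.mean(axis=0))).mean(axis=0) / (sx * sy)
        out[i] = np.where((sx == 0) | (sy == 0), np.nan, c)
    return out


def peak_lag(lags: np.ndarray, coefficients: np.ndarray) -> float:
    """Absolute lag of the maximum coefficient; exact ties are broken toward
    the smallest absolute lag (conservative for rapid-synchrony claims)."""
    c = np.asarray(coefficients, float)
    finite = np.isfinite(c)
    if not finite.any():
        raise ValueError("no finite coefficients")
    best = np.nanmax(c)
    tied = np.flatnonzero(finite & (c >= best - 1e-15))
    i = tied[np.argmin(np.abs(lags[tied]))]
    return float(abs(lags[i]))


def peak_lag_summary(mean_functions: dict[str, np.ndarray], lags: np.ndarray,
                     fast_threshold: float = 0.5) -> dict:
    """Summarise peak lags of dyad-averaged cross-correlation functions.

    ``mean_functions`` maps a combination label to its (trial- then
    dyad-averaged) coefficient vector.  Returns per-combo absolute peak lags
    plus pooled distribution summaries: mean, quartiles and the fraction of
    peaks faster than ``fast_threshold`` seconds.
    """
    per_combo = {label: peak_lag(lags, c) for label, c in mean_functions.items()}
    vals = np.array(list(per_combo.values()))
    return {
        "per_combo": per_combo,
        "mean": float(vals.mean()),
        "q1": float(np.percentile(vals, 25)),
        "median": float(np.percentile(vals, 50)),
        "q3": float(np.percentile(vals, 75)),
        "fraction_fast": float((vals < fast_threshold).mean()),
        "fast_threshold": fast_threshold,
        "n": int(vals.size),
    }


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (the standard convention); with at least 6
    nonzero pairs the tie-corrected normal approximation is used and a Z
    statistic reported, otherwise the exact distribution (Z is NaN there).
    All-zero differences leave the test undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "approx" if n >= 6 else "exact"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    if method == "approx":
        # signed Z from the positive-rank sum (scipy's zstatistic is based on
        # the smaller rank sum and loses the direction)
        ranks = stats.rankdata(np.abs(d))
        r_plus = ranks[d > 0].sum()
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        sigma2 -= (counts ** 3 - counts).sum() / 48.0
        z = float((r_plus - mu) / np.sqrt(sigma2))
    else:
        z = np.nan
    return {"W": float(res.statistic), "Z": z, "p": float(res.pvalue),
            "n_nonzero": int(n), "method": method}
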