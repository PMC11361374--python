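"""FRAP recovery kinetics: bleach correction, model fitting, summaries.

The recovery of fluorescence in the bleached ROI is modeled as

    y(x) = y0 + (a - y0) * (1 - exp(-b * x))

with x the time since the first post-bleach frame, a the asymptotic
normalized intensity and b the recovery rate (1/s). Derived readouts are
the half-time of recovery t1/2 = ln(2)/b and the immobile fraction
percentage. The default immobile-fraction convention reports a·100%;
with a double-normalized trace (reference ratio, then pre-bleach plateau
scaled to 1) the plateau a is conventionally the *mobile* fraction, so a
``complement`` switch reporting (1 - a)·100% is provided — see the
methods note for why both exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic_data import FrapTrace, frap_model
from . import stats_reporting

__all__ = ["FrapFit", "bleach_correct", "fit_recovery", "summarize_frap"]

LN2 = math.log(2.0)


@dataclass
class FrapFit:
    """Fitted recovery parameters and derived kinetic readouts."""

    y0: float
    a: float
    b: float
    immobile_fraction_pct: float
    t_half: float
    rss: float
    converged: bool
    n_points: int
    immobile_convention: str = "plateau"


def bleach_correct(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalize a trace and return the post-bleach recovery series.

    The ROI is divided frame-by-frame by the unbleached reference region
    (cancelling acquisition photobleaching), then scaled so the mean of
    the pre-bleach corrected values is 1. Returns ``(x, y)`` where x
    restarts at 0 at the first post-bleach frame.
    """
    if np.any(trace.reference <= 0):
        raise ValueError("reference intensities must be positive")
    corrected = trace.roi / trace.reference
    pre = corrected[: trace.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean after correction")
    corrected = corrected / pre
    x = trace.t[trace.n_prebleach:] - trace.t[trace.n_prebleach]
    return x, corrected[trace.n_prebleach:]


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    y0 = float(np.clip(y[0], 0.0, 1.5))
    a = float(np.clip(np.mean(y[-5:]), 0.0, 1.5))
    b = LN2  # fallback: half-time of 1 s
    if a - y0 > 1e-6:
        ratio = (a - y) / (a - y0)
        ok = (ratio > 1e-3) & (x > 0)
        if ok.sum() >= 2:
            slope = np.polyfit(x[ok], np.log(ratio[ok]), 1)[0]
            if slope < 0:
                b = -slope
    return y0, a, max(b, 1e-6)


def fit_recovery(x: np.ndarray, y: np.ndarray,
                 immobile_convention: str = "plateau") -> FrapFit:
    """Nonlinear least-squares fit of the single-exponential recovery model.

    Bounds: y0, a in [0, 1.5]; b > 0. Initialization: y0 from the first
    post-bleach value, a from the mean of the last 5 values, b from a
    log-linear fit of (a - y)/(a - y0). On non-convergence the derived
    fields are NaN and ``converged`` is False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 post-bleach points")
    if immobile_convention not in ("plateau", "complement"):
        raise ValueError("immobile_convention must be 'plateau' or 'complement'")
    p0 = _initial_guess(x, y)
    try:
        popt, _ = curve_fit(
            frap_model, x, y, p0=p0,
            bounds=([0.0, 0.0, 1e-9], [1.5, 1.5, np.inf]),
            maxfev=10000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        y0, a, b = (float(v) for v in popt)
        converged = np.isfinite([y0, a, b]).all() and b > 0
    except RuntimeError:
        y0, a, b = p0
        converged = False
    if converged:
        resid = y - frap_model(x, y0, a, b)
        rss = float(resid @ resid)
        t_half = LN2 / b
        if_pct = a * 100.0 if immobile_convention == "plateau" else (1.0 - a) * 100.0
    else:
        rss, t_half, if_pct = float("nan"), float("nan"), float("nan")
    return FrapFit(y0=y0, a=a, b=b, immobile_fraction_pct=if_pct, t_half=t_half,
                   rss=rss, converged=converged, n_points=len(x),
                   immobile_convention=immobile_convention)


def fit_trace(trace: FrapTrace, immobile_convention: str = "plateau") -> FrapFit:
    """Convenience: bleach-correct then fit one raw trace."""
    x, y = bleach_correct(trace)
    return fit_recovery(x, y, immobile_convention=immobile_convention)


def summarize_frap(fits_by_condition: dict[str, list[FrapFit]]):
    """Mean ± SD of immobile fraction % and t1/2 per condition.

    Non-converged fits are excluded from the means but counted. With
    exactly two conditions an unpaired two-tailed t test on the per-cell
    immobile fractions is returned as well (otherwise ``None``).
    """
    rows = []
    per_cond_if: dict[str, np.ndarray] = {}
    for cond, fits in fits_by_condition.items():
        ok = [f for f in fits if f.converged]
        if not ok:
            raise ValueError(f"condition {cond!r} has no converged fit")
        if_vals = np.array([f.immobile_fraction_pct for f in ok])
        th_vals = np.array([f.t_half for f in ok])
        per_cond_if[cond] = if_vals
        rows.append({
            "condition": cond,
            "n_cells": len(fits),
            "n_converged": len(ok),
            "immobile_fraction_pct_mean": float(if_vals.mean()),
            "immobile_fraction_pct_sd": float(if_vals.std(ddof=1)) if len(ok) > 1 else np.nan,
            "t_half_mean_s": float(th_vals.mean()),
            "t_half_sd_s": float(th_vals.std(ddof=1)) if len(ok) > 1 else np.nan,
        })
    summary = pd.DataFrame(rows)
    test = None
    if len(fits_by_condition) == 2:
        (c1, v1), (c2, v2) = per_cond_if.items()
        test = stats_reporting.t_test(v1, v2, paired=False)
        test.comparison = f"{c1} vs {c2}"
    return summary, test
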