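"""Analytical method-performance QC: calibration, LOD/LOQ, recovery, precision.

The detection and quantification limits follow the ICH calibration-curve
approach: LOD = 3.3 σ/S and LOQ = 3 × LOD, with S the slope of the
calibration line and σ the "standard deviation of the response".  σ is
taken as the residual standard deviation of the ordinary-least-squares
calibration fit (n − 2 denominator) by default; ``sigma`` can be overridden
with, e.g., the sd of blank responses where that reading is preferred.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import CalibrationCurve


def fit_calibration(points: Iterable[tuple[float, float]]) -> CalibrationCurve:
    """OLS line through (concentration, response) calibration points."""
    pts = sorted((float(c), float(r)) for c, r in points)
    if len(pts) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in pts])
    resp = np.array([p[1] for p in pts])
    if np.unique(conc).size < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(design, resp, rcond=None)
    residuals = resp - (slope * conc + intercept)
    sigma = float(np.sqrt(np.sum(residuals**2) / (len(pts) - 2)))
    if slope == 0:
        raise ValueError("calibration slope is zero")
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            residual_sd=sigma, n=len(pts),
                            concentrations=tuple(conc), responses=tuple(resp))


def lod(curve: CalibrationCurve, sigma: float | None = None) -> float:
    """Limit of detection, 3.3 σ/S, in concentration units (µg/kg)."""
    if curve.slope == 0:
        raise ValueError("slope is zero; LOD undefined")
    s = curve.residual_sd if sigma is None else float(sigma)
    return 3.3 * s / abs(curve.slope)


def loq(curve: CalibrationCurve, sigma: float | None = None) -> float:
    """Limit of quantification, 3 × LOD, in µg/kg."""
    return 3.0 * lod(curve, sigma=sigma)


def recovery(spiked_measured: float, spiked_true: float) -> float:
    """Spike recovery in percent: 100 × measured/true."""
    if spiked_true <= 0:
        raise ValueError("spiked_true must be > 0")
    return 100.0 * spiked_measured / spiked_true


def repeatability_rsd(replicates_by_day: Mapping[object, Sequence[float]]) -> tuple[float, float]:
    """Intra- and inter-day precision as relative standard deviations (%).

    Intra-day RSD: mean over days of 100·sd/mean within the day (sd with
    n − 1).  Inter-day RSD: 100·sd/mean across the daily means.  Requires
    at least 2 replicates per day and 2 days.
    """
    days = list(replicates_by_day)
    if len(days) < 2:
        raise ValueError("inter-day RSD needs at least 2 days")
    intra = []
    daily_means = []
    for day in days:
        vals = np.asarray(list(replicates_by_day[day]), dtype=float)
        if vals.size < 2:
            raise ValueError(f"day {day!r}: need at least 2 replicates")
        m = vals.mean()
        if m == 0:
            raise ValueError(f"day {day!r}: zero mean, RSD undefined")
        intra.append(100.0 * np.std(vals, ddof=1) / m)
        daily_means.append(m)
    daily_means = np.asarray(daily_means)
    grand = daily_means.mean()
    if grand == 0:
        raise ValueError("zero grand mean, inter-day RSD undefined")
    inter = 100.0 * np.std(daily_means, ddof=1) / grand
    return float(np.mean(intra)), float(inter)
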