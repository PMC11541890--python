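"""Calibration-curve statistics: OLS fit, LOD/LOQ, linear range, repeatability.

The detection and quantification limits follow the ICH-style definitions
``LOD = 3.3 sigma / S`` and ``LOQ = 10 sigma / S`` with ``S`` the slope of
the calibration line.  "Standard deviation of the response" is interpreted
as the regression's residual standard deviation (n-2 denominator); blank-SD
and intercept-SE estimators are selectable since the definition is ambiguous
in common usage.  The calibration response of the screening method is the R1
reduction peak current.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peakdetect import DetectedPeak

__all__ = [
    "CalibrationResult",
    "LinearRange",
    "fit_calibration",
    "find_linear_range",
    "repeatability",
    "LOD_FACTOR",
    "LOQ_FACTOR",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationResult:
    """Linear calibration summary (concentrations in umol/L, currents in uA)."""

    slope: float  # uA per umol/L
    intercept: float  # uA
    sigma: float  # uA, SD of the response
    r_squared: float
    lod: float  # umol/L
    loq: float  # umol/L
    n: int
    sigma_estimator: str = "residual_sd"
    linear_range: tuple[float, float] | None = None


@dataclass(frozen=True)
class LinearRange:
    lo: float
    hi: float
    r_squared: float
    n_levels: int


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    sigma_estimator: str = "residual_sd",
    blank_sd: float | None = None,
) -> CalibrationResult:
    """Ordinary least squares of response on concentration, with LOD/LOQ.

    Parameters
    ----------
    concentrations, responses
        Paired observations; at least three distinct concentration levels.
    sigma_estimator
        ``"residual_sd"`` (default; residual SD with n-2 denominator),
        ``"intercept_se"`` (standard error of the intercept) or ``"blank_sd"``
        (caller-supplied SD of blank responses).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.unique(x).size < 3:
        raise ValueError("calibration needs at least 3 distinct concentration levels")

    fit = stats.linregress(x, y)
    n = x.size
    residuals = y - (fit.intercept + fit.slope * x)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
    if sigma_estimator == "residual_sd":
        sigma = residual_sd
    elif sigma_estimator == "intercept_se":
        sigma = float(fit.intercept_stderr)
    elif sigma_estimator == "blank_sd":
        if blank_sd is None:
            raise ValueError("blank_sd estimator requires the blank_sd argument")
        sigma = float(blank_sd)
    else:
        raise ValueError(f"unknown sigma estimator {sigma_estimator!r}")

    slope = float(fit.slope)
    if slope == 0.0 or not np.isfinite(slope):
        raise ValueError("zero or non-finite slope: LOD/LOQ undefined")
    return CalibrationResult(
        slope=slope,
        intercept=float(fit.intercept),
        sigma=sigma,
        r_squared=float(fit.rvalue**2),
        lod=LOD_FACTOR * sigma / abs(slope),
        loq=LOQ_FACTOR * sigma / abs(slope),
        n=n,
        sigma_estimator=sigma_estimator,
    )


def find_linear_range(
    levels: Sequence[float],
    responses: Sequence[float],
    r2_min: float = 0.99,
    min_levels: int = 3,
) -> LinearRange | None:
    """Widest contiguous span of concentration levels fitting linearly.

    All replicate observations falling inside a candidate span are fitted
    together; spans qualify when the fit reaches ``r2 >= r2_min``.  Among
    qualifying spans the widest (most levels) wins, preferring spans that
    include the top level, then higher spans.  Returns ``None`` when no span
    qualifies.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    unique = np.unique(x)
    if unique.size < 4:
        raise ValueError("linear-range search needs at least 4 distinct levels")

    best: tuple | None = None
    for i in range(unique.size):
        for j in range(i + min_levels - 1, unique.size):
            lo, hi = unique[i], unique[j]
            mask = (x >= lo) & (x <= hi)
            fit = stats.linregress(x[mask], y[mask])
            r2 = float(fit.rvalue**2)
            if r2 < r2_min:
                continue
            key = (j - i + 1, j == unique.size - 1, hi, -lo)
            if best is None or key > best[0]:
                best = (key, LinearRange(float(lo), float(hi), r2, j - i + 1))
    return None if best is None else best[1]


def extract_r1_currents(
    traces: Sequence,
    baseline_cfg=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration response: |R1 peak current| per trace, with concentrations.

    Each trace (cathodic sweep, raw) is cropped to the standard window,
    baseline-corrected, and its R1-window reduction peak extracted; traces
    must carry ``concentration`` metadata.  Traces without a detectable R1
    peak are skipped.
    """
    from .peak_library import R1_WINDOW
    from .peakdetect import detect_peaks, match_peaks
    from .preprocess import correct_baseline, crop

    concentrations, responses = [], []
    for vg in traces:
        corrected, _ = correct_baseline(crop(vg), baseline_cfg)
        peaks = [p for p in detect_peaks(corrected) if p.sign == "reduction"]
        (match,) = match_peaks(peaks, [("R1", *R1_WINDOW)])
        if match.found:
            concentrations.append(float(vg.meta["concentration"]))
            responses.append(abs(match.peak.height))
    return np.asarray(concentrations), np.asarray(responses)


def repeatability(
    peak_sets: Mapping[str, Sequence[DetectedPeak]],
    ip_bound: float = 13.0,
    ep_bound: float = 1.0,
) -> pd.DataFrame:
    """Replicate relative standard deviations of peak current and potential.

    ``peak_sets`` maps a process label (e.g. ``"MPHP/R1"``) to the peaks
    measured in replicate runs.  RSD% = 100 * sd / |mean| with sample SD
    (ddof=1).  Entries with zero mean get ``NaN`` RSD, fail their bound flag
    and carry a note.  Default bounds are the repeatability limits of the
    reference method (13.0% for I_p, 1.0% for E_p).
    """
    records = []
    for label, peaks in peak_sets.items():
        if len(peaks) < 2:
            raise ValueError(f"{label!r}: repeatability needs >= 2 replicates")
        ip = np.array([p.height for p in peaks], dtype=float)
        ep = np.array([p.potential for p in peaks], dtype=float)
        row: dict = {"label": label, "n": len(peaks), "note": ""}
        for name, values, bound in (("ip", ip, ip_bound), ("ep", ep, ep_bound)):
            mean = values.mean()
            if mean == 0.0:
                row[f"{name}_rsd_pct"] = np.nan
                row[f"{name}_pass"] = False
                row["note"] += f"{name}: zero mean, RSD undefined; "
            else:
                rsd = 100.0 * values.std(ddof=1) / abs(mean)
                row[f"{name}_rsd_pct"] = rsd
                row[f"{name}_pass"] = bool(rsd <= bound)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("label")
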