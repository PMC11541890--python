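"""Voltammogram preprocessing: window cropping, baseline subtraction, normalization.

The preprocessing chain mirrors the reference screening method: anodic sweeps
are cut to -1.60..+1.60 V and cathodic sweeps to +1.80..-1.80 V, the slowly
varying background is removed by a polynomial fit, and currents are scaled to
unit maximum absolute value.  The original workflow fitted the baseline
interactively in a commercial plotting tool; here the standard automated
surrogate is used -- iterative polynomial fitting in which points that deviate
strongly from the current fit (the redox peaks) are excluded before refitting,
so peaks do not drag the baseline.  Because DPV traces carry both oxidation
(positive) and reduction (negative) peaks, the default clip rule excludes
outliers on both sides of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import Voltammogram

__all__ = [
    "BaselineFitConfig",
    "DEFAULT_CROP_WINDOWS",
    "crop",
    "correct_baseline",
    "normalize",
    "preprocess_trace",
]

#: Default crop windows (V) per scan direction, as in the reference method.
DEFAULT_CROP_WINDOWS: dict[str, tuple[float, float]] = {
    "anodic": (-1.60, 1.60),
    "cathodic": (-1.80, 1.80),
}

_EDGE_TOL = 1e-9  # inclusive-boundary tolerance on the potential grid


@dataclass(frozen=True)
class BaselineFitConfig:
    """Iteratively clipped polynomial baseline fit.

    ``clip_rule`` controls which residuals are treated as peak points and
    excluded between iterations: ``"both"`` (default; oxidation and reduction
    peaks), ``"above"`` or ``"below"``.  Clipping is at ``clip_k`` robust
    standard deviations (scaled MAD) of the residuals.
    """

    order: int = 3
    max_iter: int = 50
    clip_k: float = 2.5
    clip_rule: str = "both"
    tol: float = 1e-6  # relative change in the fitted baseline

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("polynomial order must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.clip_rule not in ("both", "above", "below"):
            raise ValueError(f"bad clip_rule {self.clip_rule!r}")


def crop(vg: Voltammogram, lo: float | None = None, hi: float | None = None) -> Voltammogram:
    """Restrict a trace to ``lo <= E <= hi`` (inclusive ends).

    Defaults to the standard window for the trace's scan direction.  Raises
    ``ValueError`` when the window misses the trace entirely.
    """
    if lo is None or hi is None:
        d_lo, d_hi = DEFAULT_CROP_WINDOWS[vg.scan_direction]
        lo = d_lo if lo is None else lo
        hi = d_hi if hi is None else hi
    if lo > hi:
        lo, hi = hi, lo
    mask = (vg.potentials >= lo - _EDGE_TOL) & (vg.potentials <= hi + _EDGE_TOL)
    if not mask.any():
        raise ValueError(
            f"crop window ({lo}, {hi}) V does not intersect the trace range "
            f"[{vg.potentials.min()}, {vg.potentials.max()}] V"
        )
    return Voltammogram(
        vg.potentials[mask].copy(),
        vg.currents[mask].copy(),
        vg.scan_direction,
        dict(vg.meta, crop=(float(lo), float(hi))),
    )


def _robust_sd(residuals: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(residuals - np.median(residuals))))


def correct_baseline(
    vg: Voltammogram, cfg: BaselineFitConfig | None = None
) -> tuple[Voltammogram, Voltammogram]:
    """Subtract an iteratively clipped polynomial baseline.

    Returns ``(corrected, baseline)`` with the exact conservation property
    ``corrected.currents + baseline.currents == vg.currents``.  On
    non-convergence within ``max_iter`` iterations a warning is emitted and
    the best fit returned.
    """
    cfg = cfg or BaselineFitConfig()
    n = len(vg)
    if n <= 2 * (cfg.order + 1):
        raise ValueError(
            f"trace has {n} points; need more than {2 * (cfg.order + 1)} "
            f"for an order-{cfg.order} baseline"
        )
    e = vg.potentials
    i = vg.currents
    min_points = 2 * (cfg.order + 1)

    include = np.ones(n, dtype=bool)
    previous_masks: list[np.ndarray] = []
    previous_fit = None
    converged = False
    fitted = np.zeros(n)
    for _ in range(cfg.max_iter):
        coeffs = np.polynomial.polynomial.polyfit(e[include], i[include], cfg.order)
        fitted = np.polynomial.polynomial.polyval(e, coeffs)
        if previous_fit is not None:
            scale = max(float(np.max(np.abs(fitted))), 1e-30)
            if float(np.max(np.abs(fitted - previous_fit))) <= cfg.tol * scale:
                converged = True
                break
        previous_fit = fitted
        residuals = i - fitted
        sd = _robust_sd(residuals[include])
        if sd <= 0:  # residuals flat (noise-free polynomial input): done
            converged = True
            break
        if cfg.clip_rule == "above":
            keep = residuals <= cfg.clip_k * sd
        elif cfg.clip_rule == "below":
            keep = residuals >= -cfg.clip_k * sd
        else:
            keep = np.abs(residuals) <= cfg.clip_k * sd
        if keep.sum() < min_points:  # never starve the fit
            converged = True
            break
        if any(np.array_equal(keep, m) for m in [include, *previous_masks]):
            converged = True  # fixed point or short cycle of the clip mask
            break
        previous_masks = [include]
        include = keep
    if not converged:
        warnings.warn(
            f"baseline fit did not converge within {cfg.max_iter} iterations; "
            "returning the best fit",
            RuntimeWarning,
            stacklevel=2,
        )
    corrected = Voltammogram(
        e.copy(), i - fitted, vg.scan_direction, dict(vg.meta, baseline_corrected=True)
    )
    baseline = Voltammogram(
        e.copy(), fitted, vg.scan_direction, dict(vg.meta, baseline=True)
    )
    return corrected, baseline


def normalize(vg: Voltammogram) -> Voltammogram:
    """Scale currents to unit maximum absolute value (sign-preserving)."""
    scale = float(np.max(np.abs(vg.currents)))
    if scale == 0.0:
        raise ValueError("cannot normalize an all-zero trace")
    return Voltammogram(
        vg.potentials.copy(),
        vg.currents / scale,
        vg.scan_direction,
        dict(vg.meta, normalized=True, normalization_scale=scale),
    )


def preprocess_trace(
    vg: Voltammogram,
    window: tuple[float, float] | None = None,
    baseline_cfg: BaselineFitConfig | None = None,
    normalized: bool = False,
) -> Voltammogram:
    """Standard chain: crop -> baseline-correct -> (optionally) normalize."""
    out = crop(vg, *(window or (None, None)))
    out, _ = correct_baseline(out, baseline_cfg)
    if normalized:
        out = normalize(out)
    return out
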