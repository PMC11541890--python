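"""Rule-based screening decisions: SC positivity, group assignment, interferent flags.

The decision logic mirrors the reference screening method:

* A sample is **positive** for synthetic cathinones when the cathodic sweep
  shows a reduction peak in the R1 window (about -1.45..-1.15 V vs Ag/AgCl).
  The R2 process (about -1.70..-1.45 V) is recorded as supporting evidence
  but is not required, since it has lower sensitivity; samples showing
  neither R1 nor R2 are negative.
* Positive samples are assigned a structural group from the anodic-sweep
  oxidation count: a thiophene marker (oxidations below 0 V) identifies G6;
  otherwise 5, 4, 3 oxidations in the +0.45..+1.40 V window map to G4, G3,
  G2; two oxidations near +0.90/+1.0 V without a +0.60 V peak map to G5;
  one or none maps to G1.  Unmatchable patterns stay positive with no group.
* Mixtures of cathinones are resolved to the group with the larger expected
  anodic-process count.
* Interferent flags: caffeine (+1.30 V oxidation not accounted for by a
  methylenedioxy fingerprint), MDMA/MDEA (paired reductions at -0.70 and
  -0.50 V) and paracetamol (-0.24 V reduction with a +0.21 V oxidation);
  none of these reductions reach the R1/R2 windows, so flags never alter
  positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .peak_library import GROUP_ORDER, MATCH_HALFWIDTH, R1_WINDOW, R2_WINDOW, group_signature
from .peakdetect import (
    DEFAULT_MIN_PROMINENCE_FRACTION,
    DEFAULT_MIN_WIDTH,
    DetectedPeak,
    MatchResult,
    detect_peaks,
    match_peaks,
)
from .simulate import Voltammogram

__all__ = [
    "ClassifierConfig",
    "ScreeningResult",
    "screen",
    "assign_group",
    "resolve_mixture",
    "flag_interferents",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Windows and tolerances of the decision rules (V vs Ag/AgCl)."""

    r1_window: tuple[float, float] = R1_WINDOW
    r2_window: tuple[float, float] = R2_WINDOW
    anodic_count_window: tuple[float, float] = (0.45, 1.40)
    g6_window: tuple[float, float] = (-0.40, -0.10)
    g5_band: tuple[float, float] = (0.80, 1.10)
    o1_window: tuple[float, float] = (0.50, 0.70)  # methylenedioxy O1 at ~+0.60 V
    caffeine_potential: float = 1.30
    mdma_potentials: tuple[float, float] = (-0.70, -0.50)
    paracetamol_reduction: float = -0.24
    paracetamol_oxidation: float = 0.21
    tolerance: float = MATCH_HALFWIDTH  # +/- window for single-potential flags
    caffeine_height_factor: float = 1.5
    min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE_FRACTION
    min_width: float = DEFAULT_MIN_WIDTH
    # Absolute decision floor (uA): extrema below it are instrument noise,
    # not processes.  0.5 uA corresponds to an R1 current well below the
    # method's quantification limit at the standard dilution.
    min_peak_current: float = 0.5


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class ScreeningResult:
    """Outcome of screening one sample (paired anodic/cathodic traces)."""

    positive: bool
    r1_found: bool
    r2_found: bool
    assigned_group: str | None
    anodic_count: int
    interferent_flags: set[str] = field(default_factory=set)
    evidence: list[MatchResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.positive != self.r1_found:
            raise ValueError("positivity must coincide with an R1 detection")
        if self.assigned_group is not None and not self.positive:
            raise ValueError("a group can only be assigned to a positive sample")


def _oxidations(peaks: Sequence[DetectedPeak]) -> list[DetectedPeak]:
    return [p for p in peaks if p.sign == "oxidation"]


def _reductions(peaks: Sequence[DetectedPeak]) -> list[DetectedPeak]:
    return [p for p in peaks if p.sign == "reduction"]


def _in(peak: DetectedPeak, window: tuple[float, float]) -> bool:
    return window[0] <= peak.potential <= window[1]


def _near(peak: DetectedPeak, potential: float, tol: float) -> bool:
    return abs(peak.potential - potential) <= tol


def assign_group(
    anodic_peaks: Sequence[DetectedPeak],
    cathodic_peaks: Sequence[DetectedPeak] = (),
    config: ClassifierConfig | None = None,
) -> str | None:
    """Map an anodic-sweep peak pattern to a structural group G1-G6.

    Decision table, evaluated top-down:

    1. any oxidation in the thiophene window (-0.40..-0.10 V) -> G6;
    2. else count ``n`` of oxidations in +0.45..+1.40 V:
       ``n=5`` -> G4, ``n=4`` -> G3, ``n=3`` -> G2,
       ``n=2`` both near +0.90/+1.0 V with no +0.60 V peak -> G5,
       ``n<=1`` -> G1; anything else -> ``None`` (positive, unclassified).

    Cathodic-sweep oxidations are corroborating evidence only and do not
    enter the rule.
    """
    cfg = config or DEFAULT_CONFIG
    ox = _oxidations(anodic_peaks)
    if any(_in(p, cfg.g6_window) for p in ox):
        return "G6"
    counted = [p for p in ox if _in(p, cfg.anodic_count_window)]
    n = len(counted)
    if n == 5:
        return "G4"
    if n == 4:
        return "G3"
    if n == 3:
        return "G2"
    if n == 2:
        in_band = all(_in(p, cfg.g5_band) for p in counted)
        has_o1 = any(_in(p, cfg.o1_window) for p in counted)
        if in_band and not has_o1:
            return "G5"
        return None
    if n <= 1:
        return "G1"
    return None


def resolve_mixture(candidate_groups: Sequence[str]) -> str:
    """Pick the group with the larger expected anodic-process count.

    For a sample containing cathinones of several groups the whole-trace
    peak pattern is dominated by the richer fingerprint, so mixtures are
    assigned to the candidate with more anodic processes.  Ties break to the
    lower group index.
    """
    if not candidate_groups:
        raise ValueError("resolve_mixture needs at least one candidate group")
    for g in candidate_groups:
        if g not in GROUP_ORDER:
            raise ValueError(f"unknown group {g!r}")
    return max(
        candidate_groups,
        key=lambda g: (group_signature(g).n_anodic_expected, -GROUP_ORDER.index(g)),
    )


def flag_interferents(
    anodic_peaks: Sequence[DetectedPeak],
    cathodic_peaks: Sequence[DetectedPeak],
    config: ClassifierConfig | None = None,
) -> set[str]:
    """Detect common adulterants from their fingerprint peaks.

    Caffeine shares its +1.30 V oxidation with the terminal anodic process
    of the methylenedioxy groups (G2-G4), so it is flagged only when that
    peak appears without the accompanying +0.60 V process, or when it
    dwarfs the next-largest anodic oxidation (height ratio above
    ``caffeine_height_factor``).
    """
    cfg = config or DEFAULT_CONFIG
    flags: set[str] = set()
    tol = cfg.tolerance

    ox = _oxidations(anodic_peaks)
    caffeine_peaks = [p for p in ox if _near(p, cfg.caffeine_potential, tol)]
    if caffeine_peaks:
        has_o1 = any(_in(p, cfg.o1_window) for p in ox)
        peak = max(caffeine_peaks, key=lambda p: p.height)
        others = [p.height for p in ox if p is not peak]
        dominant = bool(others) and peak.height >= cfg.caffeine_height_factor * max(others)
        if not has_o1 or dominant:
            flags.add("caffeine")

    red = _reductions(cathodic_peaks)
    if all(any(_near(p, e, tol) for p in red) for e in cfg.mdma_potentials):
        flags.add("MDMA/MDEA")

    if any(_near(p, cfg.paracetamol_reduction, tol) for p in red) and any(
        _near(p, cfg.paracetamol_oxidation, tol) for p in _oxidations(anodic_peaks)
    ):
        flags.add("paracetamol")

    return flags


def screen_sample(
    anodic_raw: Voltammogram | None,
    cathodic_raw: Voltammogram,
    config: ClassifierConfig | None = None,
    baseline_cfg=None,
) -> ScreeningResult:
    """Full decision pipeline on raw traces: crop, baseline-correct, screen."""
    from .preprocess import correct_baseline, crop

    def prep(vg: Voltammogram) -> Voltammogram:
        corrected, _ = correct_baseline(crop(vg), baseline_cfg)
        return corrected

    anodic = prep(anodic_raw) if anodic_raw is not None else None
    return screen(anodic, prep(cathodic_raw), config)


def screen(
    anodic_vg: Voltammogram | None,
    cathodic_vg: Voltammogram,
    config: ClassifierConfig | None = None,
) -> ScreeningResult:
    """Screen one sample from preprocessed (baseline-corrected) traces.

    The class fingerprint lives in the cathodic sweep, which is therefore
    mandatory; without an anodic sweep the sample can still be called
    positive/negative but no group is assigned.
    """
    cfg = config or DEFAULT_CONFIG
    if cathodic_vg is None:
        raise ValueError("screening requires the cathodic sweep (R1/R2 fingerprint)")

    cathodic_peaks = detect_peaks(
        cathodic_vg, cfg.min_prominence_fraction, cfg.min_width, cfg.min_peak_current
    )
    r_windows = [
        ("R1", cfg.r1_window[0], cfg.r1_window[1]),
        ("R2", cfg.r2_window[0], cfg.r2_window[1]),
    ]
    matches = match_peaks(_reductions(cathodic_peaks), r_windows)
    by_label = {m.label: m for m in matches}
    r1_found = by_label["R1"].found
    r2_found = by_label["R2"].found

    anodic_peaks: list[DetectedPeak] = []
    if anodic_vg is not None:
        anodic_peaks = detect_peaks(
            anodic_vg, cfg.min_prominence_fraction, cfg.min_width, cfg.min_peak_current
        )

    positive = r1_found
    assigned = None
    if positive and anodic_vg is not None:
        assigned = assign_group(anodic_peaks, cathodic_peaks, cfg)

    counted = [
        p for p in _oxidations(anodic_peaks) if _in(p, cfg.anodic_count_window)
    ]
    return ScreeningResult(
        positive=positive,
        r1_found=r1_found,
        r2_found=r2_found,
        assigned_group=assigned,
        anodic_count=len(counted),
        interferent_flags=flag_interferents(anodic_peaks, cathodic_peaks, cfg),
        evidence=matches,
    )
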