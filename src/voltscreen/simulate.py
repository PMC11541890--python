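"""Synthetic DPV trace generator.

No raw voltammograms are deposited with the screening study this package
reproduces, so all analyses run on simulated traces built from the fingerprint
library.  The signal model is deliberately simple and fully documented:

``I(E) = baseline(E) + sum over peaks of
         sign * amplitude_scale * concentration * rel_amplitude
              * gauss(E; Ep', width) + noise``

where ``Ep' = Ep + pH shift + replicate jitter`` and ``gauss`` is a
unit-height Gaussian parameterized by its full width at half maximum.  The baseline is a cubic
polynomial plus exponential solvent-discharge rises at both edges of the
potential window.  Noise is additive white Gaussian with a standard deviation
expressed as a fraction of the trace's largest peak component, which keeps
simulated replicate repeatability inside the repeatability bounds reported
for the real electrode (peak-current RSD < 13%, peak-potential RSD < 1%).

Sweeps cover -2.0 to +2.0 V (anodic, increasing grid) and +2.0 to -2.0 V
(cathodic, decreasing grid) on a 10 mV step, matching the instrument settings
of the reference method (80 mV amplitude, 10 mV step, 50 ms modulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .peak_library import AnalyteProfile, PeakSpec, get_profile, sc_ids

__all__ = [
    "Voltammogram",
    "SimulationParams",
    "PanelSample",
    "simulate_voltammogram",
    "make_fixture_46",
    "simulate_calibration",
    "potential_grid",
    "baseline_current",
    "MIXTURE_SAMPLES",
    "R2_SUPPRESSED_SAMPLES",
    "CAFFEINE_SAMPLES",
    "MDMA_SAMPLES",
    "NEGATIVE_SAMPLES",
]

Composition = Sequence[tuple[str, float]]


@dataclass
class Voltammogram:
    """One DPV trace: potential grid (V vs Ag/AgCl) and currents (uA)."""

    potentials: np.ndarray
    currents: np.ndarray
    scan_direction: str  # "anodic" | "cathodic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape or self.potentials.ndim != 1:
            raise ValueError("potentials and currents must be equal-length 1-D arrays")
        if self.scan_direction not in ("anodic", "cathodic"):
            raise ValueError(f"bad scan direction {self.scan_direction!r}")
        d = np.diff(self.potentials)
        if self.scan_direction == "anodic" and not np.all(d > 0):
            raise ValueError("anodic scans need a strictly increasing grid")
        if self.scan_direction == "cathodic" and not np.all(d < 0):
            raise ValueError("cathodic scans need a strictly decreasing grid")

    def __len__(self) -> int:
        return self.potentials.size

    @property
    def step(self) -> float:
        """Grid step magnitude in V."""
        return float(abs(np.diff(self.potentials)).mean())

    def ascending(self) -> "Voltammogram":
        """Copy with the grid sorted ascending (no-op for anodic scans)."""
        if self.potentials[0] <= self.potentials[-1]:
            return self
        return Voltammogram(
            self.potentials[::-1].copy(),
            self.currents[::-1].copy(),
            # direction metadata is preserved by callers that need it
            "anodic",
            dict(self.meta, flipped_from="cathodic"),
        )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic signal model (units in comments)."""

    step_potential: float = 0.010  # V; sets the grid, as on the instrument
    e_min: float = -2.0  # V, sweep start (anodic) / end (cathodic)
    e_max: float = 2.0  # V
    amplitude_scale: float = 0.05  # uA per (umol/L) per unit rel_amplitude
    baseline_coeffs: tuple[float, ...] = (2.0, 0.5, -0.3, 0.1)  # uA, ascending powers of E
    edge_scale: float = 12.0  # uA at the window edges (solvent discharge)
    edge_decay: float = 0.05  # V, e-folding length of the edge currents
    noise_sd_fraction: float = 0.02  # of the largest peak component height
    potential_jitter_sd: float = 0.005  # V, per-peak replicate jitter
    pH: float = 8.0  # working pH of the supporting electrolyte
    pH_ref: float = 8.0  # pH at which library potentials were recorded
    pH_shift_slope: float = -0.059  # V per pH unit, shared by all peaks

    def __post_init__(self) -> None:
        if self.step_potential <= 0:
            raise ValueError("step_potential must be positive")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.e_min >= self.e_max:
            raise ValueError("need e_min < e_max")

    @property
    def ph_shift(self) -> float:
        """Potential shift (V) applied to every peak at the working pH."""
        return (self.pH - self.pH_ref) * self.pH_shift_slope


DEFAULT_PARAMS = SimulationParams()


def potential_grid(params: SimulationParams, scan_direction: str) -> np.ndarray:
    """Exact potential grid for one sweep, free of float accumulation."""
    n_lo = round(params.e_min / params.step_potential)
    n_hi = round(params.e_max / params.step_potential)
    grid = np.arange(n_lo, n_hi + 1) * params.step_potential
    grid = np.round(grid, 9)
    if scan_direction == "cathodic":
        grid = grid[::-1]
    elif scan_direction != "anodic":
        raise ValueError(f"bad scan direction {scan_direction!r}")
    return grid


def baseline_current(params: SimulationParams, potentials: np.ndarray) -> np.ndarray:
    """Smooth background: cubic polynomial plus signed edge rises (uA)."""
    e = np.asarray(potentials, dtype=float)
    background = np.polynomial.polynomial.polyval(e, params.baseline_coeffs)
    background = background + params.edge_scale * np.exp(
        -(params.e_max - e) / params.edge_decay
    )
    background = background - params.edge_scale * np.exp(
        -(e - params.e_min) / params.edge_decay
    )
    return background


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gauss(e: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Gaussian whose ``width`` is the full width at half maximum."""
    sigma = width * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((e - center) / sigma) ** 2)


def _peak_height(peak: PeakSpec, concentration: float, params: SimulationParams,
                 label_scales: Mapping[str, float] | None) -> float:
    scale = 1.0 if label_scales is None else float(label_scales.get(peak.label, 1.0))
    return params.amplitude_scale * concentration * peak.rel_amplitude * scale


def simulate_voltammogram(
    composition: Composition,
    scan_direction: str,
    params: SimulationParams | None = None,
    seed: int | Sequence[int] | np.random.Generator = 0,
    label_scales: Mapping[str, float] | None = None,
) -> Voltammogram:
    """Simulate one DPV trace for a mixture of library analytes.

    Parameters
    ----------
    composition
        Pairs ``(analyte_id, concentration in umol/L)``; may be empty, in
        which case the trace is the bare baseline plus noise.
    scan_direction
        ``"anodic"`` (grid -2.0 -> +2.0 V) or ``"cathodic"`` (+2.0 -> -2.0 V).
    params
        Signal-model parameters; defaults to :data:`DEFAULT_PARAMS`.
    seed
        Anything accepted by :func:`numpy.random.default_rng`; the trace is
        deterministic given the seed.
    label_scales
        Optional per-label amplitude multipliers (e.g. ``{"R2": 0.0}`` to
        suppress the low-sensitivity second reduction in a sample).

    Raises
    ------
    UnknownAnalyteError
        For analytes missing from the library.
    ValueError
        For non-positive concentrations.
    """
    params = params or DEFAULT_PARAMS
    rng = np.random.default_rng(seed)
    grid = potential_grid(params, scan_direction)
    currents = baseline_current(params, grid)

    profiles: list[tuple[AnalyteProfile, float]] = []
    for analyte_id, conc in composition:
        if conc <= 0:
            raise ValueError(f"concentration for {analyte_id!r} must be positive")
        profiles.append((get_profile(analyte_id), float(conc)))

    max_component = 0.0
    for profile, conc in profiles:
        for peak in profile.peaks(scan_direction):
            height = _peak_height(peak, conc, params, label_scales)
            jitter = rng.normal(0.0, params.potential_jitter_sd)
            center = peak.potential + params.ph_shift + jitter
            currents = currents + peak.current_sign * height * _gauss(
                grid, center, peak.width
            )
            max_component = max(max_component, height)

    if params.noise_sd_fraction > 0:
        # Peak-free traces (blanks/negatives) still carry instrument noise,
        # referenced to a nominal 100 umol/L full-amplitude peak.
        reference = max_component if max_component > 0 else params.amplitude_scale * 100.0
        currents = currents + rng.normal(
            0.0, params.noise_sd_fraction * reference, size=grid.size
        )

    meta = {
        "composition": [(a, c) for a, c in composition],
        "pH": params.pH,
        "scan_direction": scan_direction,
    }
    if label_scales:
        meta["label_scales"] = dict(label_scales)
    return Voltammogram(grid, currents, scan_direction, meta)


# ---------------------------------------------------------------------------
# 46-sample seized-panel fixture
# ---------------------------------------------------------------------------

#: Samples (1-based ids) containing two cathinones from different groups.
MIXTURE_SAMPLES: dict[int, tuple[str, str]] = {
    8: ("methylone", "dibutylone"),  # G2 + G3
    28: ("mephedrone", "MDPV"),  # G1 + G4
}
#: Samples whose R2 process falls below detection (R1-only positives).
R2_SUPPRESSED_SAMPLES = frozenset({7, 26, 27, 30, 32, 40})
#: Samples adulterated with caffeine.
CAFFEINE_SAMPLES = frozenset({3, 19, 20, 23, 25, 29, 30, 33, 34, 35, 36, 38, 39, 41})
#: Samples containing MDMA.
MDMA_SAMPLES = frozenset({7, 46})
#: SC-free samples (46 is the MDMA-only one).
NEGATIVE_SAMPLES = frozenset({13, 22, 44, 46})
_NEGATIVE_BASE: dict[int, list[str]] = {13: ["cocaine"], 22: ["paracetamol"], 44: [], 46: []}

_PANEL_CONCENTRATION = 100.0  # umol/L after the standard extraction/dilution


@dataclass
class PanelSample:
    """One seized-panel sample: paired traces plus ground-truth metadata."""

    sample_id: int
    anodic: Voltammogram
    cathodic: Voltammogram
    truth: dict


def _panel_compositions() -> dict[int, dict]:
    """Ground-truth composition for each of the 46 samples.

    42 samples contain cathinones (two of them mixtures); single-SC samples
    cycle round-robin through the 15 library cathinones so every group G1-G6
    is represented.  Interferent adulterations follow the fixed sample lists
    above.
    """
    cathinones = sc_ids()
    compositions: dict[int, dict] = {}
    rotation = 0
    for sid in range(1, 47):
        analytes: list[str] = []
        groups: list[str] = []
        if sid in NEGATIVE_SAMPLES:
            analytes.extend(_NEGATIVE_BASE[sid])
            positive = False
        elif sid in MIXTURE_SAMPLES:
            analytes.extend(MIXTURE_SAMPLES[sid])
            groups = [get_profile(a).group for a in MIXTURE_SAMPLES[sid]]
            positive = True
        else:
            sc = cathinones[rotation % len(cathinones)]
            rotation += 1
            analytes.append(sc)
            groups = [get_profile(sc).group]
            positive = True
        if sid in CAFFEINE_SAMPLES:
            analytes.append("caffeine")
        if sid in MDMA_SAMPLES:
            analytes.append("MDMA")
        compositions[sid] = {
            "analytes": analytes,
            "groups": groups,
            "sc_positive": positive,
            "caffeine": sid in CAFFEINE_SAMPLES,
            "mdma": sid in MDMA_SAMPLES,
            "r2_suppressed": sid in R2_SUPPRESSED_SAMPLES,
        }
    return compositions


def make_fixture_46(
    params: SimulationParams | None = None, seed: int = 0
) -> list[PanelSample]:
    """Simulate the 46-sample seized panel (42 SC-positive, 4 negative).

    The panel mirrors the published composition summary: two SC mixtures
    (samples 8 and 28), six R1-only samples whose R2 amplitude is set below
    detection (7, 26, 27, 30, 32, 40), caffeine in 14 samples and MDMA in
    two (7 and 46, the latter SC-free).  Per-trace seeds are derived
    deterministically from the top-level seed and the sample index.
    """
    params = params or DEFAULT_PARAMS
    panel: list[PanelSample] = []
    for sid, truth in _panel_compositions().items():
        comp = [(a, _PANEL_CONCENTRATION) for a in truth["analytes"]]
        scales = {"R2": 0.0} if truth["r2_suppressed"] else None
        anodic = simulate_voltammogram(
            comp, "anodic", params, seed=[seed, sid, 0], label_scales=scales
        )
        cathodic = simulate_voltammogram(
            comp, "cathodic", params, seed=[seed, sid, 1], label_scales=scales
        )
        for vg in (anodic, cathodic):
            vg.meta["sample_id"] = sid
        panel.append(
            PanelSample(sample_id=sid, anodic=anodic, cathodic=cathodic, truth=dict(truth))
        )
    return panel


# ---------------------------------------------------------------------------
# Calibration series
# ---------------------------------------------------------------------------

#: Default calibration levels (umol/L): 8 log-spaced points over 1-100.
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = tuple(
    float(c) for c in np.round(np.logspace(0, 2, 8), 1)
)


def simulate_calibration(
    analyte: str,
    concentrations: Sequence[float] | None = None,
    replicates: int = 3,
    params: SimulationParams | None = None,
    seed: int = 0,
    scan_direction: str = "cathodic",
) -> list[Voltammogram]:
    """Simulate a calibration series: ``replicates`` traces per level.

    The cathodic sweep is the default since the calibration response of the
    reference method is the R1 reduction current.  Traces carry
    ``concentration`` and ``replicate`` metadata.
    """
    if concentrations is None:
        concentrations = DEFAULT_CALIBRATION_LEVELS
    if len(concentrations) == 0:
        raise ValueError("need at least one concentration level")
    get_profile(analyte)  # fail fast on unknown analytes
    traces: list[Voltammogram] = []
    for level_idx, conc in enumerate(concentrations):
        for rep in range(replicates):
            vg = simulate_voltammogram(
                [(analyte, float(conc))],
                scan_direction,
                params,
                seed=[seed, level_idx, rep],
            )
            vg.meta.update(concentration=float(conc), replicate=rep)
            traces.append(vg)
    return traces


def with_params(params: SimulationParams | None = None, **overrides) -> SimulationParams:
    """Convenience: copy of ``params`` (default model) with field overrides."""
    return replace(params or DEFAULT_PARAMS, **overrides)
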