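"""Per-analyte electrochemical fingerprint library.

The screening method rests on a small body of reference knowledge: for each
analyte (15 synthetic cathinones, 10 electroactive interferents, 3
electrochemically silent drugs) the potentials, signs and relative sizes of
its DPV peaks in both sweep directions, and for each of the six structural
groups G1-G6 the anodic-process signature used by the classifier.  That
knowledge is shipped as a YAML data file (``data/analytes.yaml``) and exposed
here through typed records.

Conventions
-----------
* Potentials are in V vs Ag/AgCl; oxidations are positive current peaks and
  reductions negative current peaks, in both scan directions.
* Relative amplitudes default to 1.0 for R1, 0.6 for R2 (the R2 process has
  lower sensitivity) and 0.8 for oxidation peaks.
* Peak width defaults to 0.07 V full width at half maximum, a typical DPV
  peak width; both defaults are overridable per peak in the data file.
* Window matching throughout the package uses a +/-0.10 V half-width around
  the library potentials.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import yaml

__all__ = [
    "PeakSpec",
    "AnalyteProfile",
    "GroupSignature",
    "load_library",
    "get_profile",
    "group_signature",
    "sc_ids",
    "interferent_ids",
    "all_ids",
    "R1_WINDOW",
    "R2_WINDOW",
    "DEFAULT_PEAK_WIDTH",
    "MATCH_HALFWIDTH",
    "GROUP_ORDER",
]

#: Cathodic-scan windows (V vs Ag/AgCl) of the two class-diagnostic
#: reduction processes.  R1 spans the -1.40 V family and alpha-PVT's -1.22 V;
#: R2 spans the -1.60 V family and alpha-PVT's -1.47 V.  The boundary at
#: -1.45 V belongs to R2.
R1_WINDOW: tuple[float, float] = (-1.45, -1.15)
R2_WINDOW: tuple[float, float] = (-1.70, -1.45)

DEFAULT_PEAK_WIDTH: float = 0.07  # V, full width at half maximum of DPV peaks
MATCH_HALFWIDTH: float = 0.10  # V, half-width for window matching

GROUP_ORDER: tuple[str, ...] = ("G1", "G2", "G3", "G4", "G5", "G6")

_DEFAULT_REL_AMPLITUDE = {"R1": 1.0, "R2": 0.6}
_DEFAULT_OX_AMPLITUDE = 0.8


@dataclass(frozen=True)
class PeakSpec:
    """One expected redox process of an analyte."""

    label: str  # O1..O5, R1, R2
    potential: float  # V vs Ag/AgCl
    sign: str  # "oxidation" | "reduction"
    rel_amplitude: float = 1.0  # dimensionless, (0, 1]
    width: float = DEFAULT_PEAK_WIDTH  # V, full width at half maximum

    def __post_init__(self) -> None:
        if self.sign not in ("oxidation", "reduction"):
            raise ValueError(f"bad sign {self.sign!r}")
        if not 0.0 < self.rel_amplitude <= 1.0:
            raise ValueError(f"rel_amplitude {self.rel_amplitude} not in (0, 1]")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def current_sign(self) -> int:
        """+1 for oxidation (positive current peak), -1 for reduction."""
        return 1 if self.sign == "oxidation" else -1


@dataclass(frozen=True)
class AnalyteProfile:
    """Expected DPV fingerprint of one analyte in both sweep directions."""

    analyte_id: str
    category: str  # "SC" | "interferent" | "silent"
    group: str | None  # G1..G6 for SCs, None otherwise
    peaks_anodic: tuple[PeakSpec, ...]
    peaks_cathodic: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if self.category not in ("SC", "interferent", "silent"):
            raise ValueError(f"bad category {self.category!r}")
        if self.category == "silent" and (self.peaks_anodic or self.peaks_cathodic):
            raise ValueError(f"{self.analyte_id}: silent analytes carry no peaks")
        if self.category == "SC":
            if self.group not in GROUP_ORDER:
                raise ValueError(f"{self.analyte_id}: SC needs a group G1-G6")
            self._require_cathodic_fingerprint()

    def _require_cathodic_fingerprint(self) -> None:
        def in_window(label: str, window: tuple[float, float]) -> bool:
            return any(
                p.label == label
                and p.sign == "reduction"
                and window[0] <= p.potential <= window[1]
                for p in self.peaks_cathodic
            )

        if not in_window("R1", R1_WINDOW) or not in_window("R2", R2_WINDOW):
            raise ValueError(
                f"{self.analyte_id}: SC profiles need cathodic-scan R1 in "
                f"{R1_WINDOW} and R2 in {R2_WINDOW}"
            )

    def peaks(self, scan_direction: str) -> tuple[PeakSpec, ...]:
        if scan_direction == "anodic":
            return self.peaks_anodic
        if scan_direction == "cathodic":
            return self.peaks_cathodic
        raise ValueError(f"bad scan direction {scan_direction!r}")


@dataclass(frozen=True)
class GroupSignature:
    """Anodic-process signature of one structural group."""

    group_id: str
    n_anodic_expected: int
    anodic_windows: tuple[tuple[float, float], ...]
    special_markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.n_anodic_expected <= 5:
            raise ValueError("n_anodic_expected must be in 0..5")
        for lo, hi in self.anodic_windows:
            if not (-2.0 <= lo < hi <= 2.0):
                raise ValueError(f"window ({lo}, {hi}) outside [-2, +2] V")


class UnknownAnalyteError(KeyError):
    """Raised when an analyte id is not in the library."""


class UnknownGroupError(KeyError):
    """Raised when a group id is not G1-G6."""


def _peak_from_record(rec: dict) -> PeakSpec:
    label = rec["label"]
    sign = rec.get("sign") or ("reduction" if label.startswith("R") else "oxidation")
    default_amp = _DEFAULT_REL_AMPLITUDE.get(label, _DEFAULT_OX_AMPLITUDE)
    if sign == "reduction" and not label.startswith("R"):
        default_amp = 0.6
    return PeakSpec(
        label=label,
        potential=float(rec["potential"]),
        sign=sign,
        rel_amplitude=float(rec.get("rel_amplitude", default_amp)),
        width=float(rec.get("width", DEFAULT_PEAK_WIDTH)),
    )


def _default_library_path() -> Path:
    return Path(importlib.resources.files("voltscreen") / "data" / "analytes.yaml")


@lru_cache(maxsize=4)
def load_library(path: str | Path | None = None) -> dict[str, AnalyteProfile]:
    """Load the analyte library, keyed by analyte id.

    Parameters
    ----------
    path
        YAML file with ``analytes:`` and ``groups:`` sections; defaults to the
        packaged library.
    """
    raw = yaml.safe_load(Path(path or _default_library_path()).read_text())
    library: dict[str, AnalyteProfile] = {}
    for rec in raw["analytes"]:
        profile = AnalyteProfile(
            analyte_id=rec["analyte_id"],
            category=rec["category"],
            group=rec.get("group"),
            peaks_anodic=tuple(_peak_from_record(p) for p in rec.get("anodic", [])),
            peaks_cathodic=tuple(_peak_from_record(p) for p in rec.get("cathodic", [])),
        )
        if profile.analyte_id in library:
            raise ValueError(f"duplicate analyte id {profile.analyte_id!r}")
        library[profile.analyte_id] = profile
    return library


@lru_cache(maxsize=4)
def _load_groups(path: str | Path | None = None) -> dict[str, GroupSignature]:
    raw = yaml.safe_load(Path(path or _default_library_path()).read_text())
    return {
        rec["group_id"]: GroupSignature(
            group_id=rec["group_id"],
            n_anodic_expected=int(rec["n_anodic_expected"]),
            anodic_windows=tuple(tuple(w) for w in rec["anodic_windows"]),
            special_markers=dict(rec.get("special_markers") or {}),
        )
        for rec in raw["groups"]
    }


def get_profile(analyte_id: str, path: str | Path | None = None) -> AnalyteProfile:
    """Return the fingerprint of one analyte; raise UnknownAnalyteError if absent."""
    library = load_library(path)
    try:
        return library[analyte_id]
    except KeyError:
        raise UnknownAnalyteError(
            f"analyte {analyte_id!r} is not in the fingerprint library; "
            f"known ids: {sorted(library)}"
        ) from None


def group_signature(group_id: str, path: str | Path | None = None) -> GroupSignature:
    """Return the anodic-process signature of one group G1-G6."""
    groups = _load_groups(path)
    try:
        return groups[group_id]
    except KeyError:
        raise UnknownGroupError(
            f"group {group_id!r} unknown; expected one of {GROUP_ORDER}"
        ) from None


def sc_ids(path: str | Path | None = None) -> list[str]:
    """Ids of the 15 synthetic cathinones, in library order."""
    return [a for a, p in load_library(path).items() if p.category == "SC"]


def interferent_ids(path: str | Path | None = None) -> list[str]:
    """Ids of the 13 interferents (electroactive and silent), in library order."""
    return [a for a, p in load_library(path).items() if p.category != "SC"]


def all_ids(path: str | Path | None = None) -> list[str]:
    return list(load_library(path))
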