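"""Sieve-class arithmetic: collapse raw particle-size distributions onto the
12 standard sieve classes and summarise them as Wentworth fractions.

Particle-size data arrive as percentage weight retained per sieve aperture
(up to ~99 distinct apertures across laboratories). They are first collapsed
onto a common set of 12 standard classes (11 apertures from 64 mm down to
0.063 mm, plus the pan), and then summarised into the Wentworth size fractions
used throughout the monitoring method: silt/clay (S/C), fine/medium/coarse sand
(fS/mS/cS), fine/medium/coarse gravel (fG/mG/cG), with cobbles (>= 64 mm) kept
as a remainder outside the 7-vector.

"Retained-on" semantics apply throughout: mass reported against aperture *a*
passed every coarser sieve and was retained on *a*; the pan (aperture 0) holds
everything finer than 0.063 mm. The aperture->fraction boundaries are a
configurable mapping because published sieve/fraction tables are not always
unambiguous about which sieves feed fine vs medium gravel; the defaults below
are lower-bound-inclusive Wentworth intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Standard sieve apertures (mm), coarse to fine; the pan is coded as 0.0.
STANDARD_APERTURES_MM: tuple[float, ...] = (
    64.0, 32.0, 16.0, 8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.063, 0.0,
)

#: The 7 Wentworth fractions of the test vector, fine to coarse.
WENTWORTH_FRACTIONS: tuple[str, ...] = ("S/C", "fS", "mS", "cS", "fG", "mG", "cG")

#: Lower-inclusive aperture intervals (mm) for each fraction. Cobbles (>=64 mm)
#: are tracked separately and excluded from the 7-vector.
DEFAULT_FRACTION_BOUNDS: dict[str, tuple[float, float]] = {
    "S/C": (0.0, 0.063),
    "fS": (0.063, 0.25),
    "mS": (0.25, 0.5),
    "cS": (0.5, 2.0),
    "fG": (2.0, 4.0),
    "mG": (4.0, 16.0),
    "cG": (16.0, 64.0),
}

COBBLES_MIN_MM = 64.0


class ApertureError(ValueError):
    """An input sieve aperture falls outside the configured mapping range."""


@dataclass(frozen=True)
class SieveMapping:
    """Data-driven mapping from arbitrary apertures onto standard classes.

    An input aperture maps to the largest standard aperture not exceeding it
    (retained-on semantics). Apertures at or above ``max_aperture_mm`` are
    rejected — material that coarse should have been recorded against the
    64 mm (cobbles) sieve directly.
    """

    standard_apertures_mm: tuple[float, ...] = STANDARD_APERTURES_MM
    max_aperture_mm: float = 100.0
    fraction_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_BOUNDS)
    )

    def standard_class(self, aperture_mm: float) -> float:
        if not (0.0 <= aperture_mm < self.max_aperture_mm) or math.isnan(aperture_mm):
            raise ApertureError(
                f"aperture {aperture_mm!r} mm outside mapping range "
                f"[0, {self.max_aperture_mm}) mm"
            )
        candidates = [a for a in self.standard_apertures_mm if a <= aperture_mm]
        return max(candidates)

    def fraction_of(self, standard_aperture_mm: float) -> str:
        """Wentworth fraction name for a standard class; 'cobbles' above 64 mm."""
        if standard_aperture_mm >= COBBLES_MIN_MM:
            return "cobbles"
        for name, (lo, hi) in self.fraction_bounds.items():
            if lo <= standard_aperture_mm < hi:
                return name
        raise ApertureError(
            f"standard aperture {standard_aperture_mm!r} mm not covered by fraction bounds"
        )


DEFAULT_MAPPING = SieveMapping()


@dataclass(frozen=True)
class WentworthComposition:
    """Percentage weight per Wentworth fraction, plus a cobbles remainder.

    ``fractions`` holds the 7-vector (S/C, fS, mS, cS, fG, mG, cG) used by the
    sediment envelope and change test; ``cobbles`` is material >= 64 mm, kept
    so the composition still conserves the input total.
    """

    fractions: dict[str, float]
    cobbles: float = 0.0

    def __post_init__(self) -> None:
        missing = set(WENTWORTH_FRACTIONS) - set(self.fractions)
        if missing:
            raise ValueError(f"missing Wentworth fractions: {sorted(missing)}")
        bad = {k: v for k, v in self.fractions.items() if v < 0}
        if bad or self.cobbles < 0:
            raise ValueError(f"negative fraction percentages: {bad or self.cobbles}")

    def as_vector(self) -> np.ndarray:
        """The 7-vector in canonical fine-to-coarse order."""
        return np.array([self.fractions[f] for f in WENTWORTH_FRACTIONS], dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()) + self.cobbles)

    @property
    def mud(self) -> float:
        return self.fractions["S/C"]

    @property
    def sand(self) -> float:
        return self.fractions["fS"] + self.fractions["mS"] + self.fractions["cS"]

    @property
    def gravel(self) -> float:
        return self.fractions["fG"] + self.fractions["mG"] + self.fractions["cG"]


def collapse_to_standard_sieves(
    psd: dict[float, float], mapping: SieveMapping = DEFAULT_MAPPING
) -> dict[float, float]:
    """Collapse a raw aperture->percent PSD onto the 12 standard classes.

    Mass-conserving: the output percentages sum to the input total exactly
    (floating-point addition aside). Unknown or out-of-range apertures raise
    :class:`ApertureError` listing the offending aperture.
    """
    out = {a: 0.0 for a in mapping.standard_apertures_mm}
    for aperture, pct in psd.items():
        if pct < 0:
            raise ValueError(f"negative percent retained ({pct}) on {aperture} mm sieve")
        out[mapping.standard_class(float(aperture))] += float(pct)
    return out


def to_wentworth(
    std_psd: dict[float, float], mapping: SieveMapping = DEFAULT_MAPPING
) -> WentworthComposition:
    """Summarise a 12-class PSD into Wentworth fractions + cobbles."""
    fracs = {name: 0.0 for name in WENTWORTH_FRACTIONS}
    cobbles = 0.0
    for aperture, pct in std_psd.items():
        name = mapping.fraction_of(float(aperture))
        if name == "cobbles":
            cobbles += float(pct)
        else:
            fracs[name] += float(pct)
    return WentworthComposition(fractions=fracs, cobbles=cobbles)


def psd_from_long(rows) -> dict[float, float]:
    """Build an aperture->percent dict from (aperture_mm, percent) pairs,
    summing duplicate apertures."""
    psd: dict[float, float] = {}
    for aperture, pct in rows:
        a = float(aperture)
        psd[a] = psd.get(a, 0.0) + float(pct)
    return psd
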