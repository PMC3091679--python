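"""Spectrophotometric assay conversions: chlorophyll, anthocyanin, lignin.

The pigment conversions are the fixed linear combinations of optical
densities used with the 80% acetone (chlorophyll) and acidified methanol
(anthocyanin) extractions:

    chlorophyll  (μg) = OD663 × 7.15 + OD647 × 18.71
    anthocyanin  (μg) = OD530 − 0.25 × OD657

Lignin thioglycolate absorbance at 280 nm is converted to μg through a
linear standard curve fitted by ordinary least squares to alkali-lignin
standards.  The conversions return instrument-scale quantities; per-gram
reporting is an optional division by the recorded sample mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

CHL_COEF_663 = 7.15
CHL_COEF_647 = 18.71
ANTH_BLANK_FACTOR = 0.25


def _check_od(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"optical density {name} must be finite and ≥ 0, got {value}")
    return value


def chlorophyll(do663: float, do647: float) -> float:
    """Total chlorophyll (μg) from OD at 663 and 647 nm."""
    return _check_od("DO663", do663) * CHL_COEF_663 + _check_od("DO647", do647) * CHL_COEF_647


def anthocyanin(do530: float, do657: float) -> float:
    """Anthocyanin (μg) from OD at 530 nm, blanked by 0.25 × OD657.

    The result can be negative when the 657-nm blank exceeds the 530-nm
    reading (a below-blank sample); callers should treat negative values
    as flagged, not as mass.
    """
    return _check_od("DO530", do530) - ANTH_BLANK_FACTOR * _check_od("DO657", do657)


def below_blank(micrograms: float) -> bool:
    """True when a pigment conversion fell below the blank (negative mass)."""
    return micrograms < 0


@dataclass(frozen=True)
class Calibration:
    """Linear absorbance → mass standard curve (μg = slope × A + intercept)."""

    slope: float
    intercept: float
    standard: str = "lignin alkali"
    a_min: float = float("-inf")
    a_max: float = float("inf")

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    @classmethod
    def fit(cls, absorbances: Sequence[float], masses: Sequence[float],
            standard: str = "lignin alkali") -> "Calibration":
        """Ordinary-least-squares fit of mass on absorbance (≥ 2 standards)."""
        a = np.asarray(absorbances, dtype=float)
        m = np.asarray(masses, dtype=float)
        if a.size < 2 or a.size != m.size:
            raise ValueError("calibration needs ≥ 2 paired standard points")
        if np.ptp(a) == 0:
            raise ValueError("degenerate calibration: all standards at one absorbance")
        slope, intercept = np.polyfit(a, m, 1)
        return cls(slope=float(slope), intercept=float(intercept), standard=standard,
                   a_min=float(a.min()), a_max=float(a.max()))

    def in_range(self, absorbance: float) -> bool:
        return self.a_min <= absorbance <= self.a_max


def lignin(a280: float, cal: Calibration) -> float:
    """Lignin (μg) from thioglycolate absorbance at 280 nm via ``cal``."""
    a280 = _check_od("A280", a280)
    return cal.slope * a280 + cal.intercept


@dataclass
class AssayRecord:
    """Absorbance readings of one sample plus optional mass metadata.

    ``readings`` maps wavelength (nm) to optical density; ``fresh_mass_g``
    enables per-gram reporting via :meth:`per_gram`.
    """

    readings: dict[float, float]
    fresh_mass_g: float | None = None

    def od(self, wavelength: float) -> float:
        if wavelength not in self.readings:
            raise KeyError(f"no reading at {wavelength} nm")
        return _check_od(f"OD{wavelength:g}", self.readings[wavelength])

    def chlorophyll(self) -> float:
        return chlorophyll(self.od(663), self.od(647))

    def anthocyanin(self) -> float:
        return anthocyanin(self.od(530), self.od(657))

    def lignin(self, cal: Calibration) -> float:
        return lignin(self.od(280), cal)

    def per_gram(self, micrograms: float) -> float:
        """μg per gram fresh weight (requires ``fresh_mass_g``)."""
        if self.fresh_mass_g is None or self.fresh_mass_g <= 0:
            raise ValueError("per-gram reporting requires a positive fresh_mass_g")
        return micrograms / self.fresh_mass_g
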