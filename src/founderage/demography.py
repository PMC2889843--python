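"""Demographic arithmetic: per-generation growth rates and year conversions.

The population model is constant exponential growth, ``p1 = p0 * r**g``, with
``r`` the multiplicative fold-growth per generation and ``g`` the (possibly
fractional) number of generations between two census years at a fixed number
of years per generation (default 25).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


class DemographyError(ValueError):
    """Invalid demographic input."""


def growth_rate(
    p0: float,
    p1: float,
    year0: float,
    year1: float,
    years_per_generation: float = 25.0,
) -> float:
    """Per-generation fold growth rate between two census points.

    g = (year1 - year0) / years_per_generation; r = (p1/p0)**(1/g).
    Fractional generation counts are kept exact (no rounding before
    exponentiation).
    """
    if p0 <= 0 or p1 <= 0:
        raise DemographyError("population sizes must be > 0")
    if year1 <= year0:
        raise DemographyError("year1 must exceed year0")
    if years_per_generation <= 0:
        raise DemographyError("years_per_generation must be > 0")
    g = (year1 - year0) / years_per_generation
    return (p1 / p0) ** (1.0 / g)


class YearConversion(NamedTuple):
    years: float
    calendar_year: float | None


def generations_to_years(
    g: float,
    years_per_generation: float = 25.0,
    reference_year: float | None = None,
) -> YearConversion:
    """Convert an age in generations to years before a reference.

    Returns ``(years, calendar_year)``; ``calendar_year`` is ``None`` when no
    reference year is given.
    """
    if g < 0:
        raise DemographyError("g must be >= 0")
    years = g * years_per_generation
    cal = None if reference_year is None else reference_year - years
    return YearConversion(years, cal)


@dataclass(frozen=True)
class GrowthModel:
    """A census pair with its implied growth rate."""

    p0: float
    p1: float
    year0: float
    year1: float
    years_per_generation: float = 25.0

    def __post_init__(self):
        # reuse validation
        growth_rate(self.p0, self.p1, self.year0, self.year1, self.years_per_generation)

    @property
    def generations(self) -> float:
        return (self.year1 - self.year0) / self.years_per_generation

    @property
    def r(self) -> float:
        return growth_rate(
            self.p0, self.p1, self.year0, self.year1, self.years_per_generation
        )

    def project(self, g: float) -> float:
        """Population size g generations after year0."""
        return self.p0 * self.r**g
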