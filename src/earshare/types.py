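"""Record types for a wheat grain-filling isotope trial.

The unit of observation throughout the package is the field *plot*
(genotype x replicate).  Raw measurements are carried as small frozen
dataclasses; the mixing model consumes per-plot aggregated
:class:`PlotIsotopeProfile` objects built from them.

delta13C values are carried in per-mil (permil, ‰) versus VPDB everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

#: Plant parts for which delta13C is measured.
ORGANS = ("flag_leaf", "peduncle", "glumes", "awns", "grains")

#: Chemical fraction analysed: bulk dry matter, the water-soluble fraction
#: (sugar-rich extract representing recent assimilates), or respired CO2.
FRACTIONS = ("DM", "WSF", "respired_CO2")

#: Sampling occasions: the two mid-grain-filling samplings bracketing an
#: auxiliary irrigation, and physiological maturity (grains only).
OCCASIONS = ("before_irrigation", "after_irrigation", "maturity")

#: Plausible delta13C range for C3 plant material, permil vs VPDB.
C3_DELTA_RANGE = (-40.0, -10.0)

#: Canopy strata for ceptometer PAR profiles, top of canopy downward.
PAR_STRATA = ("ear_base", "flag_leaf", "penultimate_leaf", "third_leaf")


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable layout."""


class IntegrityError(ValueError):
    """Records violate a uniqueness or consistency constraint."""


class DegenerateEndMembersError(ValueError):
    """The two source pools have identical delta13C; the mixture is unidentifiable."""


@dataclass(frozen=True)
class OrganIsotopeRecord:
    """One delta13C measurement of one organ fraction on one occasion."""

    plot_id: str
    genotype: str
    replicate: int
    organ: str
    fraction: str
    occasion: str
    delta13C: float

    def validate(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.occasion not in OCCASIONS:
            raise ValueError(f"unknown occasion {self.occasion!r}")
        if not math.isfinite(self.delta13C):
            raise ValueError("delta13C must be finite")
        lo, hi = C3_DELTA_RANGE
        if self.fraction != "respired_CO2" and not (lo <= self.delta13C <= hi):
            raise ValueError(
                f"delta13C {self.delta13C} permil outside the C3 range [{lo}, {hi}]"
            )
        if self.organ == "grains" and self.occasion != "maturity":
            raise ValueError("grain delta13C is only measured at maturity")

    @property
    def key(self) -> tuple:
        return (self.plot_id, self.organ, self.fraction, self.occasion)


@dataclass(frozen=True)
class PlotIsotopeProfile:
    """Per-plot end-member and grain delta13C, the mixing model's unit of analysis.

    End members are occasion-averaged WSF values; the grain value is bulk
    dry matter at maturity.
    """

    plot_id: str
    delta_awns: float
    delta_peduncle: float
    delta_flag: Optional[float] = None
    delta_glumes: Optional[float] = None
    delta_grain: float = float("nan")
    grain_yield: Optional[float] = None
    #: occasions actually averaged per organ, e.g. {"awns": ("before_irrigation",)}
    occasions_used: dict = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        for name in ("delta_awns", "delta_peduncle", "delta_grain"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be finite for plot {self.plot_id}")

    def end_member(self, organ: str) -> float:
        """delta13C of a named end member ('awns', 'peduncle' or 'flag_leaf')."""
        if organ == "awns":
            return self.delta_awns
        if organ == "peduncle":
            return self.delta_peduncle
        if organ == "flag_leaf":
            if self.delta_flag is None:
                raise ValueError(f"plot {self.plot_id} has no flag-leaf value")
            return self.delta_flag
        raise ValueError(f"unknown end member {organ!r}")


@dataclass(frozen=True)
class GasExchangeRecord:
    """Whole-organ gas-exchange rates (umol CO2 organ^-1 s^-1)."""

    plot_id: str
    organ: str  # "flag_leaf" or "ear"
    net_photosynthesis: float
    dark_respiration: float
    organ_area: Optional[float] = None  # m^2

    def validate(self) -> None:
        if self.organ not in ("flag_leaf", "ear"):
            raise ValueError(f"gas exchange organ must be flag_leaf or ear, got {self.organ!r}")
        if self.dark_respiration < 0:
            raise ValueError("dark_respiration is a positive magnitude")
        if self.organ_area is not None and self.organ_area <= 0:
            raise ValueError("organ_area must be positive")


@dataclass(frozen=True)
class SpadSeries:
    """Weekly SPAD chlorophyll readings for one plot's flag leaves."""

    plot_id: str
    dates: Sequence[float]  # days after heading, strictly increasing
    spad_values: Sequence[float]

    def validate(self) -> None:
        if len(self.dates) != len(self.spad_values):
            raise ValueError("dates and spad_values differ in length")
        if len(self.dates) == 0:
            raise ValueError(f"empty SPAD series for plot {self.plot_id}")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("SPAD dates must be strictly increasing")


@dataclass(frozen=True)
class ParProfile:
    """Ceptometer PAR profile: incident plus transmitted PAR below each stratum."""

    plot_id: str
    incident: float  # umol photon m^-2 s^-1
    transmitted: Sequence[tuple]  # (stratum_label, PAR below stratum), top down

    def validate(self) -> None:
        if self.incident <= 0:
            raise ValueError("incident PAR must be positive")
        labels = [s for s, _ in self.transmitted]
        if tuple(labels) != PAR_STRATA[: len(labels)]:
            raise ValueError(
                f"strata must be {PAR_STRATA} top-down, got {tuple(labels)}"
            )
        prev = self.incident
        for label, value in self.transmitted:
            if not 0 <= value <= self.incident:
                raise ValueError(f"transmitted PAR at {label} outside [0, incident]")
            if value > prev + 1e-9:
                raise ValueError(
                    f"transmitted PAR increases with depth at stratum {label!r}"
                )
            prev = value
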