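"""Whole-organ photosynthetic carbohydrate budget from heading to senescence.

Gross photosynthesis (net CO2 uptake plus dark respiration) is integrated
over the saturating-light part of the day and the organ's active duration,
and converted to carbohydrate mass assuming every fixed CO2 becomes one
CH2O unit.  The flag leaf's active duration ends when its SPAD chlorophyll
reading drops below a threshold (20 by default); ear senescence is an
observed date and is passed in directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GasExchangeRecord, SpadSeries

#: g/mol of one CH2O carbohydrate unit (12.011 + 2*1.008 + 15.999).
CH2O_MOLAR_MASS = 30.026

#: Default duration of the daylight period with saturating PPFD, h/day.
#: A sensitivity parameter, not a measured constant.
DEFAULT_DAYLIGHT_HOURS = 10.0

#: SPAD reading below which the flag leaf is considered senesced.
SPAD_SENESCENCE_THRESHOLD = 20.0


@dataclass(frozen=True)
class ActiveDuration:
    days: float
    censored: bool  # True when SPAD never crossed the threshold


@dataclass(frozen=True)
class OrganBudget:
    """Accumulated whole-organ photosynthesis over the grain-filling period."""

    organ: str
    gross_photosynthesis: float  # umol CO2 organ^-1 s^-1
    daylight_hours: float  # h/day at saturating PPFD
    active_days: float  # heading -> senescence
    carbohydrate_mass: float  # g CH2O organ^-1
    censored_duration: bool = False


def gross_photosynthesis(net: float, dark_respiration: float) -> float:
    """Gross CO2 fixation = net photosynthesis + dark respiration (umol organ^-1 s^-1)."""
    if dark_respiration < 0:
        raise ValueError("dark_respiration is a positive magnitude")
    return net + dark_respiration


def flag_leaf_active_days(
    spad: SpadSeries,
    threshold: float = SPAD_SENESCENCE_THRESHOLD,
    heading_day: float = 0.0,
) -> ActiveDuration:
    """Days from heading until the SPAD series first drops below ``threshold``.

    The crossing is located by linear interpolation between the bracketing
    weekly measurements; a reading exactly at the threshold counts as the
    crossing.  If the series never reaches the threshold the last
    observation day is used and the result flagged as censored.
    """
    spad.validate()
    days = np.asarray(spad.dates, float)
    vals = np.asarray(spad.spad_values, float)
    for i, v in enumerate(vals):
        if v <= threshold:
            if v == threshold or i == 0:
                return ActiveDuration(days[i] - heading_day, censored=False)
            d0, d1 = days[i - 1], days[i]
            v0, v1 = vals[i - 1], vals[i]
            crossing = d0 + (v0 - threshold) / (v0 - v1) * (d1 - d0)
            return ActiveDuration(crossing - heading_day, censored=False)
    return ActiveDuration(days[-1] - heading_day, censored=True)


def accumulated_carbohydrates(
    gross: float, daylight_hours: float, active_days: float
) -> float:
    """g CH2O fixed by the organ over its active period.

    mass = gross[umol/s] * 1e-6 * daylight_hours * 3600 * active_days
           * 30.026 g/mol; exactly multilinear in the three factors.
    """
    if gross < 0 or daylight_hours < 0 or active_days < 0:
        raise ValueError("all budget factors must be non-negative")
    return gross * 1e-6 * daylight_hours * 3600.0 * active_days * CH2O_MOLAR_MASS


def organ_budget(
    gasex: GasExchangeRecord,
    active_days: float,
    daylight_hours: float = DEFAULT_DAYLIGHT_HOURS,
    censored: bool = False,
) -> OrganBudget:
    """Budget for one organ from its gas-exchange record and active duration."""
    gasex.validate()
    gross = gross_photosynthesis(gasex.net_photosynthesis, gasex.dark_respiration)
    mass = accumulated_carbohydrates(max(gross, 0.0), daylight_hours, active_days)
    return OrganBudget(
        organ=gasex.organ,
        gross_photosynthesis=gross,
        daylight_hours=daylight_hours,
        active_days=active_days,
        carbohydrate_mass=mass,
        censored_duration=censored,
    )


def budget_table(
    gasex_records,
    spad_by_plot: dict,
    ear_active_days: float,
    daylight_hours: float = DEFAULT_DAYLIGHT_HOURS,
    heading_day: float = 0.0,
    spad_threshold: float = SPAD_SENESCENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-plot, per-organ budgets.

    Flag-leaf duration comes from each plot's SPAD series; the ear's active
    duration (visually scored peduncle colour change) is supplied as a
    single observed value in days after heading.
    """
    rows = []
    for rec in gasex_records:
        if rec.organ == "flag_leaf":
            series = spad_by_plot.get(rec.plot_id)
            if series is None:
                raise ValueError(f"no SPAD series for plot {rec.plot_id}")
            dur = flag_leaf_active_days(series, spad_threshold, heading_day)
            b = organ_budget(rec, dur.days, daylight_hours, censored=dur.censored)
        else:
            b = organ_budget(rec, ear_active_days, daylight_hours)
        rows.append(
            {
                "plot_id": rec.plot_id,
                "organ": b.organ,
                "gross_photosynthesis": b.gross_photosynthesis,
                "active_days": b.active_days,
                "daylight_hours": b.daylight_hours,
                "carbohydrate_g": b.carbohydrate_mass,
                "censored_duration": b.censored_duration,
            }
        )
    return pd.DataFrame(rows)


def compare_organ_budgets(table: pd.DataFrame):
    """One-way ANOVA of accumulated carbohydrates between organs.

    Returns the :class:`~earshare.stats.AnovaResult`; with equal ear and
    flag-leaf whole-organ budgets the comparison is non-significant.
    """
    from .stats import one_way_anova

    groups = {
        organ: sub["carbohydrate_g"].to_numpy()
        for organ, sub in table.groupby("organ")
    }
    return one_way_anova(groups)
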