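"""Carbon-isotope arithmetic and organ-level summaries.

All delta13C values are expressed in per-mil (‰) relative to the VPDB
standard: delta = 1000 * (R_sample / R_standard - 1), with R the 13C/12C
molar ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import OrganIsotopeRecord

#: 13C/12C ratio of the VPDB standard (Craig's value); used only as a
#: convenience default when converting raw ratios.
R_VPDB = 0.0112372


@dataclass(frozen=True)
class IsotopeRatio:
    """A raw 13C/12C sample ratio with its (VPDB-calibrated) standard ratio."""

    r_sample: float
    r_standard: float = R_VPDB

    def validate(self) -> None:
        if self.r_sample <= 0 or self.r_standard <= 0:
            raise ValueError("isotope ratios must be strictly positive")

    @property
    def delta_permil(self) -> float:
        return delta_from_ratios(self.r_sample, self.r_standard)


def delta_from_ratios(r_sample: float, r_standard: float = R_VPDB) -> float:
    """delta13C (‰) from the sample and standard 13C/12C ratios.

    delta = 1000 * (r_sample / r_standard - 1).
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be strictly positive")
    return 1000.0 * (r_sample / r_standard - 1.0)


def ratio_from_delta(delta_permil: float, r_standard: float = R_VPDB) -> float:
    """Inverse of :func:`delta_from_ratios`."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be strictly positive")
    r = r_standard * (1.0 + delta_permil / 1000.0)
    if r <= 0:
        raise ValueError(f"delta {delta_permil} permil implies a non-positive ratio")
    return r


def discrimination(delta_air: float, delta_plant: float) -> float:
    """Carbon isotope discrimination Delta13C (‰), Farquhar convention.

    Delta = (delta_air - delta_plant) / (1 + delta_plant/1000).

    Auxiliary: the partitioning pipeline works directly on delta13C and
    never depends on this transform.
    """
    denom = 1.0 + delta_plant / 1000.0
    if denom <= 0:
        raise ValueError("delta_plant must exceed -1000 permil")
    return (delta_air - delta_plant) / denom


def organ_summary(
    records: Iterable[OrganIsotopeRecord],
    group_keys: Sequence[str] = ("organ", "fraction", "occasion"),
) -> pd.DataFrame:
    """Group means with standard errors, one row per group.

    Parameters
    ----------
    records
        Organ isotope records.
    group_keys
        Record attributes to group by, e.g. ``("organ", "fraction",
        "occasion")`` for a table-of-organs layout or ``("genotype",)`` for
        genotype means.

    Returns
    -------
    DataFrame with columns ``mean``, ``se`` (NaN when n = 1) and ``n``.
    SE = sd / sqrt(n) with the sample (ddof=1) standard deviation.
    """
    rows = [
        {**{k: getattr(r, k) for k in group_keys}, "delta13C": r.delta13C}
        for r in records
    ]
    if not rows:
        raise ValueError("no records to summarise")
    df = pd.DataFrame(rows)
    grouped = df.groupby(list(group_keys), sort=True)["delta13C"]
    out = grouped.agg(
        mean="mean",
        se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="size",
    ).reset_index()
    return out


def summary_to_csv(summary: pd.DataFrame, path) -> None:
    """Write an :func:`organ_summary` table to CSV (layout mirrors the trial tables)."""
    summary.to_csv(path, index=False, float_format="%.6g")
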