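"""Per-stratum canopy PAR interception from ceptometer profiles.

The ceptometer records incident PAR above the canopy and transmitted PAR
below each stratum (ear base, flag leaf + peduncle, penultimate leaf, third
leaf, top down).  The fraction intercepted by a stratum is the exact
difference between the PAR above and below it, relative to incident; no
extinction model is fitted.
"""

from __future__ import annotations

import pandas as pd

from .types import ParProfile


def stratum_interception(profile: ParProfile) -> pd.DataFrame:
    """Percent of incident PAR intercepted by each canopy stratum.

    For stratum k (top down): intercepted_k = (PAR above k - PAR below k)
    / incident * 100, with "above" the top stratum being the incident
    reading.  A final ``residual_transmitted`` row carries the fraction
    passing below the lowest stratum, so the rows sum to 100%.
    """
    profile.validate()
    rows = []
    above = profile.incident
    for label, below in profile.transmitted:
        rows.append(
            {
                "plot_id": profile.plot_id,
                "stratum": label,
                "intercepted_pct": (above - below) / profile.incident * 100.0,
            }
        )
        above = below
    rows.append(
        {
            "plot_id": profile.plot_id,
            "stratum": "residual_transmitted",
            "intercepted_pct": above / profile.incident * 100.0,
        }
    )
    return pd.DataFrame(rows)


def interception_table(profiles) -> pd.DataFrame:
    """Stacked interception table for many plots."""
    return pd.concat(
        [stratum_interception(p) for p in profiles], ignore_index=True
    )
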