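"""Readers, writers and per-plot aggregation for the trial's tabular formats.

All tables are comma-separated UTF-8 CSV with a mandatory header row and
decimal points.  Column names can be remapped through a small YAML/dict
schema config of the form ``{table: {column_map: {file_col: canonical}}}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import yaml

from .types import (
    GasExchangeRecord,
    IntegrityError,
    OrganIsotopeRecord,
    ParProfile,
    PAR_STRATA,
    PlotIsotopeProfile,
    SchemaError,
    SpadSeries,
)

log = logging.getLogger("earshare")

ISOTOPE_COLUMNS = (
    "plot_id", "genotype", "replicate", "organ", "fraction", "occasion",
    "delta13C_permil",
)
GASEX_COLUMNS = ("plot_id", "organ", "net_photosynthesis", "dark_respiration")
SPAD_COLUMNS = ("plot_id", "day", "spad")
PAR_COLUMNS = ("plot_id", "incident") + tuple(f"below_{s}" for s in PAR_STRATA)
AGRONOMY_COLUMNS = ("plot_id", "genotype", "replicate", "grain_yield")


def _load_table(path, required, column_map: Optional[dict] = None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{Path(path).name}: missing mandatory column(s) {', '.join(missing)}"
        )
    return df


def read_isotopes(
    path, column_map: Optional[dict] = None, skip_invalid: bool = False
) -> List[OrganIsotopeRecord] | Tuple[List[OrganIsotopeRecord], pd.DataFrame]:
    """Read organ delta13C records.

    Rows violating record invariants are reported with their (1-based data)
    row numbers; with ``skip_invalid=True`` they are dropped and returned in
    a second rejects table instead of raising.  Duplicate
    (plot, organ, fraction, occasion) keys always raise IntegrityError.
    """
    df = _load_table(path, ISOTOPE_COLUMNS, column_map)
    records, rejects = [], []
    for i, row in df.iterrows():
        rec = OrganIsotopeRecord(
            plot_id=str(row["plot_id"]),
            genotype=str(row["genotype"]),
            replicate=int(row["replicate"]),
            organ=str(row["organ"]),
            fraction=str(row["fraction"]),
            occasion=str(row["occasion"]),
            delta13C=float(row["delta13C_permil"]),
        )
        try:
            rec.validate()
        except ValueError as exc:
            rejects.append({"row": i + 1, "reason": str(exc)})
            continue
        records.append(rec)
    if rejects and not skip_invalid:
        detail = "; ".join(f"row {r['row']}: {r['reason']}" for r in rejects)
        raise IntegrityError(f"{Path(path).name}: invalid rows - {detail}")
    seen: Dict[tuple, int] = {}
    for rec in records:
        if rec.key in seen:
            raise IntegrityError(
                f"{Path(path).name}: duplicate key {rec.key} (first seen earlier)"
            )
        seen[rec.key] = 1
    if skip_invalid:
        return records, pd.DataFrame(rejects, columns=["row", "reason"])
    return records


def read_gasex(path, column_map: Optional[dict] = None) -> List[GasExchangeRecord]:
    df = _load_table(path, GASEX_COLUMNS, column_map)
    records = []
    for i, row in df.iterrows():
        rec = GasExchangeRecord(
            plot_id=str(row["plot_id"]),
            organ=str(row["organ"]),
            net_photosynthesis=float(row["net_photosynthesis"]),
            dark_respiration=float(row["dark_respiration"]),
            organ_area=float(row["organ_area"])
            if "organ_area" in df.columns and pd.notna(row.get("organ_area"))
            else None,
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise IntegrityError(f"{Path(path).name}: row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def read_spad(path, column_map: Optional[dict] = None) -> List[SpadSeries]:
    """Read long-format SPAD readings (plot_id, day, spad) into per-plot series."""
    df = _load_table(path, SPAD_COLUMNS, column_map)
    out = []
    for plot_id, sub in df.groupby("plot_id", sort=True):
        sub = sub.sort_values("day")
        series = SpadSeries(
            plot_id=str(plot_id),
            dates=tuple(float(d) for d in sub["day"]),
            spad_values=tuple(float(v) for v in sub["spad"]),
        )
        series.validate()
        out.append(series)
    return out


def read_par(path, column_map: Optional[dict] = None) -> List[ParProfile]:
    df = _load_table(path, PAR_COLUMNS, column_map)
    out = []
    for i, row in df.iterrows():
        profile = ParProfile(
            plot_id=str(row["plot_id"]),
            incident=float(row["incident"]),
            transmitted=tuple(
                (s, float(row[f"below_{s}"])) for s in PAR_STRATA
            ),
        )
        try:
            profile.validate()
        except ValueError as exc:
            raise IntegrityError(f"{Path(path).name}: row {i + 1}: {exc}") from exc
        out.append(profile)
    return out


def read_agronomy(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    df = _load_table(path, AGRONOMY_COLUMNS, column_map)
    df["plot_id"] = df["plot_id"].astype(str)
    return df


@dataclass
class TrialData:
    """Everything a pipeline run consumes, in typed form."""

    isotopes: List[OrganIsotopeRecord] = field(default_factory=list)
    gasex: List[GasExchangeRecord] = field(default_factory=list)
    spad: List[SpadSeries] = field(default_factory=list)
    par: List[ParProfile] = field(default_factory=list)
    agronomy: Optional[pd.DataFrame] = None


def load_schema_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("schema config must be a mapping of table -> options")
    return cfg


def read_trial_tables(paths: Dict[str, str], schema_config: Optional[dict] = None) -> TrialData:
    """Read any subset of the trial tables.

    ``paths`` maps table name ('isotopes', 'gasex', 'spad', 'par',
    'agronomy') to a CSV path; ``schema_config`` optionally supplies
    per-table ``column_map`` entries.
    """
    cfg = schema_config or {}

    def cmap(table):
        return (cfg.get(table) or {}).get("column_map")

    data = TrialData()
    readers = {
        "isotopes": lambda p: setattr(data, "isotopes", read_isotopes(p, cmap("isotopes"))),
        "gasex": lambda p: setattr(data, "gasex", read_gasex(p, cmap("gasex"))),
        "spad": lambda p: setattr(data, "spad", read_spad(p, cmap("spad"))),
        "par": lambda p: setattr(data, "par", read_par(p, cmap("par"))),
        "agronomy": lambda p: setattr(data, "agronomy", read_agronomy(p, cmap("agronomy"))),
    }
    for table, path in paths.items():
        if table not in readers:
            raise SchemaError(f"unknown table {table!r}")
        readers[table](path)
    return data


def isotopes_to_frame(records: Iterable[OrganIsotopeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "genotype": r.genotype,
                "replicate": r.replicate,
                "organ": r.organ,
                "fraction": r.fraction,
                "occasion": r.occasion,
                "delta13C_permil": r.delta13C,
            }
            for r in records
        ],
        columns=list(ISOTOPE_COLUMNS),
    )


def write_isotopes(records: Iterable[OrganIsotopeRecord], path) -> None:
    isotopes_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-plot aggregation


def build_plot_profiles(
    records: Iterable[OrganIsotopeRecord],
    agronomy: Optional[pd.DataFrame] = None,
) -> Tuple[List[PlotIsotopeProfile], pd.DataFrame]:
    """Aggregate records into one :class:`PlotIsotopeProfile` per plot.

    End-member values are the arithmetic mean of the WSF delta13C over the
    occasions actually measured (an organ missing one occasion simply uses
    the other); the grain value is dry matter at maturity.  Plots lacking a
    grain value or either of the awns/peduncle end members are excluded;
    exclusions are returned with their reasons.  The result is independent
    of input record order.
    """
    by_plot: Dict[str, list] = {}
    for rec in sorted(records, key=lambda r: (r.plot_id, r.organ, r.fraction, r.occasion)):
        by_plot.setdefault(rec.plot_id, []).append(rec)

    profiles, excluded = [], []
    for plot_id, recs in sorted(by_plot.items()):
        wsf: Dict[str, Dict[str, float]] = {}
        grain = None
        for r in recs:
            if r.fraction == "WSF" and r.occasion in ("before_irrigation", "after_irrigation"):
                wsf.setdefault(r.organ, {})[r.occasion] = r.delta13C
            elif r.organ == "grains" and r.fraction == "DM" and r.occasion == "maturity":
                grain = r.delta13C

        def organ_mean(organ):
            vals = wsf.get(organ)
            if not vals:
                return None, ()
            occs = tuple(sorted(vals))
            return sum(vals[o] for o in occs) / len(occs), occs

        awns, occ_a = organ_mean("awns")
        ped, occ_p = organ_mean("peduncle")
        flag, occ_f = organ_mean("flag_leaf")
        glumes, occ_g = organ_mean("glumes")

        reason = None
        if grain is None:
            reason = "no grain DM delta13C at maturity"
        elif awns is None and ped is None:
            reason = "both end members missing"
        elif awns is None:
            reason = "awns WSF delta13C missing"
        elif ped is None:
            reason = "peduncle WSF delta13C missing"
        if reason is not None:
            log.warning("plot %s excluded from profiles: %s", plot_id, reason)
            excluded.append({"plot_id": plot_id, "reason": reason})
            continue

        gy = None
        if agronomy is not None:
            match = agronomy.loc[agronomy["plot_id"] == plot_id, "grain_yield"]
            if len(match):
                gy = float(match.iloc[0])

        profiles.append(
            PlotIsotopeProfile(
                plot_id=plot_id,
                delta_awns=awns,
                delta_peduncle=ped,
                delta_flag=flag,
                delta_glumes=glumes,
                delta_grain=grain,
                grain_yield=gy,
                occasions_used={
                    "awns": occ_a, "peduncle": occ_p,
                    "flag_leaf": occ_f, "glumes": occ_g,
                },
            )
        )
    return profiles, pd.DataFrame(excluded, columns=["plot_id", "reason"])


def profiles_to_frame(profiles: Iterable[PlotIsotopeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plot_id": p.plot_id,
                "delta_awns": p.delta_awns,
                "delta_peduncle": p.delta_peduncle,
                "delta_flag": p.delta_flag,
                "delta_glumes": p.delta_glumes,
                "delta_grain": p.delta_grain,
                "grain_yield": p.grain_yield,
            }
            for p in profiles
        ]
    )
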