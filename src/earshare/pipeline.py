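"""End-to-end orchestration: ingest -> profiles -> mixing fits -> report.

A run is driven by a small YAML/dict config, is deterministic given the
inputs and seed, and leaves a machine-readable manifest (input hashes,
config echo, versions) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import build_plot_profiles, profiles_to_frame, read_trial_tables
from .isotope import organ_summary
from .mixing import (
    GrainMixingModel,
    WaterStatusBins,
    round_half_up,
    summarize_contributions,
)
from .stats import one_way_anova, tukey_letters_from_groups

log = logging.getLogger("earshare")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def parse_bins(spec) -> WaterStatusBins:
    """Bins from config: 'default' or {label: [lo, hi], ...}."""
    if spec in (None, "default"):
        return WaterStatusBins()
    if isinstance(spec, str):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    return WaterStatusBins(edges={k: tuple(v) for k, v in spec.items()})


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise PipelineError("config: expected a mapping with an 'inputs' section")
    return cfg


def run_pipeline(config, outdir: Optional[str] = None) -> Path:
    """Run the full partitioning analysis and write the report directory.

    ``config`` is a dict or YAML path with keys: ``inputs`` (table name ->
    CSV path; 'isotopes' mandatory), optional ``bins``, ``boot``, ``seed``,
    ``translocation_offset``, ``slope_tol`` and ``out``.  Returns the
    report directory.  Outputs: bin_weights.csv, contributions.csv,
    scatter.csv, fit_diagnostics.json, manifest.json.
    """
    cfg = load_config(config)
    inputs: Dict[str, str] = cfg["inputs"]
    if "isotopes" not in inputs:
        raise PipelineError("config: inputs.isotopes is mandatory")
    out = Path(outdir or cfg.get("out", "report"))
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc
        return result

    data = stage("ingest", read_trial_tables, inputs, cfg.get("schema"))
    log.info("ingest: %d isotope records", len(data.isotopes))

    profiles, excluded = stage("profiles", build_plot_profiles, data.isotopes, data.agronomy)
    log.info("profiles: %d plots, %d excluded", len(profiles), len(excluded))
    if not profiles:
        raise PipelineError("stage 'profiles': no usable plots")

    bins = stage("bins", parse_bins, cfg.get("bins", "default"))
    offset = float(cfg.get("translocation_offset", 0.0))
    slope_tol = float(cfg.get("slope_tol", 0.05))

    frame = profiles_to_frame(profiles)
    res_ped = stage(
        "mix-awns-peduncle",
        lambda: GrainMixingModel(frame, "peduncle", bins, offset).fit(slope_tol),
    )
    has_flag = frame["delta_flag"].notna().all()
    res_flag = None
    if has_flag:
        res_flag = stage(
            "mix-awns-flag",
            lambda: GrainMixingModel(frame, "flag_leaf", bins, offset).fit(slope_tol),
        )

    for res in filter(None, (res_ped, res_flag)):
        clipped = res.weights["clipped"].sum()
        if clipped:
            log.warning("%s model: %d bin weight(s) clipped to [0, 1]",
                        res.model.end_member_b, clipped)
        snapped = res.weights["out_of_support"].sum()
        if snapped:
            log.warning("%s model: %d plot(s) outside the bin support",
                        res.model.end_member_b, snapped)

    # --- outputs ----------------------------------------------------------
    weight_tables = []
    diagnostics = {}
    boot = int(cfg.get("boot", 0))
    seed = cfg.get("seed")
    for res in filter(None, (res_ped, res_flag)):
        name = f"awns+{res.model.end_member_b}"
        tab = res.weights.copy()
        tab.insert(0, "model", name)
        weight_tables.append(tab)
        d = res.diagnostics
        diagnostics[name] = {
            "slope": d.slope, "rsquared": d.rsquared,
            "resid_sd_permil": d.resid_sd, "n_plots": d.n, "slope_ok": d.slope_ok,
        }
        if boot:
            if seed is None:
                raise PipelineError("stage 'bootstrap': a seed is required when boot > 0")
            ci = stage("bootstrap", res.bootstrap, boot, int(seed))
            diagnostics[name]["bootstrap"] = ci.to_dict(orient="records")
    pd.concat(weight_tables, ignore_index=True).to_csv(out / "bin_weights.csv", index=False)

    if res_flag is not None:
        report = stage("contributions", summarize_contributions,
                       res_ped.bin_weights, res_flag.bin_weights)
        per_bin = report.per_bin.copy()
        extra = []
        for label, avg in [("bin_mean", report.bin_mean),
                           ("plot_weighted_mean", report.plot_weighted_mean)]:
            extra.append(
                {"bin": label, "n_plots": np.nan,
                 "ear_share": avg["ear_share"], "shoot_share": avg["shoot_share"],
                 "flag_share_raw": avg["flag_share"],
                 "flag_share": int(round_half_up(avg["flag_share"]))}
            )
        pd.concat([per_bin, pd.DataFrame(extra)], ignore_index=True).to_csv(
            out / "contributions.csv", index=False
        )
        diagnostics["awn_flag_weight_ratio"] = report.awn_flag_ratio
        diagnostics["awn_flag_weight_ratio_rounded"] = report.awn_flag_ratio_rounded

    scatter = res_ped.bin_weights.plots[
        ["plot_id", "bin", "da", "db", "dg", "predicted"]
    ].rename(columns={"da": "delta_awns", "db": "delta_end_member_b",
                      "dg": "delta_grain_observed",
                      "predicted": "delta_grain_predicted"})
    scatter.to_csv(out / "scatter.csv", index=False)

    with open(out / "fit_diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1, sort_keys=True)

    manifest = {
        "package": "earshare",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items()},
        "n_plots": len(profiles),
        "n_excluded": int(len(excluded)),
        "excluded": excluded.to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("report written to %s", out)
    return out


# ---------------------------------------------------------------------------
# trial summary tables (Table 1 / Table 2 style)


def organ_table(records) -> pd.DataFrame:
    """Organ x fraction x occasion delta13C means with SE and Tukey letters.

    Letters compare organs within each (fraction, occasion) column, so the
    layout mirrors a per-sampling organ table.
    """
    summary = organ_summary(records, ("organ", "fraction", "occasion"))
    letters = {}
    df = pd.DataFrame(
        [{"organ": r.organ, "fraction": r.fraction, "occasion": r.occasion,
          "delta13C": r.delta13C} for r in records]
    )
    for (fraction, occasion), sub in df.groupby(["fraction", "occasion"]):
        groups = {o: g["delta13C"].to_numpy() for o, g in sub.groupby("organ")}
        if len(groups) < 2 or sum(len(v) for v in groups.values()) <= len(groups):
            letters.update({(o, fraction, occasion): "a" for o in groups})
            continue
        for organ, letter in tukey_letters_from_groups(groups).items():
            letters[(organ, fraction, occasion)] = letter
    summary["tukey"] = [
        letters.get((r.organ, r.fraction, r.occasion), "")
        for r in summary.itertuples()
    ]
    return summary


def genotype_table(agronomy: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype agronomic means ± SE with ANOVA stars and Tukey letters."""
    traits = [c for c in agronomy.columns
              if c not in ("plot_id", "genotype", "replicate")
              and pd.api.types.is_numeric_dtype(agronomy[c])]
    rows = []
    for trait in traits:
        groups = {g: sub[trait].dropna().to_numpy()
                  for g, sub in agronomy.groupby("genotype")}
        groups = {g: v for g, v in groups.items() if len(v)}
        anova = one_way_anova(groups)
        letters = tukey_letters_from_groups(groups)
        for g, vals in groups.items():
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            rows.append({"trait": trait, "genotype": g, "mean": float(vals.mean()),
                         "se": float(se) if np.isfinite(se) else np.nan,
                         "n": len(vals), "tukey": letters[g],
                         "anova_p": anova.p_value, "anova_stars": anova.stars})
    return pd.DataFrame(rows)
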