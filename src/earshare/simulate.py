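"""Seeded generator of complete synthetic wheat trials.

Emulates a 6-genotype x 3-replicate randomized trial under good agronomic
conditions: organ water-soluble-fraction (WSF) delta13C drawn around
anchor means for the two mid-grain-filling samplings, a latent per-plot
water-status gradient u ~ Uniform(0, 1) that shifts every organ's delta13C
upward (less negative) as stress grows, and mature-grain delta13C generated
as the water-status-weighted mixture of the plot's recorded awns and
peduncle signatures plus analytical noise.  Gas exchange, SPAD senescence
series, ceptometer PAR profiles and agronomic components are generated with
matching structure so every pipeline stage runs end to end.

Anchor means, dispersions and the weight schedules default to the
field-trial geometry the package is designed around; they are defaults, not
facts, and every one is overridable through :class:`SyntheticTrialConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .mixing import WaterStatusBins, assign_bin_flagged
from .types import OrganIsotopeRecord, C3_DELTA_RANGE

#: WSF delta13C anchor means (permil) per organ and sampling occasion.
DEFAULT_WSF_ANCHORS: Dict[str, Dict[str, float]] = {
    "flag_leaf": {"before_irrigation": -29.7, "after_irrigation": -30.1},
    "peduncle": {"before_irrigation": -26.9, "after_irrigation": -28.2},
    "glumes": {"before_irrigation": -26.5},  # not sampled after irrigation
    "awns": {"before_irrigation": -25.4, "after_irrigation": -26.1},
}

#: Dry matter minus WSF offset (permil), applied to the before-irrigation DM sampling.
DEFAULT_DM_OFFSETS: Dict[str, float] = {
    "flag_leaf": 1.6,
    "peduncle": 1.0,
    "glumes": 0.3,
    "awns": -0.1,
}

#: Water-status sensitivity gamma (permil shift per unit latent u); the
#: peduncle responds most, mirroring its largest before/after-irrigation
#: shift.  Sized so grain delta13C spans roughly 2 permil across plots.
DEFAULT_GAMMA: Dict[str, float] = {
    "flag_leaf": 1.2,
    "peduncle": 1.8,
    "glumes": 1.5,
    "awns": 1.4,
}

#: Per-bin true awns weights for the binned schedules (most favourable ->
#: least favourable water status).
BINNED_WEIGHTS_AWNS_PEDUNCLE = {"most_favourable": 0.58, "intermediate": 0.74,
                                "least_favourable": 0.90}
BINNED_WEIGHTS_AWNS_FLAG = {"most_favourable": 0.82, "intermediate": 0.895,
                            "least_favourable": 0.97}


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """All generator knobs, with trial-realistic defaults."""

    n_genotypes: int = 6
    n_reps: int = 3
    wsf_anchors: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WSF_ANCHORS.items()}
    )
    dm_offsets: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DM_OFFSETS))
    #: per-plot organ delta13C SD, permil (SE 0.1 at n=3 -> SD ~0.17)
    organ_sd: float = 0.17
    gamma: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    #: weight schedule: "linear" (w rises linearly with stress u) or
    #: "binned" (per-water-status-bin constants)
    weight_schedule: str = "linear"
    #: awns weight against the peduncle at u=0 (best water status) and u=1
    w_awns_peduncle: tuple = (0.58, 0.90)
    #: awns weight against the flag leaf at u=0 and u=1
    w_awns_flag: tuple = (0.82, 0.97)
    #: analytical + biological noise on grain delta13C, permil
    grain_noise_sd: float = 0.15
    #: constant source->grain translocation fractionation, permil
    translocation_offset: float = 0.0
    bins: WaterStatusBins = field(default_factory=WaterStatusBins)
    #: grain yield: base (Mg/ha), slope per permil of grain delta13C
    #: (negative: stressed plots yield less), and residual SD
    gy_base: float = 6.85
    gy_slope: float = -0.45
    gy_sd: float = 0.15
    #: whole-organ gas exchange means (umol CO2 organ^-1 s^-1): (net, dark resp)
    gasex_flag: tuple = (0.060, 0.010)
    gasex_ear: tuple = (0.055, 0.025)
    gasex_sd: float = 0.004
    organ_area_flag: float = 0.0030  # m^2
    organ_area_ear: float = 0.0045
    #: SPAD series: initial reading, decay per day, reading noise, weekly sampling
    spad_initial: float = 48.0
    spad_decay: float = 0.75
    spad_sd: float = 1.0
    spad_last_day: int = 49
    #: PAR: incident mean and the transmitted fraction below each stratum
    par_incident: float = 1800.0
    par_fractions: tuple = (0.70, 0.40, 0.25, 0.15)
    par_sd_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_reps < 1:
            raise ValueError("trial must have at least one genotype and replicate")
        if self.organ_sd < 0 or self.grain_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.weight_schedule not in ("linear", "binned"):
            raise ValueError("weight_schedule must be 'linear' or 'binned'")
        for name, (w0, w1) in [("w_awns_peduncle", self.w_awns_peduncle),
                               ("w_awns_flag", self.w_awns_flag)]:
            if not (0 <= w0 <= 1 and 0 <= w1 <= 1):
                raise ValueError(f"{name} endpoints must lie in [0, 1]")


PAR_STRATA = ("ear_base", "flag_leaf", "penultimate_leaf", "third_leaf")


@dataclass
class TrialTables:
    """Generated CSV-shaped tables plus the ground-truth sidecar."""

    isotopes: pd.DataFrame
    gasex: pd.DataFrame
    spad: pd.DataFrame
    par: pd.DataFrame
    agronomy: pd.DataFrame
    truth: pd.DataFrame
    config: Optional[SyntheticTrialConfig] = None

    def write(self, outdir) -> Dict[str, Path]:
        """Write all tables (and the generator config) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("isotopes", "gasex", "spad", "par", "agronomy", "truth"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["bins"] = self.config.bins.edges
            with open(outdir / "truth_config.json", "w") as fh:
                json.dump(cfg, fh, indent=1, sort_keys=True, default=list)
            paths["truth_config"] = outdir / "truth_config.json"
        return paths


def _linear_weight(endpoints: tuple, u: float) -> float:
    w0, w1 = endpoints
    return w0 + (w1 - w0) * u


def _binned_weight(
    da: float, db: float, weights_by_bin: Dict[str, float], bins: WaterStatusBins
) -> tuple:
    """Self-consistent bin weight for a plot with end members (da, db).

    The candidate weight of each bin predicts a noise-free grain value
    w*da + (1-w)*db; a candidate is feasible when that prediction is
    assigned back to its own bin.  Among feasible candidates the one whose
    prediction sits deepest inside its bin interval is chosen (a monotone
    schedule always has at least one feasible candidate).  Returns
    (bin_label, weight).
    """
    best = None
    for label in bins.labels:
        w = weights_by_bin[label]
        pred = w * da + (1.0 - w) * db
        assigned, _ = assign_bin_flagged(pred, bins)
        if assigned != label:
            continue
        lo, hi = bins.edges[label]
        # margin: depth inside the interval (support-edge bins count their
        # open side as unbounded, since out-of-support values snap to them)
        support_lo, support_hi = bins.support
        lo_margin = np.inf if lo == support_lo else pred - lo
        hi_margin = np.inf if hi == support_hi else hi - pred
        margin = min(lo_margin, hi_margin)
        if best is None or margin > best[2]:
            best = (label, w, margin)
    if best is None:  # pragma: no cover - monotone schedules always match
        raise RuntimeError("no self-consistent bin for the weight schedule")
    return best[0], best[1]


def generate_trial(config: SyntheticTrialConfig = SyntheticTrialConfig()) -> TrialTables:
    """Generate one complete synthetic trial; byte-identical for equal config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_c3, hi_c3 = C3_DELTA_RANGE

    iso_rows, truth_rows, gasex_rows, spad_rows, par_rows, agro_rows = ([] for _ in range(6))

    for g in range(1, config.n_genotypes + 1):
        genotype = f"G{g}"
        tkw_base = rng.normal(44.0, 2.5)
        for r in range(1, config.n_reps + 1):
            plot_id = f"{genotype}_r{r}"
            u = float(rng.uniform())

            # --- organ WSF values, shifted by water status ----------------
            wsf: Dict[str, Dict[str, float]] = {}
            for organ, anchors in config.wsf_anchors.items():
                wsf[organ] = {}
                for occasion, anchor in anchors.items():
                    value = (
                        anchor
                        + config.gamma.get(organ, 0.0) * (u - 0.5)
                        + rng.normal(0.0, config.organ_sd)
                    )
                    wsf[organ][occasion] = float(np.clip(value, lo_c3, hi_c3))
                    iso_rows.append(
                        dict(plot_id=plot_id, genotype=genotype, replicate=r,
                             organ=organ, fraction="WSF", occasion=occasion,
                             delta13C_permil=wsf[organ][occasion])
                    )
                # DM sampled before irrigation only
                dm = (
                    anchors["before_irrigation"]
                    + config.dm_offsets.get(organ, 0.0)
                    + config.gamma.get(organ, 0.0) * (u - 0.5)
                    + rng.normal(0.0, config.organ_sd)
                )
                iso_rows.append(
                    dict(plot_id=plot_id, genotype=genotype, replicate=r,
                         organ=organ, fraction="DM", occasion="before_irrigation",
                         delta13C_permil=float(np.clip(dm, lo_c3, hi_c3)))
                )

            def occ_mean(organ):
                vals = wsf[organ]
                return sum(vals.values()) / len(vals)

            da, db, df_ = occ_mean("awns"), occ_mean("peduncle"), occ_mean("flag_leaf")

            # --- true mixing weights -------------------------------------
            if config.weight_schedule == "linear":
                w_ap = _linear_weight(config.w_awns_peduncle, u)
                w_af = _linear_weight(config.w_awns_flag, u)
                pred = w_ap * da + (1.0 - w_ap) * db
                true_bin, _ = assign_bin_flagged(pred, config.bins)
            else:
                ap = dict(zip(
                    ("most_favourable", "intermediate", "least_favourable"),
                    (config.w_awns_peduncle[0],
                     (config.w_awns_peduncle[0] + config.w_awns_peduncle[1]) / 2,
                     config.w_awns_peduncle[1]),
                ))
                af = dict(zip(
                    ("most_favourable", "intermediate", "least_favourable"),
                    (config.w_awns_flag[0],
                     (config.w_awns_flag[0] + config.w_awns_flag[1]) / 2,
                     config.w_awns_flag[1]),
                ))
                true_bin, w_ap = _binned_weight(da, db, ap, config.bins)
                w_af = af[true_bin]

            grain_noise = float(rng.normal(0.0, config.grain_noise_sd))
            grain = (
                w_ap * da + (1.0 - w_ap) * db
                + config.translocation_offset + grain_noise
            )
            grain = float(np.clip(grain, lo_c3, hi_c3))
            iso_rows.append(
                dict(plot_id=plot_id, genotype=genotype, replicate=r,
                     organ="grains", fraction="DM", occasion="maturity",
                     delta13C_permil=grain)
            )

            # --- gas exchange ---------------------------------------------
            for organ, (net, resp), area in [
                ("flag_leaf", config.gasex_flag, config.organ_area_flag),
                ("ear", config.gasex_ear, config.organ_area_ear),
            ]:
                gasex_rows.append(
                    dict(plot_id=plot_id, organ=organ,
                         net_photosynthesis=float(rng.normal(net, config.gasex_sd)),
                         dark_respiration=float(abs(rng.normal(resp, config.gasex_sd / 2))),
                         organ_area=area)
                )

            # --- SPAD series ------------------------------------------------
            s0 = rng.normal(config.spad_initial, 1.5)
            decay = abs(rng.normal(config.spad_decay, 0.05))
            for day in range(0, config.spad_last_day + 1, 7):
                spad_rows.append(
                    dict(plot_id=plot_id, day=day,
                         spad=float(max(0.0, s0 - decay * day
                                        + rng.normal(0.0, config.spad_sd))))
                )

            # --- PAR profile -----------------------------------------------
            incident = float(rng.normal(config.par_incident, 60.0))
            fracs = np.clip(
                np.array(config.par_fractions)
                + rng.normal(0.0, config.par_sd_frac, size=len(config.par_fractions)),
                0.0, 1.0,
            )
            fracs = np.minimum.accumulate(fracs)  # transmitted PAR cannot grow with depth
            row = dict(plot_id=plot_id, incident=incident)
            for stratum, f in zip(PAR_STRATA, fracs):
                row[f"below_{stratum}"] = float(incident * f)
            par_rows.append(row)

            # --- agronomy ---------------------------------------------------
            gy = (
                config.gy_base
                + config.gy_slope * (grain - (-26.1))
                + rng.normal(0.0, config.gy_sd)
            )
            agro_rows.append(
                dict(plot_id=plot_id, genotype=genotype, replicate=r,
                     grain_yield=float(gy),
                     biomass=float(rng.normal(15.0, 0.7)),
                     harvest_index=float(rng.normal(0.45, 0.015)),
                     tkw=float(tkw_base + rng.normal(0.0, 0.8)),
                     kernel_weight_per_spike=float(rng.normal(2.5, 0.35)),
                     wsc_awns_g=float(abs(rng.normal(0.15, 0.03))),
                     wsc_glumes_g=float(abs(rng.normal(0.15, 0.03))),
                     wsc_flag_g=float(abs(rng.normal(0.15, 0.03))),
                     wsc_peduncle_g=float(abs(rng.normal(0.90, 0.10))))
            )

            truth_rows.append(
                dict(plot_id=plot_id, genotype=genotype, replicate=r, u=u,
                     w_awns_peduncle=w_ap, w_awns_flag=w_af,
                     true_bin=true_bin, delta_awns_mean=da,
                     delta_peduncle_mean=db, delta_flag_mean=df_,
                     grain_noise=grain_noise, delta_grain=grain)
            )

    return TrialTables(
        isotopes=pd.DataFrame(iso_rows),
        gasex=pd.DataFrame(gasex_rows),
        spad=pd.DataFrame(spad_rows),
        par=pd.DataFrame(par_rows),
        agronomy=pd.DataFrame(agro_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def trial_records(tables: TrialTables):
    """Typed OrganIsotopeRecords from a generated isotopes table."""
    return [
        OrganIsotopeRecord(
            plot_id=row.plot_id, genotype=row.genotype, replicate=int(row.replicate),
            organ=row.organ, fraction=row.fraction, occasion=row.occasion,
            delta13C=float(row.delta13C_permil),
        )
        for row in tables.isotopes.itertuples()
    ]


# ---------------------------------------------------------------------------
# worked example


#: (plot, awns, peduncle) anchor spreads for the noise-free worked example.
_WORKED_LEAST = [("W1", -25.3, -26.8), ("W2", -25.4, -26.9), ("W3", -25.5, -27.0)]
_WORKED_MOST = [("W4", -26.0, -27.4), ("W5", -26.1, -27.55), ("W6", -26.2, -27.7)]
WORKED_WEIGHTS_AWNS_PEDUNCLE = {"least_favourable": 0.90, "most_favourable": 0.58}
WORKED_WEIGHTS_AWNS_FLAG = {"least_favourable": 0.97, "most_favourable": 0.82}


def generate_worked_example() -> TrialTables:
    """Minimal noise-free 2-bin, 6-plot fixture with hand-checkable numbers.

    Three plots sit in each extreme water-status bin at the trial's anchor
    delta13C values.  Grain delta13C is the exact awns+peduncle mixture at
    that bin's weight (0.90 or 0.58 awns); the flag-leaf value of each plot
    is solved so the same grain is simultaneously the exact awns+flag
    mixture at the corresponding weight (0.97 or 0.82 awns).  Both fitted
    models therefore recover the scheduled weights exactly, with a
    through-origin slope of 1 and R^2 = 1.
    """
    iso_rows, truth_rows, gasex_rows, spad_rows, par_rows, agro_rows = ([] for _ in range(6))
    plots = [(p, a, b, "least_favourable") for p, a, b in _WORKED_LEAST] + [
        (p, a, b, "most_favourable") for p, a, b in _WORKED_MOST
    ]
    for i, (plot_id, awns, ped, bin_label) in enumerate(plots, start=1):
        genotype = f"G{(i - 1) % 3 + 1}"
        rep = (i - 1) // 3 + 1
        w_ap = WORKED_WEIGHTS_AWNS_PEDUNCLE[bin_label]
        w_af = WORKED_WEIGHTS_AWNS_FLAG[bin_label]
        grain = w_ap * awns + (1.0 - w_ap) * ped
        flag = (grain - w_af * awns) / (1.0 - w_af)

        for organ, value in [
            ("awns", awns), ("peduncle", ped), ("flag_leaf", flag), ("glumes", grain),
        ]:
            iso_rows.append(
                dict(plot_id=plot_id, genotype=genotype, replicate=rep,
                     organ=organ, fraction="WSF", occasion="before_irrigation",
                     delta13C_permil=value)
            )
        iso_rows.append(
            dict(plot_id=plot_id, genotype=genotype, replicate=rep,
                 organ="grains", fraction="DM", occasion="maturity",
                 delta13C_permil=grain)
        )
        # deterministic companion tables so the full pipeline runs
        for organ, net, resp, area in [
            ("flag_leaf", 0.060, 0.010, 0.0030), ("ear", 0.055, 0.025, 0.0045),
        ]:
            gasex_rows.append(dict(plot_id=plot_id, organ=organ,
                                   net_photosynthesis=net, dark_respiration=resp,
                                   organ_area=area))
        for day in range(0, 50, 7):
            spad_rows.append(dict(plot_id=plot_id, day=day, spad=48.0 - 0.76 * day))
        par_rows.append(
            dict(plot_id=plot_id, incident=1800.0, below_ear_base=1260.0,
                 below_flag_leaf=720.0, below_penultimate_leaf=450.0,
                 below_third_leaf=270.0)
        )
        agro_rows.append(
            dict(plot_id=plot_id, genotype=genotype, replicate=rep,
                 grain_yield=6.9 - 0.8 * (grain + 26.1))
        )
        truth_rows.append(
            dict(plot_id=plot_id, genotype=genotype, replicate=rep, u=np.nan,
                 w_awns_peduncle=w_ap, w_awns_flag=w_af, true_bin=bin_label,
                 delta_awns_mean=awns, delta_peduncle_mean=ped,
                 delta_flag_mean=flag, grain_noise=0.0, delta_grain=grain)
        )
    return TrialTables(
        isotopes=pd.DataFrame(iso_rows),
        gasex=pd.DataFrame(gasex_rows),
        spad=pd.DataFrame(spad_rows),
        par=pd.DataFrame(par_rows),
        agronomy=pd.DataFrame(agro_rows),
        truth=pd.DataFrame(truth_rows),
        config=None,
    )
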