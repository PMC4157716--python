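"""Two-end-member delta13C mixing model for grain-filling source partitioning.

The grain's carbon isotope composition is treated as a conservative mixture
of the water-soluble-fraction signatures of two photosynthetic source pools:

    delta_grain = w * delta_A + (1 - w) * delta_B (+ offset)

with A the awns (ear) and B either the peduncle (integrating the whole
shoot, pre-anthesis reserves included) or the flag-leaf blade.  The mixing
weight w is allowed to depend on plot water status, proxied by the grain
delta13C itself through a small set of bins: less negative grain delta13C
means a more stressed plot and a larger ear share.  Translocation from
source to grain is assumed not to fractionate (offset = 0 by default).

Within each bin w is estimated by separable least squares on the plots of
that bin; the slope-1 / intercept-0 relation between observed and mixture-
predicted grain delta13C is then *verified* with a through-origin
regression rather than imposed.

The statsmodels-style entry point is :class:`GrainMixingModel`, whose
``fit()`` returns a :class:`MixingResults`; the underlying operations are
plain functions usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .types import DegenerateEndMembersError, PlotIsotopeProfile

__all__ = [
    "WaterStatusBins",
    "DEFAULT_BINS",
    "closed_form_fraction",
    "assign_bin",
    "estimate_bin_weights",
    "predict_grain_delta",
    "validate_fit",
    "flag_contribution_extrapolation",
    "summarize_contributions",
    "bootstrap_weights",
    "GrainMixingModel",
    "MixingResults",
    "BinWeights",
    "FitDiagnostics",
    "ContributionReport",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (so 12.5 -> 13), matching reported integer percents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# water-status bins


@dataclass(frozen=True)
class WaterStatusBins:
    """Grain-delta13C intervals used as a water-status stratification.

    ``edges`` maps bin label -> (lo, hi) closed interval in permil.  More
    negative grain delta13C indicates a better plot water status.  Values in
    the gap between the two extreme intervals go to ``intermediate``; values
    outside the overall support are mapped to the nearest extreme bin and
    flagged.
    """

    edges: dict = field(
        default_factory=lambda: {
            "most_favourable": (-27.0, -26.4),
            "intermediate": (-26.4, -25.8),
            "least_favourable": (-25.8, -25.2),
        }
    )

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.edges.items():
            if not lo < hi:
                raise ValueError(f"bin {label!r} has empty interval ({lo}, {hi})")
        spans = sorted(self.edges.values())
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi - 1e-12:
                raise ValueError("water-status bins overlap")

    @property
    def labels(self) -> tuple:
        """Labels ordered from most to least favourable (ascending delta)."""
        return tuple(sorted(self.edges, key=lambda k: self.edges[k][0]))

    @property
    def support(self) -> tuple:
        los, his = zip(*self.edges.values())
        return (min(los), max(his))


DEFAULT_BINS = WaterStatusBins()


def assign_bin(
    delta_grain: float, bins: WaterStatusBins = DEFAULT_BINS
) -> str:
    """Bin label for a grain delta13C value (total function).

    Closed endpoints; interior gaps between bins resolve to the bin whose
    edge they touch (the default bins are contiguous so this never occurs);
    values outside the overall support map to the nearest extreme bin.
    """
    label, _ = assign_bin_flagged(delta_grain, bins)
    return label


def assign_bin_flagged(
    delta_grain: float, bins: WaterStatusBins = DEFAULT_BINS
) -> tuple:
    """Like :func:`assign_bin` but also reports whether the value lay
    outside the bins' overall support (and was snapped to the nearest)."""
    if not np.isfinite(delta_grain):
        raise ValueError("grain delta13C must be finite")
    support_lo, support_hi = bins.support
    matches = [
        label for label, (lo, hi) in bins.edges.items() if lo <= delta_grain <= hi
    ]
    if matches:
        # a value on a shared closed endpoint belongs to the extreme bin
        # (the bin nearer the support edge), matching the stated intervals
        def extremity(label):
            lo, hi = bins.edges[label]
            return min(lo - support_lo, support_hi - hi)

        return min(matches, key=extremity), False
    # outside every interval: nearest bin by interval distance
    def dist(item):
        _, (lo, hi) = item
        return max(lo - delta_grain, delta_grain - hi, 0.0)

    label = min(bins.edges.items(), key=dist)[0]
    lo, hi = bins.support
    outside = not (lo <= delta_grain <= hi)
    return label, outside


# ---------------------------------------------------------------------------
# elementary mass balance


class SourceFraction(NamedTuple):
    fraction: float
    out_of_range: bool  # True when the raw fraction falls outside [0, 1]


def closed_form_fraction(
    delta_grain: float, delta_a: float, delta_b: float
) -> SourceFraction:
    """Two-pool mass-balance fraction of source *a* in the grain signal.

    f = (delta_grain - delta_b) / (delta_a - delta_b).  The value is not
    clipped; a fraction outside [0, 1] (grain outside the end-member
    interval) is returned with ``out_of_range=True``.
    """
    denom = delta_a - delta_b
    if denom == 0:
        raise DegenerateEndMembersError(
            "end members have identical delta13C; the mixture is unidentifiable"
        )
    f = (delta_grain - delta_b) / denom
    return SourceFraction(f, not (0.0 <= f <= 1.0))


def predict_grain_delta(w: float, delta_a: float, delta_b: float, offset: float = 0.0) -> float:
    """Mixture-predicted grain delta13C: w*delta_a + (1-w)*delta_b + offset."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"mixing weight {w} outside [0, 1]")
    return w * delta_a + (1.0 - w) * delta_b + offset


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitDiagnostics:
    """Through-origin agreement between observed and mixture-predicted grain delta13C.

    slope = sum(x*y)/sum(x^2) with x the prediction and y the observation;
    rsquared uses the uncentred convention 1 - SS_res / sum(y^2), the proper
    convention for a regression through the origin (the centred one can be
    negative there).
    """

    slope: float
    rsquared: float
    resid_sd: float
    n: int
    slope_ok: bool


def validate_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    slope_tol: float = 0.05,
) -> FitDiagnostics:
    """Verify the slope-1 / origin-0 relation between observation and prediction."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 pairs to assess the fit")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all predictions are zero; through-origin slope undefined")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    resid_sd = float(np.sqrt(ss_res / (y.size - 1)))
    return FitDiagnostics(
        slope=beta,
        rsquared=r2,
        resid_sd=resid_sd,
        n=int(y.size),
        slope_ok=abs(beta - 1.0) <= slope_tol,
    )


def _profiles_frame(
    profiles: Iterable[PlotIsotopeProfile] | pd.DataFrame,
    end_member_b: str,
) -> pd.DataFrame:
    """Internal: normalise input to a frame with plot_id, da, db, dg columns."""
    if end_member_b not in ("peduncle", "flag_leaf"):
        raise ValueError("end_member_b must be 'peduncle' or 'flag_leaf'")
    if isinstance(profiles, pd.DataFrame) and {"plot_id", "da", "db", "dg"} <= set(
        profiles.columns
    ):
        df = profiles[["plot_id", "da", "db", "dg"]].copy()
    elif isinstance(profiles, pd.DataFrame):
        col_b = "delta_peduncle" if end_member_b == "peduncle" else "delta_flag"
        for col in ("plot_id", "delta_awns", col_b, "delta_grain"):
            if col not in profiles.columns:
                raise ValueError(f"profiles frame lacks column {col!r}")
        df = profiles.rename(columns={col_b: "db", "delta_awns": "da", "delta_grain": "dg"})
        df = df[["plot_id", "da", "db", "dg"]].copy()
    else:
        rows = []
        for p in profiles:
            p.validate()
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "da": p.delta_awns,
                    "db": p.end_member(end_member_b),
                    "dg": p.delta_grain,
                }
            )
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no plots supplied")
    if not np.isfinite(df[["da", "db", "dg"]].to_numpy()).all():
        raise ValueError("non-finite delta13C in profiles")
    return df.reset_index(drop=True)


def _solve_bin_weight(da, db, dg, offset: float) -> tuple:
    """Closed-form separable least-squares weight for one bin, clipped to [0, 1].

    Minimises sum_i (dg_i - offset - [w*da_i + (1-w)*db_i])^2 over w:
    with x = da - db and y = dg - offset - db,  w* = sum(x*y) / sum(x^2).
    Returns (w, clipped flag).
    """
    x = np.asarray(da, float) - np.asarray(db, float)
    if np.any(x == 0):
        raise DegenerateEndMembersError("a plot has identical end-member delta13C")
    y = np.asarray(dg, float) - offset - np.asarray(db, float)
    w = float(np.sum(x * y) / np.sum(x * x))
    clipped = not (0.0 <= w <= 1.0)
    return min(1.0, max(0.0, w)), clipped


@dataclass(frozen=True)
class BinWeights:
    """Per-water-status-bin mixing weights with pooled fit diagnostics."""

    end_member_b: str
    per_bin: pd.DataFrame  # bin, weight_a, weight_b, n_plots, clipped, out_of_support
    plots: pd.DataFrame  # plot_id, bin, da, db, dg, predicted, out_of_support
    diagnostics: FitDiagnostics
    bins: WaterStatusBins
    offset: float = 0.0

    def weight(self, bin_label: str) -> float:
        row = self.per_bin.loc[self.per_bin["bin"] == bin_label]
        if row.empty:
            raise KeyError(bin_label)
        return float(row["weight_a"].iloc[0])


def estimate_bin_weights(
    profiles,
    end_member_b: str = "peduncle",
    bins: WaterStatusBins = DEFAULT_BINS,
    offset: float = 0.0,
    slope_tol: float = 0.05,
) -> BinWeights:
    """Estimate the awns weight per water-status bin by separable least squares.

    Each plot is assigned to a bin by its grain delta13C; within each
    occupied bin the weight minimising the squared mixture residuals has the
    closed form w* = sum((dg-db)(da-db)) / sum((da-db)^2), clipped to [0, 1]
    with a flag.  Diagnostics (through-origin slope, uncentred R^2, residual
    SD) are computed on the pooled predictions across bins.
    """
    df = _profiles_frame(profiles, end_member_b)
    assignments = [assign_bin_flagged(v, bins) for v in df["dg"]]
    df["bin"] = [a[0] for a in assignments]
    df["out_of_support"] = [a[1] for a in assignments]

    occupied = df["bin"].unique()
    if len(occupied) == 1 and len(bins.edges) > 1:
        warnings.warn(
            "all plots fall in one water-status bin; the water-status "
            "dependence of the mixing weight is unidentifiable",
            stacklevel=2,
        )

    rows = []
    pred = np.full(len(df), np.nan)
    for label in bins.labels:
        sub = df[df["bin"] == label]
        if sub.empty:
            rows.append(
                {"bin": label, "weight_a": np.nan, "weight_b": np.nan,
                 "n_plots": 0, "clipped": False, "out_of_support": 0}
            )
            continue
        w, clipped = _solve_bin_weight(sub["da"], sub["db"], sub["dg"], offset)
        rows.append(
            {"bin": label, "weight_a": w, "weight_b": 1.0 - w,
             "n_plots": int(len(sub)), "clipped": clipped,
             "out_of_support": int(sub["out_of_support"].sum())}
        )
        pred[sub.index] = w * sub["da"] + (1.0 - w) * sub["db"] + offset
    df["predicted"] = pred

    if len(df) >= 3:
        diagnostics = validate_fit(df["dg"], df["predicted"], slope_tol=slope_tol)
    else:  # too few plots for a meaningful through-origin check
        diagnostics = FitDiagnostics(np.nan, np.nan, np.nan, len(df), False)
    return BinWeights(
        end_member_b=end_member_b,
        per_bin=pd.DataFrame(rows),
        plots=df,
        diagnostics=diagnostics,
        bins=bins,
        offset=offset,
    )


def bootstrap_weights(
    profiles,
    end_member_b: str = "peduncle",
    bins: WaterStatusBins = DEFAULT_BINS,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    coverage: float = 0.95,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for the per-bin awns weight.

    Plots are resampled with replacement *within* their bin, so the
    water-status stratification is held fixed.  Bins with fewer than two
    plots get a missing interval.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for reproducible intervals")
    rng = np.random.default_rng(seed)
    df = _profiles_frame(profiles, end_member_b)
    df["bin"] = [assign_bin(v, bins) for v in df["dg"]]

    alpha = (1.0 - coverage) / 2.0
    out = []
    for label in bins.labels:
        sub = df[df["bin"] == label].reset_index(drop=True)
        n = len(sub)
        if n < 2:
            out.append({"bin": label, "n_plots": n, "weight_lo": np.nan,
                        "weight_hi": np.nan, "n_boot": n_boot})
            continue
        ws = np.empty(n_boot)
        da, db, dg = (sub[c].to_numpy() for c in ("da", "db", "dg"))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ws[b], _ = _solve_bin_weight(da[idx], db[idx], dg[idx], offset)
        lo, hi = np.quantile(ws, [alpha, 1.0 - alpha])
        out.append({"bin": label, "n_plots": n, "weight_lo": float(lo),
                    "weight_hi": float(hi), "n_boot": n_boot})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# contribution reporting


def flag_contribution_extrapolation(
    awn_share_model1: float, flag_weight_model2: float, awn_weight_model2: float
) -> tuple:
    """Flag-leaf share of grain carbon by cross-model extrapolation.

    The awns+shoot model gives the ear (awn) share of grain carbon in a bin;
    the awns+flag model gives, for the same bin, the flag:awn weight ratio.
    Scaling the ear share by that ratio bounds the flag leaf's own share:

        flag_share = awn_share_model1 * (flag_weight_model2 / awn_weight_model2)

    Shares and weights are percentages in [0, 100].  Returns
    (raw_percent, integer_percent) with half-up rounding.
    """
    for name, v in [("awn_share_model1", awn_share_model1),
                    ("flag_weight_model2", flag_weight_model2),
                    ("awn_weight_model2", awn_weight_model2)]:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
    if awn_weight_model2 == 0:
        if flag_weight_model2 == 0:
            return 0.0, 0
        raise ZeroDivisionError("awn weight of the awns+flag model is zero")
    raw = awn_share_model1 * (flag_weight_model2 / awn_weight_model2)
    return raw, int(round_half_up(raw))


@dataclass(frozen=True)
class ContributionReport:
    """Per-bin and averaged organ shares of grain carbon, in percent."""

    per_bin: pd.DataFrame  # bin, n_plots, ear_share, shoot_share, flag share cols
    #: simple mean over occupied bins
    bin_mean: dict
    #: plot-count-weighted mean
    plot_weighted_mean: dict
    #: awn:flag weight ratio in the most favourable occupied bin, raw and rounded
    awn_flag_ratio: float
    awn_flag_ratio_rounded: int

    def summary(self) -> str:
        lines = ["Grain carbon contribution report", "=" * 34]
        tab = self.per_bin.copy()
        for col in ("ear_share", "shoot_share", "flag_share_raw"):
            tab[col] = tab[col].map(lambda v: f"{v:.1f}" if np.isfinite(v) else "--")
        lines.append(tab.to_string(index=False))
        for name, avg in [("bin mean", self.bin_mean),
                          ("plot-weighted mean", self.plot_weighted_mean)]:
            lines.append(
                f"{name}: ear {avg['ear_share']:.1f}%  shoot {avg['shoot_share']:.1f}%"
                f"  flag {avg['flag_share']:.1f}% (~{int(round_half_up(avg['flag_share']))}%)"
            )
        lines.append(
            f"awn:flag weight ratio (most favourable bin): "
            f"{self.awn_flag_ratio:.2f} (~{self.awn_flag_ratio_rounded}x)"
        )
        return "\n".join(lines)


def summarize_contributions(
    bin_weights_awns_peduncle: BinWeights,
    bin_weights_awns_flag: BinWeights,
) -> ContributionReport:
    """Combine the two fitted models into organ shares of grain carbon.

    Per bin: ear share = awns weight of the awns+peduncle model (x100),
    shoot share = its complement; the flag leaf's own share is obtained by
    scaling the ear share with the flag:awn weight ratio of the awns+flag
    model (:func:`flag_contribution_extrapolation`).  Averages over occupied
    bins are reported both unweighted and plot-count-weighted.
    """
    ap, af = bin_weights_awns_peduncle, bin_weights_awns_flag
    if ap.bins.edges != af.bins.edges:
        raise ValueError("the two models were fitted on different bin structures")
    merged = ap.per_bin.merge(af.per_bin, on="bin", suffixes=("_ap", "_af"))
    rows = []
    for _, r in merged.iterrows():
        ear = 100.0 * r["weight_a_ap"]
        occupied = r["n_plots_ap"] > 0 and np.isfinite(ear)
        if occupied and r["n_plots_af"] > 0 and np.isfinite(r["weight_a_af"]):
            flag_raw, flag_int = flag_contribution_extrapolation(
                ear, 100.0 * r["weight_b_af"], 100.0 * r["weight_a_af"]
            )
        else:
            flag_raw, flag_int = np.nan, None
        rows.append(
            {
                "bin": r["bin"],
                "n_plots": int(r["n_plots_ap"]),
                "ear_share": ear if occupied else np.nan,
                "shoot_share": 100.0 - ear if occupied else np.nan,
                "flag_share_raw": flag_raw,
                "flag_share": flag_int,
            }
        )
    per_bin = pd.DataFrame(rows)

    occ = per_bin[per_bin["n_plots"] > 0]
    if occ.empty:
        raise ValueError("no occupied bins")

    def _avg(weights) -> dict:
        weights = np.asarray(weights, float)
        weights = weights / weights.sum()
        return {
            "ear_share": float(np.sum(weights * occ["ear_share"])),
            "shoot_share": float(np.sum(weights * occ["shoot_share"])),
            "flag_share": float(np.sum(weights * occ["flag_share_raw"])),
        }

    bin_mean = _avg(np.ones(len(occ)))
    plot_mean = _avg(occ["n_plots"].to_numpy())

    # flag-vs-awn weight ratio in the most favourable occupied bin of model 2
    af_occ = af.per_bin[af.per_bin["n_plots"] > 0]
    if af_occ.empty:
        raise ValueError("awns+flag model has no occupied bin")
    best = af_occ.iloc[0]  # per_bin rows follow bins.labels: most favourable first
    wb = float(best["weight_b"])
    wa = float(best["weight_a"])
    ratio = wa / wb if wb > 0 else np.inf
    return ContributionReport(
        per_bin=per_bin,
        bin_mean=bin_mean,
        plot_weighted_mean=plot_mean,
        awn_flag_ratio=ratio,
        awn_flag_ratio_rounded=int(round_half_up(ratio)) if np.isfinite(ratio) else -1,
    )


# ---------------------------------------------------------------------------
# model / results objects


class GrainMixingModel:
    """Water-status-binned two-end-member mixing model for grain delta13C.

    Parameters
    ----------
    profiles
        Iterable of :class:`~earshare.types.PlotIsotopeProfile` or a
        DataFrame with columns ``plot_id, delta_awns, delta_peduncle``
        (and/or ``delta_flag``), ``delta_grain``.
    end_member_b
        Second source pool: ``"peduncle"`` (shoot-integrated, default) or
        ``"flag_leaf"``.
    bins
        Water-status stratification of grain delta13C.
    translocation_offset
        Constant fractionation (permil) added during source-to-grain
        translocation; 0 by default (the no-fractionation assumption).
    """

    def __init__(
        self,
        profiles,
        end_member_b: str = "peduncle",
        bins: WaterStatusBins = DEFAULT_BINS,
        translocation_offset: float = 0.0,
    ) -> None:
        self.profiles = profiles
        self.end_member_b = end_member_b
        self.bins = bins
        self.translocation_offset = float(translocation_offset)
        # validates eagerly so construction fails fast on bad input
        self._frame = _profiles_frame(profiles, end_member_b)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GrainMixingModel":
        return cls(df, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self._frame)

    def fit(self, slope_tol: float = 0.05) -> "MixingResults":
        bw = estimate_bin_weights(
            self._frame,
            end_member_b=self.end_member_b,
            bins=self.bins,
            offset=self.translocation_offset,
            slope_tol=slope_tol,
        )
        return MixingResults(self, bw)


class MixingResults:
    """Fitted per-bin mixing weights with diagnostics and reporting helpers."""

    def __init__(self, model: GrainMixingModel, bin_weights: BinWeights) -> None:
        self.model = model
        self.bin_weights = bin_weights

    # -- estimates ---------------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.bin_weights.per_bin

    def weight(self, bin_label: str) -> float:
        return self.bin_weights.weight(bin_label)

    @property
    def fitted_values(self) -> np.ndarray:
        return self.bin_weights.plots["predicted"].to_numpy()

    @property
    def observed(self) -> np.ndarray:
        return self.bin_weights.plots["dg"].to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self.observed - self.fitted_values

    # -- diagnostics -------------------------------------------------------
    @property
    def slope(self) -> float:
        return self.bin_weights.diagnostics.slope

    @property
    def rsquared(self) -> float:
        return self.bin_weights.diagnostics.rsquared

    @property
    def resid_sd(self) -> float:
        return self.bin_weights.diagnostics.resid_sd

    @property
    def diagnostics(self) -> FitDiagnostics:
        return self.bin_weights.diagnostics

    # -- uncertainty -------------------------------------------------------
    def bootstrap(
        self, n_boot: int = 1000, seed: Optional[int] = None, coverage: float = 0.95
    ) -> pd.DataFrame:
        return bootstrap_weights(
            self.model._frame,
            end_member_b=self.model.end_member_b,
            bins=self.model.bins,
            n_boot=n_boot,
            seed=seed,
            coverage=coverage,
            offset=self.model.translocation_offset,
        )

    # -- reporting ---------------------------------------------------------
    def contributions(self, flag_results: "MixingResults") -> ContributionReport:
        """Combine with an awns+flag fit into a full contribution report."""
        return summarize_contributions(self.bin_weights, flag_results.bin_weights)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Grain delta13C mixing model (awns vs %s)" % self.model.end_member_b,
            "=" * 48,
            f"plots: {self.model.nobs}   translocation offset: "
            f"{self.model.translocation_offset:+.2f} permil",
            "",
            self.weights.to_string(
                index=False,
                formatters={"weight_a": "{:.3f}".format, "weight_b": "{:.3f}".format},
                na_rep="--",
            ),
            "",
            f"through-origin slope: {d.slope:.4f} "
            f"({'ok' if d.slope_ok else 'OUTSIDE tolerance'})",
            f"uncentred R^2:        {d.rsquared:.4f}",
            f"residual SD:          {d.resid_sd:.3f} permil (n={d.n})",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MixingResults awns vs {self.model.end_member_b}, "
            f"n={self.model.nobs}, slope={self.slope:.3f}>"
        )
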