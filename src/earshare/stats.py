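"""Trial-level descriptive inference: ANOVA, Tukey HSD letters, yield diagnostics.

These reproduce the table apparatus of a small replicated field trial:
one-way (and genotype x organ two-way) analysis of variance with
significance stars, compact-letter displays from Tukey's honestly
significant difference test (Tukey-Kramer under unequal n), and the
grain-delta13C vs grain-yield relationship used as a water-status
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_stars(p: float) -> str:
    """Conventional star coding: *** <0.001, ** <0.01, * <0.05, else NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False  # True when every group has zero within-variance

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def one_way_anova(groups: Dict[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from the sum-of-squares decomposition.

    ``groups`` maps level label -> observations.  Requires at least two
    groups and at least one group with two observations.  When every group
    has zero internal variance but means differ, F is reported infinite
    with the ``degenerate`` flag set.
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(a.size for a in arrays.values())
    if n_total - len(arrays) < 1:
        raise ValueError("need at least one group with two observations")
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ss_within == 0:
        degenerate = True
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        degenerate = False
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        df_between=df_b,
        df_within=df_w,
        f_statistic=float(f),
        p_value=p,
        stars=significance_stars(p),
        degenerate=degenerate,
    )


def two_way_anova(df: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction (e.g. genotype x organ), via statsmodels.

    Returns the anova_lm table augmented with a ``stars`` column.  This is a
    summary output mirroring the trial tables, not a pipeline dependency.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={response: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table["stars"] = [
        significance_stars(p) if np.isfinite(p) else ""
        for p in table["PR(>F)"].fillna(np.nan)
    ]
    return table


# ---------------------------------------------------------------------------
# Tukey HSD compact letter display


def tukey_significance_matrix(
    means: Dict[str, float],
    pooled_variance: float,
    sizes: Dict[str, int],
    df_error: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Boolean matrix of significantly different pairs (Tukey-Kramer).

    q_ij = |m_i - m_j| / sqrt(s2/2 * (1/n_i + 1/n_j)) compared with the
    studentized range distribution with k groups and df_error degrees of
    freedom.
    """
    labels = list(means)
    k = len(labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    if k < 2 or pooled_variance < 0:
        return sig
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if pooled_variance == 0:
                different = means[a] != means[b]
            else:
                se = np.sqrt(pooled_variance / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
                q = abs(means[a] - means[b]) / se
                different = sps.studentized_range.sf(q, k, df_error) < alpha
            sig.loc[a, b] = sig.loc[b, a] = bool(different)
    return sig


def letters_from_significance(
    sig: pd.DataFrame, means: Dict[str, float]
) -> Dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different.  Letters are
    assigned from 'a' starting at the highest mean, so the display is
    invariant to relabelling and input order.
    """
    order = sorted(means, key=lambda g: (-means[g], g))
    columns = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if not sig.loc[a, b]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
            # absorb: drop columns contained in another
            columns = [
                c
                for c in columns
                if c and not any(c < other for other in columns)
            ]
            # dedupe while keeping order stable
            seen, unique = [], []
            for c in columns:
                if c not in seen:
                    seen.append(c)
                    unique.append(c)
            columns = unique
    # order columns by the best-ranked group they contain
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}


def tukey_hsd_letters(
    means: Dict[str, float],
    pooled_variance: float,
    sizes: Dict[str, int],
    alpha: float = 0.05,
    df_error: Optional[int] = None,
) -> Dict[str, str]:
    """Compact letter display from group means and the pooled error variance."""
    if len(means) == 1:
        return {next(iter(means)): "a"}
    if df_error is None:
        df_error = sum(sizes.values()) - len(sizes)
    if df_error < 1:
        raise ValueError("no error degrees of freedom for Tukey comparisons")
    sig = tukey_significance_matrix(means, pooled_variance, sizes, df_error, alpha)
    return letters_from_significance(sig, means)


def tukey_letters_from_groups(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> Dict[str, str]:
    """Convenience wrapper computing means and pooled variance from raw groups."""
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    means = {k: float(a.mean()) for k, a in arrays.items()}
    sizes = {k: int(a.size) for k, a in arrays.items()}
    df_error = sum(sizes.values()) - len(sizes)
    if df_error < 1:
        raise ValueError("no error degrees of freedom for Tukey comparisons")
    pooled = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values()) / df_error
    return tukey_hsd_letters(means, pooled, sizes, alpha=alpha, df_error=df_error)


# ---------------------------------------------------------------------------
# grain yield vs grain delta13C


@dataclass(frozen=True)
class YieldDeltaRelationship:
    pearson_r: float
    p_value: float
    #: least-squares quadratic coefficients (highest degree first)
    quadratic_coeffs: tuple
    n: int
    constant_yield: bool = False


def yield_delta_relationship(profiles) -> YieldDeltaRelationship:
    """Pearson correlation and quadratic fit of grain yield on grain delta13C.

    Used only as a water-status diagnostic: a negative correlation across
    plots indicates residual soil-moisture variability in the trial.
    ``profiles`` is an iterable of PlotIsotopeProfile (with ``grain_yield``
    set) or a DataFrame with ``delta_grain`` and ``grain_yield`` columns.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles[["delta_grain", "grain_yield"]].dropna()
        x = df["delta_grain"].to_numpy(float)
        y = df["grain_yield"].to_numpy(float)
    else:
        pairs = [
            (p.delta_grain, p.grain_yield)
            for p in profiles
            if p.grain_yield is not None
        ]
        x = np.array([a for a, _ in pairs], float)
        y = np.array([b for _, b in pairs], float)
    if x.size < 4:
        raise ValueError("need at least 4 plots with both yield and grain delta13C")
    if np.allclose(y, y[0]):
        return YieldDeltaRelationship(
            pearson_r=np.nan,
            p_value=np.nan,
            quadratic_coeffs=tuple(np.polyfit(x, y, 2)),
            n=int(x.size),
            constant_yield=True,
        )
    r, p = sps.pearsonr(x, y)
    coeffs = tuple(np.polyfit(x, y, 2))
    return YieldDeltaRelationship(
        pearson_r=float(r), p_value=float(p), quadratic_coeffs=coeffs, n=int(x.size)
    )
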