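import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from earshare.stats import (
    letters_from_significance,
    one_way_anova,
    significance_stars,
    tukey_hsd_letters,
    tukey_letters_from_groups,
    two_way_anova,
    yield_delta_relationship,
)


class TestOneWayAnova:
    def test_identical_group_means_not_significant(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0], "c": [3.0, 2.0, 1.0]}
        res = one_way_anova(groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.stars == "NS"

    def test_two_groups_f_equals_t_squared(self):
        a = [5.1, 4.8, 5.5, 5.0]
        b = [6.2, 6.0, 6.5]
        res = one_way_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_hand_computed_toy_table(self):
        # groups (1,2,3), (2,3,4), (4,5,6): grand mean 10/3
        # SS_between = 3*[(2-10/3)^2 + (3-10/3)^2 + (5-10/3)^2] = 14
        # SS_within = 2+2+2 = 6; F = (14/2)/(6/6) = 7
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [4, 5, 6]})
        assert res.ss_between == pytest.approx(14.0)
        assert res.ss_within == pytest.approx(6.0)
        assert res.f_statistic == pytest.approx(7.0)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(m, 1.0, 6) for k, m in [("a", 0), ("b", 0.5), ("c", 2)]}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(i, 1.3, rng.integers(3, 9)) for i, k in enumerate("abcd")}
        res = one_way_anova(groups)
        flat = np.concatenate(list(groups.values()))
        ss_total = float(np.sum((flat - flat.mean()) ** 2))
        assert res.ss_total == pytest.approx(ss_total, rel=1e-9)

    def test_zero_within_variance_reports_infinite_f(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert np.isinf(res.f_statistic) and res.degenerate

    @pytest.mark.parametrize(
        "p, stars", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "NS")]
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars


class TestTukeyLetters:
    def test_all_equal_means_share_a(self):
        letters = tukey_letters_from_groups(
            {"a": [1.0, 1.1, 0.9], "b": [1.0, 0.9, 1.1], "c": [1.05, 0.95, 1.0]}
        )
        assert set(letters.values()) == {"a"}

    def test_two_well_separated_groups(self):
        letters = tukey_letters_from_groups(
            {"lo": [1.0, 1.1, 0.9], "hi": [9.0, 9.1, 8.9]}
        )
        assert letters["hi"] == "a" and letters["lo"] == "b"

    def test_single_group_gets_a(self):
        assert tukey_hsd_letters({"only": 1.0}, 0.0, {"only": 3}) == {"only": "a"}

    def test_organ_delta13c_geometry_yields_four_distinct_letters(self):
        # flag << peduncle < glumes < awns with per-plot SD ~0.17, compared
        # across all 18 plots of a 6x3 trial (the table's organ contrast)
        rng = np.random.default_rng(12)
        sd = 0.1 * np.sqrt(3)
        groups = {
            organ: rng.normal(mean, sd, 18)
            for organ, mean in [("flag_leaf", -29.7), ("peduncle", -26.9),
                                ("glumes", -26.5), ("awns", -25.4)]
        }
        letters = tukey_letters_from_groups(groups)
        assert len(set(letters.values())) == 4
        assert letters["awns"] == "a" and letters["flag_leaf"] == "d"

    def test_invariant_to_relabelling(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(m, 0.5, 4) for k, m in
                  [("x", 0.0), ("y", 1.0), ("z", 3.0)]}
        base = tukey_letters_from_groups(groups)
        renamed = {"z": groups["x"], "x": groups["y"], "y": groups["z"]}
        swapped = tukey_letters_from_groups(renamed)
        assert swapped["z"] == base["x"]
        assert swapped["x"] == base["y"]
        assert swapped["y"] == base["z"]

    def test_agrees_with_statsmodels_pairwise_tukey(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(21)
        groups = {k: rng.normal(m, 1.0, 5) for k, m in
                  [("a", 0.0), ("b", 1.2), ("c", 3.5), ("d", 3.7)]}
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm_res = pairwise_tukeyhsd(values, labels, alpha=0.05)
        sm_reject = {
            (a, b): rej
            for (a, b), rej in zip(
                [tuple(r) for r in np.array(sm_res._results_table.data)[1:, :2]],
                sm_res.reject,
            )
        }
        from earshare.stats import tukey_significance_matrix

        arrays = {k: np.asarray(v) for k, v in groups.items()}
        df_err = sum(a.size for a in arrays.values()) - len(arrays)
        pooled = sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()) / df_err
        mine = tukey_significance_matrix(
            {k: a.mean() for k, a in arrays.items()}, pooled,
            {k: a.size for k, a in arrays.items()}, df_err,
        )
        for (a, b), rej in sm_reject.items():
            assert bool(mine.loc[a, b]) == bool(rej)

    def test_letters_consistent_with_significance(self):
        # sharing a letter must coincide with non-significance
        rng = np.random.default_rng(33)
        groups = {k: rng.normal(m, 1.0, 4) for k, m in
                  [("a", 0.0), ("b", 0.8), ("c", 4.0)]}
        from earshare.stats import tukey_significance_matrix

        arrays = {k: np.asarray(v) for k, v in groups.items()}
        df_err = sum(a.size for a in arrays.values()) - len(arrays)
        pooled = sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()) / df_err
        means = {k: a.mean() for k, a in arrays.items()}
        sig = tukey_significance_matrix(means, pooled,
                                        {k: a.size for k, a in arrays.items()}, df_err)
        letters = letters_from_significance(sig, means)
        for a in groups:
            for b in groups:
                if a == b:
                    continue
                shared = set(letters[a]) & set(letters[b])
                assert bool(shared) == (not sig.loc[a, b])


class TestTwoWayAnova:
    def test_genotype_by_organ_table_has_stars(self):
        rng = np.random.default_rng(4)
        rows = []
        for g in ("G1", "G2"):
            for organ, mu in [("awns", -25.4), ("flag_leaf", -29.7)]:
                for _ in range(3):
                    rows.append({"genotype": g, "organ": organ,
                                 "delta13C": rng.normal(mu, 0.2)})
        table = two_way_anova(pd.DataFrame(rows), "delta13C", "genotype", "organ")
        assert "stars" in table.columns
        assert table.loc["C(B)", "PR(>F)"] < 0.001  # organ effect dominates


class TestYieldDeltaRelationship:
    def test_strictly_decreasing_yield_gives_negative_r(self):
        df = pd.DataFrame({"delta_grain": [-27.0, -26.5, -26.0, -25.5],
                           "grain_yield": [7.4, 7.0, 6.6, 6.2]})
        rel = yield_delta_relationship(df)
        assert rel.pearson_r < 0

    def test_negative_coupling_detected_in_synthetic_trials(self):
        from earshare.io import build_plot_profiles
        from earshare.simulate import SyntheticTrialConfig, generate_trial, trial_records

        negative = 0
        n_seeds = 40
        for seed in range(n_seeds):
            tables = generate_trial(SyntheticTrialConfig(seed=seed))
            profiles, _ = build_plot_profiles(trial_records(tables), tables.agronomy)
            rel = yield_delta_relationship(
                pd.DataFrame({"delta_grain": [p.delta_grain for p in profiles],
                              "grain_yield": [p.grain_yield for p in profiles]})
            )
            negative += rel.pearson_r < 0
        assert negative / n_seeds >= 0.95

    def test_exact_quadratic_is_interpolated(self):
        x = np.array([-27.0, -26.4, -25.9, -25.3])
        y = 2.0 + 0.5 * (x + 26.0) - 0.3 * (x + 26.0) ** 2
        rel = yield_delta_relationship(pd.DataFrame({"delta_grain": x, "grain_yield": y}))
        fitted = np.polyval(rel.quadratic_coeffs, x)
        assert np.allclose(fitted, y, atol=1e-8)

    def test_constant_yield_flagged(self):
        df = pd.DataFrame({"delta_grain": [-27.0, -26.5, -26.0, -25.5],
                           "grain_yield": [7.0] * 4})
        rel = yield_delta_relationship(df)
        assert rel.constant_yield and np.isnan(rel.pearson_r)
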