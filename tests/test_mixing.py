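import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from earshare.io import profiles_to_frame
from earshare.mixing import (
    GrainMixingModel,
    WaterStatusBins,
    assign_bin,
    assign_bin_flagged,
    bootstrap_weights,
    closed_form_fraction,
    estimate_bin_weights,
    flag_contribution_extrapolation,
    predict_grain_delta,
    round_half_up,
    summarize_contributions,
    validate_fit,
)
from earshare.types import DegenerateEndMembersError


def grid_search_weight(da, db, dg, step=1e-4):
    """Independent oracle: exhaustive search of the bin weight on a fine grid."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pred = np.outer(np.asarray(da) - np.asarray(db), grid) + np.asarray(db)[:, None]
    sse = ((np.asarray(dg)[:, None] - pred) ** 2).sum(axis=0)
    return grid[int(np.argmin(sse))]


class TestClosedFormFraction:
    def test_grain_at_source_a_gives_one(self):
        f = closed_form_fraction(-25.4, -25.4, -26.9)
        assert f.fraction == 1.0 and not f.out_of_range

    def test_midpoint_gives_half(self):
        f = closed_form_fraction(-26.15, -25.4, -26.9)
        assert f.fraction == pytest.approx(0.5)

    def test_occasion_averaged_trial_geometry(self):
        # grain -26.3 between awns -25.75 and peduncle -27.55
        f = closed_form_fraction(-26.3, -25.75, -27.55)
        assert f.fraction == pytest.approx(0.6944, abs=5e-4)
        assert not f.out_of_range

    def test_out_of_interval_flagged_not_clipped(self):
        f = closed_form_fraction(-25.0, -25.4, -26.9)
        assert f.fraction > 1.0 and f.out_of_range

    def test_identical_end_members_degenerate(self):
        with pytest.raises(DegenerateEndMembersError):
            closed_form_fraction(-26.0, -26.0, -26.0)


class TestAssignBin:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (-25.5, "least_favourable"),
            (-26.7, "most_favourable"),
            (-26.1, "intermediate"),
            (-25.8, "least_favourable"),  # closed endpoint
            (-26.4, "most_favourable"),
        ],
    )
    def test_interval_membership(self, value, expected):
        assert assign_bin(value) == expected

    @pytest.mark.parametrize(
        "value, expected", [(-25.0, "least_favourable"), (-27.3, "most_favourable")]
    )
    def test_outside_support_snaps_to_nearest_and_flags(self, value, expected):
        label, outside = assign_bin_flagged(value)
        assert label == expected and outside

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            WaterStatusBins(edges={"a": (-27.0, -26.0), "b": (-26.5, -25.5)})


class TestPredictGrainDelta:
    def test_pure_source_a(self):
        assert predict_grain_delta(1.0, -25.75, -27.55) == -25.75

    @pytest.mark.parametrize(
        "w, da, db, expected",
        [
            (0.58, -25.75, -27.55, -26.506),  # most favourable weights
            (0.90, -25.40, -26.90, -25.550),  # least favourable weights
        ],
    )
    def test_printed_weight_combinations(self, w, da, db, expected):
        assert predict_grain_delta(w, da, db) == pytest.approx(expected, abs=1e-9)

    def test_trial_geometry_predicts_near_observed_grain_mean(self):
        # occasion-averaged end members with the most-favourable weights land
        # within 0.35 permil of the observed grain mean of -26.3
        assert abs(predict_grain_delta(0.58, -25.75, -27.55) - (-26.3)) <= 0.35

    @given(
        w=st.floats(0, 1, exclude_max=True),
        dw=st.floats(1e-6, 0.5),
        da=st.floats(-26.5, -25.0),
        gap=st.floats(0.5, 3.0),
    )
    def test_strictly_increasing_in_weight_when_a_heavier(self, w, dw, da, gap):
        db = da - gap
        w2 = min(1.0, w + dw)
        assert predict_grain_delta(w2, da, db) > predict_grain_delta(w, da, db)


class TestValidateFit:
    def test_perfect_agreement(self):
        y = [-26.5, -25.9, -25.4]
        d = validate_fit(y, y)
        assert d.slope == pytest.approx(1.0) and d.rsquared == pytest.approx(1.0)
        assert d.slope_ok

    def test_doubled_observations_give_slope_two_r2_one(self):
        x = np.array([-26.5, -25.9, -25.4])
        d = validate_fit(2 * x, x)
        assert d.slope == pytest.approx(2.0)
        assert d.rsquared == pytest.approx(1.0)
        assert not d.slope_ok

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            validate_fit([-26.0, -25.5], [-26.0, -25.5])


class TestEstimateBinWeights:
    def test_noise_free_fixture_recovers_printed_weights_exactly(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        bw = estimate_bin_weights(frame, "peduncle")
        assert bw.weight("least_favourable") == pytest.approx(0.90, abs=1e-9)
        assert bw.weight("most_favourable") == pytest.approx(0.58, abs=1e-9)
        bw_flag = estimate_bin_weights(frame, "flag_leaf")
        assert bw_flag.weight("least_favourable") == pytest.approx(0.97, abs=1e-9)
        assert bw_flag.weight("most_favourable") == pytest.approx(0.82, abs=1e-9)
        assert bw.diagnostics.slope == pytest.approx(1.0, abs=1e-9)
        assert bw.diagnostics.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_weights_of_both_end_members_sum_to_one(self, worked_profiles):
        bw = estimate_bin_weights(profiles_to_frame(worked_profiles), "peduncle")
        occupied = bw.per_bin.dropna(subset=["weight_a"])
        assert np.allclose(occupied["weight_a"] + occupied["weight_b"], 1.0, atol=1e-12)

    def test_single_plot_per_bin_equals_closed_form(self):
        frame = pd.DataFrame(
            [
                {"plot_id": "a", "delta_awns": -25.4, "delta_peduncle": -26.9,
                 "delta_grain": -25.55},
                {"plot_id": "b", "delta_awns": -26.1, "delta_peduncle": -27.9,
                 "delta_grain": -26.75},
            ]
        )
        bw = estimate_bin_weights(frame, "peduncle")
        for _, row in frame.iterrows():
            f = closed_form_fraction(
                row["delta_grain"], row["delta_awns"], row["delta_peduncle"]
            )
            label = assign_bin(row["delta_grain"])
            assert bw.weight(label) == pytest.approx(
                min(1.0, max(0.0, f.fraction)), abs=1e-9
            )
            # and agrees with the exhaustive grid oracle to one grid step
            w_grid = grid_search_weight(
                [row["delta_awns"]], [row["delta_peduncle"]], [row["delta_grain"]]
            )
            assert abs(bw.weight(label) - w_grid) <= 1e-4

    def test_matches_grid_search_oracle_on_random_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(25):
            n = rng.integers(2, 8)
            da = rng.uniform(-26.3, -25.2, n)
            db = da - rng.uniform(0.8, 2.5, n)
            w_true = rng.uniform(0.0, 1.0)
            dg = w_true * da + (1 - w_true) * db + rng.normal(0, 0.15, n)
            bins = WaterStatusBins(edges={"all": (-40.0, -10.0)})
            bw = estimate_bin_weights(
                pd.DataFrame({"plot_id": [f"p{i}" for i in range(n)],
                              "delta_awns": da, "delta_peduncle": db,
                              "delta_grain": dg}),
                "peduncle", bins=bins,
            )
            w_grid = grid_search_weight(da, db, dg)
            assert abs(bw.weight("all") - w_grid) <= 1e-4

    def test_out_of_interval_grain_clips_with_flag(self):
        frame = pd.DataFrame(
            [{"plot_id": "a", "delta_awns": -25.9, "delta_peduncle": -27.4,
              "delta_grain": -25.3}]  # grain above awns: raw weight > 1
        )
        with pytest.warns(UserWarning, match="one water-status bin"):
            bw = estimate_bin_weights(frame, "peduncle")
        row = bw.per_bin.set_index("bin").loc["least_favourable"]
        assert row["weight_a"] == 1.0 and row["clipped"]

    def test_single_occupied_bin_warns_unidentifiable(self):
        frame = pd.DataFrame(
            {"plot_id": ["a", "b", "c"],
             "delta_awns": [-25.7, -25.75, -25.8],
             "delta_peduncle": [-27.5, -27.55, -27.6],
             "delta_grain": [-26.5, -26.55, -26.6]}
        )
        with pytest.warns(UserWarning, match="unidentifiable"):
            estimate_bin_weights(frame, "peduncle")


class TestFlagExtrapolation:
    @pytest.mark.parametrize(
        "args, raw, rounded",
        [
            ((58.0, 18.0, 82.0), 12.73, 13),  # most favourable conditions
            ((90.0, 3.0, 97.0), 2.78, 3),  # least favourable conditions
        ],
    )
    def test_printed_bin_combinations(self, args, raw, rounded):
        got_raw, got_int = flag_contribution_extrapolation(*args)
        assert got_raw == pytest.approx(raw, abs=5e-3)
        assert got_int == rounded

    def test_zero_flag_weight_gives_zero(self):
        assert flag_contribution_extrapolation(70.0, 0.0, 100.0) == (0.0, 0)

    def test_zero_awn_weight_with_nonzero_flag_undefined(self):
        with pytest.raises(ZeroDivisionError):
            flag_contribution_extrapolation(70.0, 10.0, 0.0)


class TestContributionReport:
    def test_worked_example_shares(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        report = summarize_contributions(
            estimate_bin_weights(frame, "peduncle"),
            estimate_bin_weights(frame, "flag_leaf"),
        )
        per_bin = report.per_bin.set_index("bin")
        assert per_bin.loc["least_favourable", "flag_share"] == 3
        assert per_bin.loc["most_favourable", "flag_share"] == 13
        assert round_half_up(report.bin_mean["flag_share"]) == 8
        assert report.awn_flag_ratio == pytest.approx(82 / 18, abs=1e-9)
        assert report.awn_flag_ratio_rounded == 5

    def test_per_bin_shares_conserve_100_percent(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        report = summarize_contributions(
            estimate_bin_weights(frame, "peduncle"),
            estimate_bin_weights(frame, "flag_leaf"),
        )
        occ = report.per_bin.dropna(subset=["ear_share"])
        assert np.allclose(occ["ear_share"] + occ["shoot_share"], 100.0, atol=1e-9)

    def test_constant_weight_gives_same_average_under_both_conventions(self):
        # three bins all at w = 0.7 but different occupancy
        rng = np.random.default_rng(5)
        rows = []
        centers = {"most_favourable": -26.7, "intermediate": -26.1,
                   "least_favourable": -25.5}
        counts = {"most_favourable": 3, "intermediate": 7, "least_favourable": 2}
        for label, n in counts.items():
            for i in range(n):
                db = centers[label] - 0.7 * 1.5 + rng.normal(0, 0.02)
                da = db + 1.5
                rows.append({"plot_id": f"{label}{i}", "delta_awns": da,
                             "delta_peduncle": db, "delta_flag": db - 2.0,
                             "delta_grain": 0.7 * da + 0.3 * db})
        frame = pd.DataFrame(rows)
        report = summarize_contributions(
            estimate_bin_weights(frame, "peduncle"),
            estimate_bin_weights(frame, "flag_leaf"),
        )
        assert report.bin_mean["ear_share"] == pytest.approx(70.0, abs=1e-6)
        assert report.plot_weighted_mean["ear_share"] == pytest.approx(70.0, abs=1e-6)

    def test_mismatched_bins_rejected(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        other = WaterStatusBins(edges={"most_favourable": (-27.5, -26.4),
                                       "least_favourable": (-25.8, -25.0)})
        with pytest.raises(ValueError, match="bin"):
            summarize_contributions(
                estimate_bin_weights(frame, "peduncle"),
                estimate_bin_weights(frame, "flag_leaf", bins=other),
            )


class TestBootstrap:
    def test_deterministic_given_seed(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        a = bootstrap_weights(frame, n_boot=200, seed=42)
        b = bootstrap_weights(frame, n_boot=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_intervals_are_zero_width(self, worked_profiles):
        frame = profiles_to_frame(worked_profiles)
        ci = bootstrap_weights(frame, n_boot=200, seed=1).set_index("bin")
        for label, w in [("least_favourable", 0.90), ("most_favourable", 0.58)]:
            assert ci.loc[label, "weight_lo"] == pytest.approx(w, abs=1e-9)
            assert ci.loc[label, "weight_hi"] == pytest.approx(w, abs=1e-9)

    def test_bin_with_too_few_plots_reports_missing_interval(self):
        frame = pd.DataFrame(
            [{"plot_id": "a", "delta_awns": -25.4, "delta_peduncle": -26.9,
              "delta_grain": -25.55}]
        )
        ci = bootstrap_weights(frame, n_boot=100, seed=0).set_index("bin")
        assert np.isnan(ci.loc["least_favourable", "weight_lo"])

    def test_seed_required(self, worked_profiles):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_weights(profiles_to_frame(worked_profiles), n_boot=100)


class TestModelResultsApi:
    def test_model_fit_summary_and_residuals(self, worked_profiles):
        res = GrainMixingModel(worked_profiles).fit()
        assert res.model.nobs == 6
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.resid, 0.0, atol=1e-9)
        text = res.summary()
        assert "awns vs peduncle" in text and "0.900" in text and "0.580" in text

    def test_declared_translocation_offset_recovers_weights(self, worked_profiles):
        # shift all grain values by a constant fractionation and declare it:
        # within each bin the recovered weight must match the unshifted fit
        frame = profiles_to_frame(worked_profiles)
        shifted = frame.assign(delta_grain=frame["delta_grain"] + 0.1)
        res = GrainMixingModel(shifted, translocation_offset=0.1).fit()
        assert res.weight("least_favourable") == pytest.approx(0.90, abs=1e-9)
        assert res.weight("most_favourable") == pytest.approx(0.58, abs=1e-9)
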