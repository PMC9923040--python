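"""Summary tables: counting oracles, rounding convention, histogram, fits."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from h2slog import (
    DayMetrics,
    Peak,
    day_max_histogram,
    max_twa_fit,
    metrics_frame,
    peak_count_table,
    percent,
    seg_summary_table,
    tendency_table,
)

D0 = date(2019, 1, 7)
T0 = None


def _metric(i=0, seg="plant", person="W1", max_level=0.0, twa=0.0, peaks=(), duration=300.0):
    above_lod = max_level >= 1.6
    return DayMetrics(
        person_id=person, seg=seg, date=D0 + timedelta(days=i), duration_min=duration,
        twa=twa, stel_max=min(max_level, twa + max_level) if max_level else 0.0,
        max_level=max_level, peaks=list(peaks), n_peaks=len(peaks),
        above_lod=above_lod, above_cv=max_level > 10.0,
        twa_gt_oel=twa > 5.0, twa_gt_tenth_oel=twa > 0.5,
    )


def _peak(height, band):
    from datetime import datetime

    return Peak(datetime(2019, 1, 7, 8), 15.0, height, band, height >= 101)


class TestPercent:
    @pytest.mark.parametrize(
        "n, d, expected",
        [(424, 7083, 6), (424, 1295, 33), (1295, 7083, 18), (53, 1112, 5),
         (78, 944, 8), (78, 213, 37), (0, 100, 0)],
    )
    def test_integer_rounding_half_away_from_zero(self, n, d, expected):
        assert percent(n, d) == expected

    def test_exact_half_rounds_up(self):
        assert percent(1, 8) == 13  # 12.5 -> 13, not banker's 12

    def test_decimals_and_zero_denominator(self):
        assert percent(1, 3, decimals=2) == 33.33
        assert percent(1, 0) is None


class TestSegSummary:
    def test_counts_recovered_from_planted_flags(self):
        mets = (
            [_metric(i, "plant", "W1", max_level=12.0, twa=0.6) for i in range(3)]
            + [_metric(i, "plant", "W2", max_level=5.0) for i in range(2)]
            + [_metric(i, "plant", "W2", max_level=0.0) for i in range(5)]
            + [_metric(i, "water_net", "W3", max_level=2.0) for i in range(4)]
        )
        table = seg_summary_table(mets)
        plant = table.loc["plant"]
        assert plant["n_persons"] == 2 and plant["n_days"] == 10
        assert plant["n_above_lod"] == 5 and plant["pct_above_lod"] == 50
        assert plant["n_above_cv"] == 3 and plant["pct_above_cv_given_lod"] == 60
        assert plant["n_twa_gt_tenth"] == 3
        assert (plant["days_per_person_min"], plant["days_per_person_max"]) == (3, 7)

    def test_total_row_sums_seg_counts(self, study_metrics):
        table = seg_summary_table(study_metrics)
        for col in ["n_persons", "n_days", "n_above_lod", "n_above_cv", "n_twa_gt_tenth"]:
            assert table.loc["total", col] == table.drop("total")[col].sum()

    def test_conditional_cv_percentage_dominates_marginal(self, study_metrics):
        table = seg_summary_table(study_metrics)
        sel = table[table["n_above_lod"] < table["n_days"]].dropna(
            subset=["pct_above_cv_given_lod"]
        )
        assert (sel["pct_above_cv_given_lod"] >= sel["pct_above_cv"]).all()

    def test_empty_input_gives_zero_rows(self):
        table = seg_summary_table(metrics_frame([]))
        assert (table["n_days"] == 0).all()

    def test_unknown_seg_label_rejected(self):
        frame = metrics_frame([_metric()])
        frame.loc[0, "seg"] = "office"
        with pytest.raises(ValueError, match="unknown SEG"):
            seg_summary_table(frame)


class TestHistogram:
    def test_all_censored_fall_in_terminal_bin(self):
        hist = day_max_histogram(np.full(7, 101.0))
        assert hist["count"].sum() == 7
        assert hist["count"].iloc[-1] == 7

    def test_cv_boundary_splits_ten_and_ten_point_one(self):
        hist = day_max_histogram(np.array([10.0, 10.1]))
        in_bin = lambda v: hist[(hist["left"] <= v) & (v < hist["right"])].index[0]
        assert in_bin(10.0) != in_bin(10.1)

    def test_counts_match_direct_tally(self):
        rng = np.random.default_rng(3)
        values = np.round(rng.uniform(1.6, 100.0, size=500), 1)
        hist = day_max_histogram(values, bin_width=0.5)
        assert hist["count"].sum() == 500
        edges = np.r_[hist["left"].to_numpy(), hist["right"].iloc[-1]]
        np.testing.assert_array_equal(
            hist["count"].to_numpy(), np.histogram(values, bins=edges)[0]
        )

    def test_day_metrics_input_restricted_to_detected_days(self, study_metrics):
        n_det = sum(m.above_lod for m in study_metrics)
        assert day_max_histogram(study_metrics)["count"].sum() == n_det

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            day_max_histogram(np.array([5.0]), bin_width=0.0)
        with pytest.raises(ValueError, match="above-LOD"):
            day_max_histogram(np.array([0.5]))


class TestTendency:
    def test_identical_twas_have_equal_median_and_mode(self):
        mets = [_metric(i, max_level=5.0, twa=0.04) for i in range(5)]
        row = tendency_table(mets).loc["plant"]
        assert row["median_twa_pos"] == pytest.approx(0.04)
        assert row["mode_twa_pos"] == pytest.approx(0.04)
        assert row["mode_twa_n"] == 5

    def test_planted_maximum_recovered(self):
        mets = [_metric(0, max_level=25.0, twa=5.10)] + [
            _metric(i, max_level=3.0, twa=0.01) for i in range(1, 4)
        ]
        table = tendency_table(mets)
        assert table.loc["total", "max_twa"] == pytest.approx(5.10)
        assert table.loc["total", "max_level_display"] == "25"

    def test_overload_day_renders_censored_maximum(self):
        mets = [_metric(0, max_level=101.0, twa=0.2)]
        assert tendency_table(mets).loc["plant", "max_level_display"] == ">100"

    def test_below_lod_days_excluded(self):
        mets = [_metric(0, max_level=0.0, twa=0.0), _metric(1, max_level=2.0, twa=0.01)]
        assert tendency_table(mets).loc["plant", "n_days"] == 1


class TestPeakCounts:
    def test_single_low_peak_every_day(self):
        mets = [
            _metric(i, max_level=3.0, peaks=[_peak(3.0, "low")]) for i in range(6)
        ]
        row = peak_count_table(mets).loc["plant"]
        assert row["low_max"] == 1 and row["low_median"] == 1
        assert row["all_max"] == 1 and row["all_median"] == 1
        assert row["high_max"] == 0

    def test_planted_heavy_day_dominates_maxima(self):
        heavy = _metric(
            0, "plant", max_level=50.0,
            peaks=[_peak(2.0, "low")] * 46 + [_peak(12.0, "high")] * 8,
        )
        quiet = [_metric(i, "plant", max_level=2.0, peaks=[_peak(2.0, "low")]) for i in range(1, 10)]
        table = peak_count_table([heavy] + quiet)
        assert table.loc["plant", "all_max"] == 54
        assert table.loc["plant", "high_max"] == 8
        assert table.loc["total", "all_max"] == 54

    def test_counts_match_brute_tally(self, study_metrics):
        table = peak_count_table(study_metrics)
        per_day = [m.n_peaks for m in study_metrics if m.above_lod]
        assert table.loc["total", "all_max"] == max(per_day)
        assert table.loc["total", "all_median"] == float(np.median(per_day))
        assert table.loc["total", "n_days"] == len(per_day)


class TestMaxTwaFit:
    def test_exact_power_law_has_unit_r_squared(self):
        twas = np.array([0.04, 0.09, 0.25, 1.0])  # keep day maxima above the LOD
        mets = [
            _metric(i, max_level=float(10 * t**0.5), twa=float(t))
            for i, t in enumerate(twas)
        ]
        fit = max_twa_fit(mets)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.5)

    def test_matches_closed_form_correlation(self, study_metrics):
        frame = metrics_frame(study_metrics)
        sel = frame[frame["above_lod"] & (frame["twa"] > 0)]
        x, y = np.log10(sel["twa"]), np.log10(sel["max_level"])
        fit = max_twa_fit(study_metrics)
        assert fit.n == len(sel)
        assert fit.r_squared == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2))

    def test_independent_variables_give_near_zero_r_squared(self):
        rng = np.random.default_rng(5)
        mets = [
            _metric(i, max_level=float(np.round(rng.uniform(1.6, 50), 1)),
                    twa=float(rng.lognormal(-4, 1)))
            for i in range(2000)
        ]
        assert max_twa_fit(mets).r_squared < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            max_twa_fit([_metric(0, max_level=5.0, twa=0.1)])
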