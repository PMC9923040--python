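"""Censored-data statistics: ECDF, rank tests, Bayesian contrasts, logistic
variance decomposition, lag-1 autocorrelation."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from h2slog import (
    CensoredSample,
    acf_lag1,
    assemble_person_days,
    bayes_prop_diff,
    build_workday_grid,
    cen_ecdf,
    compute_day_metrics,
    group_location_test,
    logistic_variance_decomposition,
    metrics_frame,
    normality_checks,
    pairwise_prop_contrasts,
)
from h2slog.day_assembly import WorkdayGrid


def _grid(series_by_person):
    rows = []
    for person, values in series_by_person.items():
        for i, v in enumerate(values):
            rows.append({"person_id": person, "date": date(2019, 1, 7) + timedelta(days=i),
                         "value": float(v), "status": "measured"})
    return WorkdayGrid("detected_zero", "max_level", pd.DataFrame(rows))


class TestCenEcdf:
    def test_all_censored_is_single_step_at_lod(self):
        f = cen_ecdf(CensoredSample(np.zeros(10)))
        assert f(1.5) == 0.0
        assert f(1.6) == 1.0
        assert f.frac_censored == 1.0

    def test_uncensored_reduces_to_ordinary_ecdf(self):
        values = np.array([2.0, 3.0, 3.0, 5.0])
        f = cen_ecdf(CensoredSample(values))
        for q in [1.9, 2.0, 3.0, 4.9, 5.0, 60.0]:
            assert f(q) == pytest.approx(np.mean(values <= q))

    def test_mixed_sample_matches_hand_tally(self):
        # 3 non-detects (block at 1.6) + readings 2.0, 2.0, 8.0
        f = cen_ecdf(CensoredSample(np.array([0.0, 0.0, 0.0, 2.0, 2.0, 8.0])))
        assert f(1.6) == pytest.approx(3 / 6)
        assert f(2.0) == pytest.approx(5 / 6)
        assert f(8.0) == 1.0
        assert np.all(np.diff(f.f) >= 0) and f.f[-1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cen_ecdf(CensoredSample(np.array([])))


def _kw_oracle(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    r = np.arange(1, len(pooled) + 1, dtype=float)
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = r[i:j].mean()
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        rsum = ranks[start : start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestGroupLocation:
    def test_identical_groups_do_not_reject(self):
        g = [0.0, 0.0, 1.8, 2.4, 5.0, 12.0]
        res = group_location_test([g, g, g])
        assert res.p_value > 0.95
        assert res.n_groups == 3

    def test_shifted_groups_reject_strongly(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0, 0.5, 300)
        b = a * 4
        res = group_location_test([a, b], include_nondetects=False)
        assert res.p_value < 1e-3

    def test_statistic_matches_first_principles_oracle(self):
        groups = [
            np.array([0.0, 0.0, 2.0, 3.0, 3.0]),
            np.array([0.0, 1.6, 1.6, 8.0]),
            np.array([0.0, 0.0, 0.0, 12.0, 50.0]),
        ]
        res = group_location_test(groups)
        assert res.statistic == pytest.approx(_kw_oracle(groups))

    def test_nondetects_enter_as_ties_at_zero(self):
        # sub-LOD values and true zeros must be indistinguishable in rank
        a = group_location_test([[0.0, 2.0], [1.0, 3.0]]).statistic
        b = group_location_test([[0.0, 2.0], [0.0, 3.0]]).statistic
        assert a == pytest.approx(b)

    def test_empty_group_after_filtering_rejected(self):
        with pytest.raises(ValueError, match="empty after filtering"):
            group_location_test([[0.0, 0.0], [2.0, 3.0]], include_nondetects=False)


class TestNormality:
    def test_gaussian_sample_not_rejected(self):
        rng = np.random.default_rng(12)
        res = normality_checks(rng.normal(10, 2, 400))
        assert not res.rejected

    def test_peaky_exposure_data_rejected_even_after_log(self, study_metrics):
        frame = metrics_frame(study_metrics)
        twa = frame.loc[frame["above_lod"] & (frame["twa"] > 0), "twa"].to_numpy()
        assert normality_checks(twa).rejected
        assert normality_checks(twa, log_transform=True).rejected

    def test_type_one_error_near_nominal_on_gaussian_replicates(self):
        rng = np.random.default_rng(31)
        rejections = sum(
            normality_checks(rng.normal(size=150)).rejected for _ in range(100)
        )
        # two tests at alpha=0.05 each: family-wise rate below ~10%, plus slack
        assert rejections <= 18

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_checks(np.full(10, 3.0))
        with pytest.raises(ValueError, match="at least 3"):
            normality_checks(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="positive"):
            normality_checks(np.array([0.0, 1.0, 2.0]), log_transform=True)


class TestBayesProportions:
    def test_identical_counts_do_not_differ(self):
        res = bayes_prop_diff(50, 500, 50, 500, seed=3)
        assert not res.differs
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_separated_proportions_differ(self):
        res = bayes_prop_diff(90, 100, 10, 100, seed=3)
        assert res.differs and res.ci95[0] > 0.6

    def test_published_sewerage_vs_plant_counts_do_not_differ(self):
        # CV-exceedance days: 73/1175 vs 257/3852
        res = bayes_prop_diff(73, 1175, 257, 3852, seed=3)
        assert not res.differs

    def test_antisymmetric_under_group_swap(self):
        ab = bayes_prop_diff(30, 200, 55, 300, n_mc=200_000, seed=5)
        ba = bayes_prop_diff(55, 300, 30, 200, n_mc=200_000, seed=6)
        assert ab.ci95[0] == pytest.approx(-ba.ci95[1], abs=0.01)
        assert ab.ci95[1] == pytest.approx(-ba.ci95[0], abs=0.01)
        assert ab.differs == ba.differs

    def test_pairwise_covers_all_pairs(self):
        counts = {"a": (1, 10), "b": (2, 10), "c": (3, 10)}
        out = pairwise_prop_contrasts(counts, seed=0)
        assert {(c.seg_a, c.seg_b) for c in out} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bayes_prop_diff(11, 10, 0, 10)


def _detect_frame(rng, worker_probs, n_days, seg_of):
    rows = []
    for worker, p in worker_probs.items():
        flags = rng.random(n_days) < p
        for f in flags:
            rows.append({"person_id": worker, "seg": seg_of[worker], "above_lod": bool(f)})
    return pd.DataFrame(rows)


class TestLogisticDecomposition:
    def test_single_worker_per_seg_aliases_models(self):
        rng = np.random.default_rng(2)
        frame = _detect_frame(
            rng, {"w1": 0.1, "w2": 0.4}, 200, {"w1": "plant", "w2": "water_net"}
        )
        res = logistic_variance_decomposition(frame)
        assert res.minus2ll("worker") == pytest.approx(res.minus2ll("seg_plus_worker"), abs=1e-3)
        assert res.p_seg_added_to_worker == 1.0

    def test_worker_heterogeneity_recovered(self):
        rng = np.random.default_rng(7)
        probs = {f"a{i}": p for i, p in enumerate([0.02, 0.1, 0.3, 0.5])}
        probs |= {f"b{i}": p for i, p in enumerate([0.05, 0.15, 0.25, 0.45])}
        seg_of = {w: ("plant" if w[0] == "a" else "water_net") for w in probs}
        frame = _detect_frame(rng, probs, 150, seg_of)
        res = logistic_variance_decomposition(frame)
        assert res.within_worker_dominates
        assert res.minus2ll("worker") < res.minus2ll("seg")

    def test_seg_only_effects_leave_worker_model_uncompetitive(self):
        rng = np.random.default_rng(8)
        probs = {f"a{i}": 0.1 for i in range(4)} | {f"b{i}": 0.4 for i in range(4)}
        seg_of = {w: ("plant" if w[0] == "a" else "water_net") for w in probs}
        res = logistic_variance_decomposition(_detect_frame(rng, probs, 150, seg_of))
        assert not res.within_worker_dominates
        assert res.p_worker_vs_seg > 0.05

    def test_nested_minus2ll_ordering(self, study_cohort, study_metrics):
        frame = metrics_frame(study_metrics)
        res = logistic_variance_decomposition(frame)
        tol = 1e-6
        assert res.minus2ll("seg_plus_worker") <= res.minus2ll("worker") + tol
        assert res.minus2ll("seg_plus_worker") <= res.minus2ll("seg") + tol

    def test_too_few_levels_rejected(self):
        frame = pd.DataFrame(
            {"person_id": ["w"] * 4, "seg": ["plant"] * 4, "above_lod": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError):
            logistic_variance_decomposition(frame)


class TestAcfLag1:
    def test_alternating_series_is_minus_one(self):
        assert acf_lag1(_grid({"w": [0, 1] * 20})) == pytest.approx(-1.0)

    def test_constant_series_reported_missing(self):
        assert np.isnan(acf_lag1(_grid({"w": [3.0] * 10})))

    def test_iid_series_near_zero(self):
        rng = np.random.default_rng(21)
        grid = _grid({f"w{i}": rng.exponential(1.0, 250) for i in range(4)})
        n_pairs = 4 * 249
        assert abs(acf_lag1(grid)) < 3 / np.sqrt(n_pairs)

    def test_pairs_never_span_persons(self):
        # both persons alternate, but ending/starting on the same value: a
        # junction pair across persons would spoil the perfect -1
        grid = _grid({"w1": [0.0, 1.0] * 10, "w2": [1.0, 0.0] * 10})
        assert acf_lag1(grid) == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            acf_lag1(_grid({"w": [1.0]}))

    def test_imputation_schemes_computable_on_synthetic_days(self, study_metrics):
        for scheme in ("calendar_zero", "detected_zero", "detected_only"):
            grid = build_workday_grid(study_metrics, scheme=scheme, value_field="max_level")
            r = acf_lag1(grid)
            assert np.isfinite(r) and abs(r) < 0.5
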