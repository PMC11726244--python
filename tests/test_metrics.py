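"""Evaluation suite vs brute-force oracles, hand computations, and nulls."""

import numpy as np
import pytest

from gliorisk.metrics import (
    bootstrap_ci,
    brier_score,
    censoring_km,
    ctd_index,
    ece_calibration,
    integrated_brier,
    km_estimator,
    km_survival_at,
    logrank_test,
    step_lookup,
    stratify_median,
    td_auc,
)


def _random_instance(rng, n, n_bins=8, censor=0.3):
    times = rng.exponential(20, n) + 0.5
    events = (rng.random(n) > censor).astype(int)
    edges = np.linspace(0, times.max() * 1.1, n_bins + 1)
    h = rng.uniform(0.02, 0.4, size=(n, n_bins))
    S = np.concatenate([np.ones((n, 1)), np.cumprod(1 - h, axis=1)], axis=1)
    return S, edges, times, events


def ctd_brute_force(S, edges, times, events):
    """Exhaustive O(n^2) pair enumeration of Antolini's estimator."""
    n = len(times)
    conc = total = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        # survival at the end of the right-closed bin containing T_i
        ji = min(max(np.searchsorted(edges, times[i], side="left"), 1), S.shape[1] - 1)
        for j in range(n):
            if j == i:
                continue
            if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                si, sj = S[i, ji], S[j, ji]
                conc += 1.0 if si < sj else (0.5 if si == sj else 0.0)
                total += 1
    return conc / total


class TestCtd:
    def test_perfectly_anti_ordered(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        edges = np.array([0.0, 5.0])
        S = np.array([[1, 0.1], [1, 0.4], [1, 0.7], [1, 0.9]])
        assert ctd_index(S, edges, times, events) == 1.0

    def test_shared_curve_is_half(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 0])
        edges = np.array([0.0, 4.0])
        S = np.tile([1.0, 0.5], (3, 1))
        assert ctd_index(S, edges, times, events) == 0.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            S, edges, times, events = _random_instance(rng, 25)
            if events.sum() == 0:
                continue
            assert ctd_index(S, edges, times, events) == pytest.approx(
                ctd_brute_force(S, edges, times, events), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        S, edges, times, events = _random_instance(rng, 30)
        a = ctd_index(S, edges, times, events)
        b = ctd_index(np.sqrt(S), edges, times, events)  # strictly monotone map
        assert a == b

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            ctd_index(np.ones((3, 2)), np.array([0.0, 1.0]), [1, 2, 3], [0, 0, 0])


class TestKM:
    def test_no_censoring_equals_empirical(self):
        times = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        km = km_estimator(times, np.ones(5, dtype=int))
        for t in [0.5, 1.0, 3.5, 5.0]:
            assert km_survival_at(km, t) == pytest.approx(np.mean(times > t))

    def test_all_censored_flat_one(self):
        km = km_estimator([2.0, 3.0], [0, 0])
        assert km_survival_at(km, 10.0) == 1.0

    def test_textbook_hand_computation(self):
        # times: events at 6 (3 tied), 10, 13; censored at 6, 9, 11, 16
        times = np.array([6, 6, 6, 6, 9, 10, 11, 13, 16, 20.0])
        events = np.array([1, 1, 1, 0, 0, 1, 0, 1, 0, 0])
        km = km_estimator(times, events)
        # S(6) = 1 - 3/10; S(10) = 0.7 * (1 - 1/5); S(13) = 0.56 * (1 - 1/3)
        assert km_survival_at(km, 6) == pytest.approx(0.7)
        assert km_survival_at(km, 10) == pytest.approx(0.7 * 4 / 5)
        assert km_survival_at(km, 13) == pytest.approx(0.7 * 4 / 5 * 2 / 3)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_small_instance(self):
        # group A: events at 1, 3; group B: event at 2, censored at 4
        ta, ea = np.array([1.0, 3.0]), np.array([1, 1])
        tb, eb = np.array([2.0, 4.0]), np.array([1, 0])
        # t=1: n=4, nA=2, d=1 -> eA=.5, v=.25
        # t=2: n=3, nA=1, d=1 -> eA=1/3, v=2/9
        # t=3: n=2, nA=1, d=1 -> eA=.5,  v=.25
        o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5)
        var = 0.25 + 2 / 9 + 0.25
        chi2, _ = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestTdAuc:
    def test_perfect_separation(self):
        times = np.array([10.0, 20, 50, 60])
        events = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        assert td_auc(scores, times, events, horizon=36) == 1.0

    def test_equals_rank_auc_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(30, 80) + 0.1
        events = np.ones(80, dtype=int)
        scores = -times + rng.normal(0, 10, 80)
        horizon = float(np.median(times))
        case = times <= horizon
        gt = (scores[case][:, None] > scores[~case][None, :]).mean()
        eq = (scores[case][:, None] == scores[~case][None, :]).mean()
        assert td_auc(scores, times, events, horizon) == pytest.approx(gt + 0.5 * eq, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 500
        times = rng.exponential(40, n) + 0.5
        events = (rng.random(n) < 0.85).astype(int)
        auc = td_auc(rng.random(n), times, events, horizon=30.0)
        assert abs(auc - 0.5) < 0.06

    def test_no_cases_raises(self):
        with pytest.raises(ValueError):
            td_auc([0.1, 0.2], [50.0, 60.0], [1, 1], horizon=36)


class TestBrier:
    def test_overconfident_survivor_prediction(self):
        # everyone has the event before t but S == 1 -> BS = 1
        times = np.array([1.0, 2.0, 3.0])
        events = np.ones(3, dtype=int)
        edges = np.array([0.0, 10.0])
        S = np.ones((3, 2))
        assert brier_score(S, edges, times, events, 5.0) == pytest.approx(1.0)

    def test_equals_mse_without_censoring(self):
        rng = np.random.default_rng(8)
        S, edges, times, _ = _random_instance(rng, 40, censor=0.0)
        events = np.ones(40, dtype=int)
        t = float(np.median(times))
        S_t = step_lookup(edges, S, t)
        mse = np.mean(((times > t).astype(float) - S_t) ** 2)
        assert brier_score(S, edges, times, events, t) == pytest.approx(mse, abs=1e-12)

    def test_integrated_matches_double_loop(self):
        rng = np.random.default_rng(9)
        S, edges, times, _ = _random_instance(rng, 25, censor=0.0)
        events = np.ones(25, dtype=int)
        grid = np.linspace(1.0, np.quantile(times, 0.8), 7)
        # brute-force: trapezoid over pointwise mean-squared errors
        bs = []
        for t in grid:
            tot = 0.0
            for i in range(25):
                s_i = S[i, max(np.searchsorted(edges, t, side="right") - 1, 0)]
                tot += ((1.0 if times[i] > t else 0.0) - s_i) ** 2
            bs.append(tot / 25)
        expect = np.trapezoid(bs, grid) / (grid[-1] - grid[0])
        assert integrated_brier(S, edges, times, events, grid) == pytest.approx(expect, abs=1e-10)

    def test_censoring_km_zero_raises(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 0, 0])
        # censoring KM hits 0 at t=3 (last censoring); evaluating beyond raises
        with pytest.raises(ValueError, match="censoring"):
            brier_score(np.ones((3, 2)), np.array([0.0, 10.0]), times, events, 5.0)


class TestECE:
    def test_true_probabilities_calibrated(self):
        rng = np.random.default_rng(1)
        n = 2000
        p_surv = rng.uniform(0.2, 0.95, n)  # per-subject true S(horizon)
        event_by_h = rng.random(n) > p_surv
        times = np.where(event_by_h, rng.uniform(1, 36, n), 36.5)
        events = event_by_h.astype(int)
        ece, _ = ece_calibration(p_surv, times, events, n_bins=10, horizon=36)
        assert ece < 0.05

    def test_perfect_prediction_zero(self):
        n = 50
        ece, tbl = ece_calibration(np.ones(n), np.full(n, 40.0), np.zeros(n, dtype=int),
                                   horizon=36)
        assert ece == 0.0 and len(tbl) == 1

    def test_two_bin_hand_example(self):
        # no censoring: bin A preds .9 (4 subjects, 1 event); bin B preds .2 (2, 2 events)
        preds = np.array([0.9, 0.9, 0.9, 0.9, 0.2, 0.2])
        times = np.array([40, 40, 40, 10, 5, 8.0])
        events = np.array([0, 0, 0, 1, 1, 1])
        ece, tbl = ece_calibration(preds, times, events, n_bins=10, horizon=36)
        expect = 4 / 6 * abs(0.9 - 0.75) + 2 / 6 * abs(0.2 - 0.0)
        assert ece == pytest.approx(expect, abs=1e-12)


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        res = bootstrap_ci(lambda idx: 3.5, 20, n_boot=50, seed=0, name="c")
        assert res.ci_low == res.ci_high == res.point == 3.5

    def test_seed_reproducible(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        a = bootstrap_ci(lambda idx: float(x[idx].mean()), 60, n_boot=200, seed=5)
        b = bootstrap_ci(lambda idx: float(x[idx].mean()), 60, n_boot=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_for_mean(self):
        rng = np.random.default_rng(11)
        cover = 0
        reps = 200
        for r in range(reps):
            x = rng.normal(0.0, 1.0, 50)
            res = bootstrap_ci(lambda idx: float(x[idx].mean()), 50, n_boot=300, seed=r)
            cover += res.ci_low <= 0.0 <= res.ci_high
        assert abs(cover / reps - 0.95) < 0.045

    def test_redraw_cap(self):
        def bad(idx):
            if len(np.unique(idx)) < len(idx):  # any resample with duplicates
                raise ValueError("degenerate resample")
            return 1.0

        with pytest.raises(ValueError, match="cap"):
            bootstrap_ci(bad, 10, n_boot=5, seed=0, max_redraws=3)


class TestStratify:
    def test_balanced_split_sizes(self):
        rng = np.random.default_rng(2)
        val = rng.uniform(0, 1, 300)
        test = rng.uniform(0, 1, 200)
        times = rng.exponential(30, 200)
        events = (rng.random(200) < 0.5).astype(int)
        res = stratify_median(val, test, times, events)
        n_high = int((res["group"] == "high").sum())
        assert abs(n_high - 100) <= 20

    def test_degenerate_single_group_warns(self):
        with pytest.warns(UserWarning, match="one side"):
            res = stratify_median([0.9, 0.95], [0.1, 0.2], [10.0, 20.0], [1, 0])
        assert np.isnan(res["p"])

    def test_designed_cohort_separates_groups(self, clinical_cohort):
        """True-risk median split: high-risk 3-year EFS below low-risk."""
        t = clinical_cohort
        risk = 1.0 / (1.0 + np.exp(-t["true_lp"].to_numpy()))
        res = stratify_median(risk[:300], risk[300:],
                              t["time_months"].to_numpy()[300:],
                              t["event"].to_numpy()[300:], horizon=36.0)
        assert res["efs_at_horizon"]["high"] < res["efs_at_horizon"]["low"]
        assert res["p"] < 0.05
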