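"""Discrete-time logistic-hazard model: grid, loss, networks, prediction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kendalltau

from gliorisk.survival import (
    ClinicalNormalizer,
    DiscreteTarget,
    SurvivalCurve,
    SurvTrainConfig,
    TimeGrid,
    build_survival_net,
    discretize,
    hazard_loss_grad,
    logistic_hazard_loss,
    make_time_grid,
    predict_survival_matrix,
    risk_score,
    select_covariates,
    survival_at,
    train_survival,
)


class TestTimeGrid:
    def test_equidistant_edges(self):
        grid = make_time_grid([10, 50, 100], 4, "equidistant")
        assert np.allclose(grid.edges, [0, 25, 50, 75, 100])

    def test_single_bin(self):
        grid = make_time_grid([3, 8], 1)
        assert grid.n_bins == 1 and grid.edges[-1] == 8

    def test_quantile_bins_balance_event_counts(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(20, 200) ** 1.3 + 0.1
        events = np.ones(200, dtype=int)
        grid = make_time_grid(times, 5, "quantile", events=events)
        counts = np.histogram(times, bins=grid.edges)[0]
        assert counts.max() - counts.min() <= 1

    def test_quantile_too_many_bins(self):
        with pytest.raises(ValueError):
            make_time_grid([5.0, 5.0, 7.0], 5, "quantile", events=[1, 1, 1])


class TestDiscretize:
    def test_interior_edge_goes_to_earlier_bin(self):
        grid = TimeGrid(np.array([0.0, 25.0, 50.0, 75.0, 100.0]))
        assert discretize(25.0, 1, grid).bin_index == 0
        assert discretize(50.0, 0, grid).bin_index == 1

    def test_early_event(self):
        grid = make_time_grid([100], 10)
        t = discretize(0.1, 1, grid)
        assert t.bin_index == 0 and t.event == 1

    def test_nonpositive_time_raises(self):
        grid = make_time_grid([10], 2)
        with pytest.raises(ValueError):
            discretize(0.0, 1, grid)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.concatenate([[0.0], np.sort(rng.uniform(1, 100, 6))])
        grid = TimeGrid(edges)
        t = float(rng.uniform(0.01, 120))
        # brute-force scan over half-open intervals (edge_j, edge_{j+1}]
        expect = grid.n_bins - 1
        for j in range(grid.n_bins):
            if edges[j] < t <= edges[j + 1]:
                expect = j
                break
        assert discretize(t, 1, grid).bin_index == expect


class TestLoss:
    def test_event_bin0_closed_form(self):
        assert np.isclose(
            logistic_hazard_loss(np.array([[0.5, 0.3]]), [DiscreteTarget(0, 1)]),
            -np.log(0.5),
        )

    def test_censored_bin1_closed_form(self):
        loss = logistic_hazard_loss(np.array([[0.2, 0.3]]), [DiscreteTarget(1, 0)])
        assert np.isclose(loss, -(np.log(0.8) + np.log(0.7)))

    def test_degenerate_hazard_raises(self):
        with pytest.raises(ValueError):
            logistic_hazard_loss(np.array([[0.0, 0.5]]), [DiscreteTarget(0, 1)])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            z = rng.normal(0, 2, size=(4, 6))
            ks = rng.integers(0, 6, size=4)
            ds = rng.integers(0, 2, size=4)
            _, grad = hazard_loss_grad(z, ks, ds)
            eps = 1e-6
            for i, j in [(0, 0), (1, 3), (3, 5), (2, 2)]:
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (hazard_loss_grad(zp, ks, ds)[0] - hazard_loss_grad(zm, ks, ds)[0]) / (2 * eps)
                assert abs(num - grad[i, j]) < 1e-4


class TestNetwork:
    def test_clinical_dims(self):
        net = build_survival_net("clinical", {"clinical": 4}, n_bins=12, seed=0)
        out = net.forward(None, np.zeros((3, 4)))
        assert out.shape == (3, 12)

    def test_multimodal_final_layer_dim(self):
        net = build_survival_net("multimodal", {"image": 64, "clinical": 4},
                                 n_bins=8, seed=0, hidden=32)
        assert net.fc3.W.shape == (8, 32 + 4)

    def test_seed_reproducible_init(self):
        a = build_survival_net("image", {"image": 16}, 5, seed=7)
        b = build_survival_net("image", {"image": 16}, 5, seed=7)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_multimodal_missing_input_raises(self):
        net = build_survival_net("multimodal", {"image": 8, "clinical": 4}, 5, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 8)), None)


class TestTraining:
    def test_zero_lr_flat_loss(self):
        rng = np.random.default_rng(0)
        net = build_survival_net("clinical", {"clinical": 4}, 5, seed=0, dropout=0.0)
        X = rng.normal(size=(30, 4))
        targets = [DiscreteTarget(int(k), int(d))
                   for k, d in zip(rng.integers(0, 5, 30), rng.integers(0, 2, 30))]
        before = [p.copy() for p, _ in net.parameters()]
        _, log = train_survival(net, None, X, targets, SurvTrainConfig(epochs=5, lr=0.0, seed=0))
        assert np.allclose(log, log[0])
        for (p, _), b in zip(net.parameters(), before):
            assert np.array_equal(p, b)

    def test_no_events_warns(self):
        net = build_survival_net("clinical", {"clinical": 4}, 5, seed=0)
        X = np.zeros((12, 4))
        targets = [DiscreteTarget(4, 0)] * 12
        with pytest.warns(UserWarning, match="no events"):
            train_survival(net, None, X, targets, SurvTrainConfig(epochs=2, seed=0))

    def test_recovers_clinical_risk_ranking(self, clinical_cohort):
        """On a correctly specified cohort the learned risk rank-correlates
        with the true linear predictor (Kendall tau > 0.5)."""
        table = clinical_cohort.iloc[:400]
        test = clinical_cohort.iloc[400:]
        norm = ClinicalNormalizer.fit(table)
        Xtr, kept = norm.transform(table)
        grid = make_time_grid(table["time_months"].to_numpy(), 20)
        tbl = table.loc[kept]
        targets = [discretize(t, e, grid) for t, e in zip(tbl["time_months"], tbl["event"])]
        net = build_survival_net("clinical", {"clinical": 4}, grid.n_bins, seed=0,
                                 hidden=32, dropout=0.1)
        train_survival(net, None, Xtr, targets, SurvTrainConfig(seed=0))
        Xte, kept_te = norm.transform(test)
        S = predict_survival_matrix(net, None, Xte, grid)
        risk = 1.0 - S[:, -1]
        tau = kendalltau(risk, test.loc[kept_te, "true_lp"]).statistic
        assert tau > 0.5


class TestPrediction:
    def test_large_negative_logits_survive(self):
        net = build_survival_net("clinical", {"clinical": 2}, 4, seed=0)
        net.fc3.W[...] = 0.0
        net.fc3.b[...] = -30.0  # clamped to -15 -> hazards ~ 3e-7
        grid = TimeGrid(np.linspace(0, 40, 5))
        S = predict_survival_matrix(net, None, np.zeros((3, 2)), grid)
        assert np.all(S > 0.999)

    def test_constant_half_hazard(self):
        S = np.concatenate([[1.0], np.cumprod([0.5, 0.5])])
        curve = SurvivalCurve(edges=np.array([0.0, 10.0, 20.0]), S=S)
        assert np.allclose(curve.S, [1, 0.5, 0.25])

    def test_monotone_for_random_logits(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            z = rng.normal(0, 3, size=8)
            h = 1 / (1 + np.exp(-np.clip(z, -15, 15)))
            S = np.concatenate([[1.0], np.cumprod(1 - h)])
            assert np.all(np.diff(S) <= 1e-15) and S[0] == 1.0 and S[-1] >= 0.0


class TestRiskScore:
    def test_value(self):
        curve = SurvivalCurve(edges=np.array([0.0, 36.0, 72.0]), S=np.array([1.0, 0.9, 0.5]))
        assert np.isclose(risk_score(curve, 36.0).value, 0.1)

    def test_all_survive(self):
        curve = SurvivalCurve(edges=np.array([0.0, 40.0]), S=np.array([1.0, 1.0]))
        assert risk_score(curve, 36.0).value == 0.0

    def test_horizon_beyond_grid_raises(self):
        curve = SurvivalCurve(edges=np.array([0.0, 24.0]), S=np.array([1.0, 0.8]))
        with pytest.raises(ValueError):
            risk_score(curve, 36.0)

    def test_step_interpolation_matches_bin_lookup(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            edges = np.concatenate([[0.0], np.sort(rng.uniform(1, 100, 6))])
            S = np.concatenate([[1.0], np.cumprod(rng.uniform(0.7, 1.0, 6))])
            t = float(rng.uniform(0, edges[-1]))
            j = max(np.searchsorted(edges, t, side="right") - 1, 0)
            assert survival_at(edges, S, t) == S[j]


class TestSelectCovariates:
    def test_signal_covariates_retained(self, clinical_cohort):
        kept_count = {"age": 0, "gtr": 0, "sex": 0}
        for seed in range(5):
            t = clinical_cohort.sample(400, random_state=seed)
            cand = {
                "age": t["age_years"].to_numpy(),
                "gtr": (t["resection"] == "GTR").to_numpy().astype(float),
                "sex": (t["sex"] == "M").to_numpy().astype(float),
            }
            kept, _ = select_covariates(cand, t["time_months"].to_numpy(), t["event"].to_numpy())
            for k in kept:
                kept_count[k] += 1
        assert kept_count["age"] >= 4
        assert kept_count["gtr"] >= 4
        assert kept_count["sex"] <= 1

    def test_null_retention_rate_matches_threshold(self):
        rng = np.random.default_rng(0)
        retained = 0
        n_reps = 200
        for _ in range(n_reps):
            n = 150
            x = rng.normal(size=n)
            t = rng.exponential(20, n)
            e = (rng.random(n) < 0.7).astype(int)
            cand = {"x": x, "y": rng.normal(size=n)}
            kept, _ = select_covariates(cand, t, e)
            retained += len(kept)
        rate = retained / (2 * n_reps)
        assert abs(rate - 0.15) < 0.06

    def test_strong_covariate_tiny_p(self, clinical_cohort):
        t = clinical_cohort.iloc[:400]
        cand = {"lp": t["true_lp"].to_numpy(), "noise": np.random.default_rng(1).normal(size=400)}
        kept, fits = select_covariates(cand, t["time_months"].to_numpy(), t["event"].to_numpy())
        assert "lp" in kept and fits["lp"].p_wald < 1e-3

    def test_constant_covariate_warns_and_excluded(self):
        rng = np.random.default_rng(2)
        cand = {"c": np.ones(50), "x": rng.normal(size=50)}
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = select_covariates(cand, rng.exponential(10, 50), np.ones(50, dtype=int))
        assert "c" not in kept
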