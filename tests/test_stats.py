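"""Cognition composites, collinearity, stepwise regression, LOOCV."""

import numpy as np
import pandas as pd
import pytest

from brainmux.stats import (
    collinearity,
    composite_score,
    cv_r2_score,
    fit_ols,
    hierarchical_quadratic,
    loocv_r2,
    stepwise_blockwise,
)


@pytest.fixture
def design(rng):
    n = 40
    X = pd.DataFrame({
        "x1": rng.standard_normal(n),
        "x2": rng.standard_normal(n),
        "x3": rng.standard_normal(n),
    })
    return X


class TestComposite:
    def test_zero_components_give_zero(self):
        t = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [0.0]})
        assert composite_score(t, ["a", "b", "c"], "EF").iloc[0] == 0.0

    def test_three_component_mean(self):
        t = pd.DataFrame({"a": [1.2], "b": [-0.6], "c": [0.0]})
        assert composite_score(t, ["a", "b", "c"], "EF").iloc[0] == pytest.approx(0.2)

    def test_component_order_irrelevant(self, rng):
        t = pd.DataFrame(rng.standard_normal((5, 3)), columns=["a", "b", "c"])
        x = composite_score(t, ["a", "b", "c"], "EF")
        y = composite_score(t, ["c", "a", "b"], "EF")
        assert np.allclose(x, y)

    def test_missing_component_yields_missing_composite_with_warning(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, np.nan]})
        with pytest.warns(UserWarning, match="missing"):
            out = composite_score(t, ["a", "b"], "EF")
        assert np.isnan(out.iloc[1]) and out.iloc[0] == 0.5


class TestCollinearity:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        diag = collinearity(pd.DataFrame({"x1": x1, "x2": x2}))
        assert diag.loc["x1", "vif"] == pytest.approx(1.0)
        assert diag.loc["x2", "tolerance"] == pytest.approx(1.0)
        assert not diag["flagged"].any()

    def test_duplicated_predictor_flagged_singular(self, rng):
        x = rng.standard_normal(20)
        diag = collinearity(pd.DataFrame({"x1": x, "x2": x}))
        assert diag["singular"].all()
        assert (diag["tolerance"] == 0.0).all()
        assert diag["flagged"].all()

    def test_flag_threshold_is_point_two(self, rng):
        # construct a predictor with R^2 just above/below 0.8 on the others
        z = rng.standard_normal(500)
        e = rng.standard_normal(500)
        for rho, expect_flag in [(0.93, True), (0.7, False)]:
            x2 = rho * z + np.sqrt(1 - rho**2) * e
            diag = collinearity(pd.DataFrame({"z": z, "x2": x2}))
            assert bool(diag.loc["x2", "tolerance"] < 0.2) == expect_flag
            assert bool(diag.loc["x2", "flagged"]) == expect_flag


class TestStepwise:
    def test_backward_removes_noise_keeps_exact_predictor(self, rng):
        n = 30
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = x1.copy()  # y exactly linear in x1
        X = pd.DataFrame({"x1": x1, "x2": x2})
        steps = stepwise_blockwise(y, X, ["x1", "x2"], direction="backward")
        final = steps[-1].model
        assert final.predictors == ("x1",)
        assert final.r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_predictor_matches_closed_form(self, rng):
        n = 25
        x = rng.standard_normal(n)
        y = 1.5 * x + rng.standard_normal(n)
        res = fit_ols(y, pd.DataFrame({"x": x}))
        slope = np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.coefficients["x"] == pytest.approx(slope, abs=1e-10)
        r = np.corrcoef(y, x)[0, 1]
        assert res.std_betas["x"] == pytest.approx(r, abs=1e-10)
        assert res.r2 == pytest.approx(r**2, abs=1e-10)

    def test_df_bookkeeping_one_predictor_n33(self, rng):
        x = rng.standard_normal(33)
        y = 0.4 * x + rng.standard_normal(33)
        res = fit_ols(y, pd.DataFrame({"x": x}))
        assert res.df == (1, 31)

    def test_forced_block_survives_backward_elimination(self, rng):
        n = 40
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=["a", "b", "c", "forced"])
        y = rng.standard_normal(n)  # pure noise: block 1 should empty out
        steps = stepwise_blockwise(y, X, ["a", "b", "c"], ["forced"],
                                   direction="backward")
        assert "forced" in steps[-1].model.predictors
        counts = [len(s.model.predictors) for s in steps]
        assert all(c1 > c2 for c1, c2 in zip(counts, counts[1:]))

    def test_forward_and_backward_agree_with_best_subset(self, rng):
        # one dominant predictor plus noise columns orthogonalized against
        # the response, 10 seeded cases
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 50
            raw = g.standard_normal((n, 4))
            y = 2.0 * raw[:, 0] + 0.3 * g.standard_normal(n)
            basis = np.column_stack([np.ones(n), y, raw[:, 0]])
            proj = basis @ np.linalg.lstsq(basis, raw[:, 1:], rcond=None)[0]
            raw[:, 1:] -= proj  # noise carries no in-sample signal
            X = pd.DataFrame(raw, columns=["x1", "x2", "x3", "x4"])
            back = stepwise_blockwise(y, X, list(X.columns), direction="backward")
            fwd = stepwise_blockwise(y, X, list(X.columns), direction="forward")
            # exhaustive best subset by adjusted R^2
            import itertools
            best, best_adj = None, -np.inf
            for k in range(1, 5):
                for cols in itertools.combinations(X.columns, k):
                    adj = fit_ols(y, X[list(cols)]).adj_r2
                    if adj > best_adj:
                        best, best_adj = set(cols), adj
            assert set(back[-1].model.predictors) == best
            assert set(fwd[-1].model.predictors) == best

    def test_r2_identity_and_adjusted_formula(self, rng, design):
        y = design["x1"] + 0.5 * rng.standard_normal(40)
        res = fit_ols(y, design)
        sse = np.sum((np.asarray(y) - res.fitted) ** 2)
        sst = np.sum((np.asarray(y) - np.mean(y)) ** 2)
        assert res.r2 == pytest.approx(1 - sse / sst, abs=1e-10)
        n, k = 40, 3
        assert res.adj_r2 == pytest.approx(
            1 - (1 - res.r2) * (n - 1) / (n - k - 1), abs=1e-10)

    def test_empty_blocks_rejected(self, rng, design):
        with pytest.raises(ValueError, match="empty"):
            stepwise_blockwise(rng.standard_normal(40), design, [], [])

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(20)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            fit_ols(rng.standard_normal(20), X)


class TestHierarchicalQuadratic:
    def test_pure_quadratic_recovered_exactly(self):
        age = np.linspace(20, 70, 30)
        y = (age - 45.0) ** 2
        steps = hierarchical_quadratic(age, y)
        assert steps[-1].model.r2 == pytest.approx(1.0, abs=1e-10)
        assert steps[-1].p_change < 1e-10

    def test_df_bookkeeping_two_predictors_n33(self, rng):
        age = rng.uniform(20, 70, 33)
        y = rng.standard_normal(33)
        steps = hierarchical_quadratic(age, y)
        assert steps[-1].model.df == (2, 30)

    def test_type_one_error_rate_near_alpha(self):
        # y independent of age: the quadratic F-change should fire ~5%
        hits = 0
        reps = 1000
        for s in range(reps):
            g = np.random.default_rng(s)
            age = g.uniform(20, 70, 30)
            y = g.standard_normal(30)
            steps = hierarchical_quadratic(age, y)
            hits += steps[-1].p_change < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hierarchical_quadratic(np.full(10, 50.0), np.arange(10.0))


class TestLoocv:
    def test_perfect_prediction_scores_100(self, rng):
        y = rng.standard_normal(10)
        assert cv_r2_score(y, y) == pytest.approx(100.0)

    def test_zero_prediction_scores_0(self, rng):
        y = rng.standard_normal(10)
        assert cv_r2_score(y, np.zeros(10)) == pytest.approx(0.0)

    def test_matches_hand_rolled_fold_loop(self, rng):
        n = 12
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = 0.8 * X["x"].to_numpy() + 0.3 * rng.standard_normal(n)
        got = loocv_r2(X, y)
        preds = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            xs, ys = X["x"].to_numpy()[keep], y[keep]
            b = np.cov(ys, xs, ddof=1)[0, 1] / np.var(xs, ddof=1)
            a = ys.mean() - b * xs.mean()
            preds[i] = a + b * X["x"].to_numpy()[i]
        expected = 100.0 * (1 - np.sum((y - preds) ** 2) / np.sum(y**2))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_singular_fold_reported_with_index(self):
        x = np.zeros(8)
        x[0] = 1.0  # dropping row 0 makes the column constant (rank deficient)
        X = pd.DataFrame({"x": x})
        with pytest.raises(ValueError, match="fold 0"):
            loocv_r2(X, np.arange(8.0))
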