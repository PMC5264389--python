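import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odorhab.pls import (
    KernelPLS,
    explained_variance,
    fit_pls,
    interpret,
    loo_rmsep,
    select_components,
)


def autoscaled(rng, n, p):
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestFit:
    def test_first_component_weight_proportional_to_xty(self):
        rng = np.random.default_rng(0)
        X = autoscaled(rng, 15, 6)
        y = rng.normal(size=15)
        fit = fit_pls(X, y - y.mean(), 1)
        w = fit.x_weights_[:, 0]
        ref = X.T @ (y - y.mean())
        cosine = abs(w @ ref) / np.linalg.norm(ref)
        assert cosine == pytest.approx(1.0, abs=1e-12)

    def test_saturated_model_reproduces_y(self):
        rng = np.random.default_rng(1)
        n = 8
        X = autoscaled(rng, n, n - 1)  # full column rank
        Y = rng.normal(size=(n, 3))
        Yc = Y - Y.mean(0)
        fit = fit_pls(X, Yc, n - 1)
        assert np.allclose(fit.predict(X), Yc, atol=1e-8)

    def test_matches_reference_implementation_up_to_signs(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        for _ in range(5):
            X = autoscaled(rng, 20, 8)
            Y = autoscaled(rng, 20, 3)
            mine = fit_pls(X, Y, 5)
            ref = PLSRegression(5, scale=False, tol=1e-28, max_iter=20000).fit(X, Y)
            for attr in ("x_weights_", "x_loadings_", "x_scores_", "y_loadings_"):
                M, R = getattr(mine, attr), getattr(ref, attr)
                sign = np.sign((M * R).sum(axis=0))
                assert np.allclose(M, R * sign, atol=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self):
        rng = np.random.default_rng(3)
        fit = fit_pls(autoscaled(rng, 20, 7), autoscaled(rng, 20, 3), 5)
        T = fit.x_scores_
        off = T.T @ T - np.diag((T**2).sum(0))
        assert np.abs(off).max() < 1e-8
        assert np.allclose(np.linalg.norm(fit.x_weights_, axis=0), 1.0)

    def test_coefficients_reproduce_score_space_fit(self):
        rng = np.random.default_rng(4)
        X = autoscaled(rng, 18, 6)
        Y = autoscaled(rng, 18, 3)
        fit = fit_pls(X, Y, 4)
        assert np.allclose(X @ fit.coef_, fit.x_scores_ @ fit.y_loadings_.T, atol=1e-10)

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.zeros((10, 4)), np.random.default_rng(0).normal(size=(10, 2)), 2)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_pls(autoscaled(rng, 5, 8), rng.normal(size=(5, 2)), 5)


class TestLooRmsep:
    def test_matches_naive_refit_oracle(self):
        rng = np.random.default_rng(6)
        n, p, m, A = 5, 4, 2, 2
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, m))
        got = loo_rmsep(X, Y, A).to_numpy()
        err = np.zeros((A, m))
        for i in range(n):
            keep = np.arange(n) != i
            model = KernelPLS(n_components=A, scale=True).fit(X[keep], Y[keep])
            for a in range(1, A + 1):
                pred = model.predict(X[i][None, :], n_components=a)[0]
                err[a - 1] += (Y[i] - pred) ** 2
        assert np.allclose(got, np.sqrt(err / n), atol=1e-12)

    def test_noiseless_linear_map_predicted_exactly(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 3))
        B = rng.normal(size=(3, 2))
        Y = X @ B
        r = loo_rmsep(X, Y, 3)
        assert (r.iloc[-1] < 1e-8).all()

    def test_pure_noise_overfits_at_high_components(self):
        """On unrelated X and Y, RMSEP beyond the first component trends up."""
        rng = np.random.default_rng(8)
        worse = 0
        trials = 15
        for _ in range(trials):
            X = rng.normal(size=(14, 8))
            Y = rng.normal(size=(14, 2))
            r = loo_rmsep(X, Y, 6).to_numpy().mean(axis=1)
            worse += r[5] >= r[0]
        assert worse >= trials * 0.6


class TestSelectComponents:
    def test_argmin_per_response(self):
        r = pd.DataFrame({"y": [3.0, 2.0, 2.5]}, index=pd.RangeIndex(1, 4))
        per, global_a = select_components(r)
        assert per == {"y": 2} and global_a == 2

    def test_study_pattern_picks_four(self):
        r = pd.DataFrame(
            {"lowhab": [4, 3, 2.5, 2.0, 2.2],
             "midhab": [4, 3, 2.0, 2.1, 2.2],
             "highhab": [4, 3, 2.0, 2.1, 2.2]},
            index=pd.RangeIndex(1, 6),
        )
        per, global_a = select_components(r)
        assert per == {"lowhab": 4, "midhab": 3, "highhab": 3}
        assert global_a == 4

    def test_tie_takes_fewest_components(self):
        r = pd.DataFrame({"y": [2.0, 2.0, 3.0]}, index=pd.RangeIndex(1, 4))
        per, _ = select_components(r)
        assert per == {"y": 1}


class TestExplainedVariance:
    def test_saturated_cumulative_y_is_100(self):
        rng = np.random.default_rng(9)
        n = 8
        X = autoscaled(rng, n, n - 1)
        Y = autoscaled(rng, n, 2)
        fit = fit_pls(X, Y, n - 1)
        table = explained_variance(fit)
        assert np.allclose(table[["y0", "y1"]].sum(), 100.0, atol=1e-6)

    def test_dominant_direction_captured_first(self):
        rng = np.random.default_rng(10)
        t = rng.normal(size=(30, 1))
        X = np.hstack([10 * t, rng.normal(scale=0.1, size=(30, 5))])
        X = X - X.mean(0)
        Y = t - t.mean()
        fit = fit_pls(X, Y, 3)
        assert fit.explained_x_variance_[0] > 95.0

    def test_cumulative_totals_stable_under_reporting_order(self):
        rng = np.random.default_rng(11)
        fit = fit_pls(autoscaled(rng, 16, 6), autoscaled(rng, 16, 3), 4)
        ev = fit.explained_y_variance_
        assert np.isclose(ev.sum(), ev[::-1].sum())
        assert (fit.explained_x_variance_ >= -1e-10).all()
        assert fit.explained_x_variance_.sum() <= 100 + 1e-8


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        # X columns identical up to tiny noise: single component, equal weights
        rng = np.random.default_rng(12)
        base = rng.normal(size=(20, 1))
        X = np.tile(base, (1, 4)) + rng.normal(scale=1e-9, size=(20, 4))
        X = X - X.mean(0)
        y = base - base.mean()
        fit = fit_pls(X, y, 1)
        assert np.allclose(fit.vip_, 1.0, atol=1e-4)

    def test_sum_of_squares_equals_p(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            fit = fit_pls(autoscaled(rng, 20, 8), autoscaled(rng, 20, 3), 4)
            assert np.isclose((fit.vip_**2).sum(), 8.0, atol=1e-10)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(14)
        fit = fit_pls(autoscaled(rng, 20, 8), autoscaled(rng, 20, 3), 4)
        W, T, Q = fit.x_weights_, fit.x_scores_, fit.y_loadings_
        ss = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(4)])
        p = W.shape[0]
        oracle = np.sqrt(p * ((W**2) @ ss) / ss.sum())
        assert np.allclose(fit.vip_, oracle, atol=1e-10)


class TestInterpret:
    def test_empty_report_below_thresholds(self):
        rng = np.random.default_rng(15)
        fit = fit_pls(autoscaled(rng, 20, 8), autoscaled(rng, 20, 3), 2)
        rep = interpret(fit, [f"x{j}" for j in range(8)],
                        lw_threshold=1.1, loading_threshold=1e6, vip_threshold=1e6)
        assert rep.summary.empty
        assert all(not v["predictors"] and not v["responses"]
                   for v in rep.components.values())

    def test_directional_statements_invariant_to_sign_flips(self):
        rng = np.random.default_rng(16)
        X = autoscaled(rng, 20, 6)
        Y = autoscaled(rng, 20, 3)
        fit = fit_pls(X, Y, 3)
        rep = interpret(fit, [f"x{j}" for j in range(6)])
        flipped = fit_pls(X, Y, 3)
        flip = np.array([-1.0, 1.0, -1.0])
        flipped.x_weights_ = flipped.x_weights_ * flip
        flipped.x_scores_ = flipped.x_scores_ * flip
        flipped.x_loadings_ = flipped.x_loadings_ * flip
        flipped.y_loadings_ = flipped.y_loadings_ * flip
        rep2 = interpret(flipped, [f"x{j}" for j in range(6)])
        pd.testing.assert_frame_equal(rep.summary, rep2.summary)

    def test_driver_direction_recovered_from_synthetic_truth(self):
        """A descriptor that raises the decay rate moves odorants away from
        the low-habituation profile: its effect on the lowhab distance is
        positive, reported as less habituation when it decreases."""
        rng = np.random.default_rng(17)
        n = 32
        driver = rng.normal(size=n)
        nuisance = rng.normal(size=(n, 7))
        lam = 0.02 * np.exp(0.8 * driver)
        d_low = 50 * (lam - lam.min()) / np.ptp(lam) + rng.normal(scale=0.5, size=n)
        X = np.column_stack([driver, nuisance])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = np.column_stack([d_low, -d_low + rng.normal(scale=0.5, size=n),
                             rng.normal(size=n)])
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        fit = fit_pls(X, Y, 2)
        assert fit.coef_[0, 0] > 0  # driver raises the lowhab distance
        rep = interpret(fit, ["driver"] + [f"n{j}" for j in range(7)])
        row = rep.summary[rep.summary["variable"] == "driver"]
        assert not row.empty
        assert row["less_habituation_when"].iloc[0] == "decreases"


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_vip_identity_and_score_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        p = int(rng.integers(2, 10))
        m = int(rng.integers(1, 4))
        A = int(rng.integers(1, min(n - 1, p) + 1))
        X = rng.normal(size=(n, p))
        X = X - X.mean(0)
        Y = rng.normal(size=(n, m))
        fit = fit_pls(X, Y - Y.mean(0), A)
        assert np.isclose((fit.vip_**2).sum(), p, atol=1e-8)
        T = fit.x_scores_
        off = T.T @ T - np.diag((T**2).sum(0))
        assert np.abs(off).max() < 1e-6 * max(1.0, (T**2).sum())
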