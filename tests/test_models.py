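"""Preference models: z-scoring, VIF, backward elimination, PLSR, permutation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from aesthstat import models


class TestZscore:
    def test_hand_values(self):
        z = models.zscore(pd.Series([1.0, 2.0, 3.0], name="x"))
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, gaussian_table):
        z1 = models.zscore(gaussian_table)
        z2 = models.zscore(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)
        assert abs(z1.mean()).max() < 1e-10
        assert abs(z1.std(ddof=1) - 1).max() < 1e-10

    def test_affine_invariance(self, gaussian_table):
        col = gaussian_table["f0"]
        z = models.zscore(col)
        np.testing.assert_allclose(models.zscore(3.5 * col + 2).to_numpy(), z.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(models.zscore(-2 * col).to_numpy(), -z.to_numpy(), atol=1e-12)

    def test_zero_variance_named_error(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            models.zscore(df)


class TestVif:
    def test_orthogonal_columns_unity(self):
        # 16x4 orthogonal design codes (Hadamard-style)
        h = np.array([[1.0]])
        for _ in range(4):
            h = np.block([[h, h], [h, -h]])
        tbl = pd.DataFrame(h[:, 1:5], columns=list("abcd"))
        v = models.vif(tbl)
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_ninety_percent_explained_gives_ten(self, rng):
        # construct w = a + b + orthogonal residual with R^2 exactly 0.9
        n = 32
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        resid = rng.normal(size=n)
        # orthogonalize and rescale so var(a+b) / var(w) = 0.9
        for u in (np.ones(n), a, b):
            resid -= resid @ u / (u @ u) * u
        signal = a + b
        resid *= np.sqrt((signal @ signal) / 9.0 / (resid @ resid))
        w = signal + resid
        tbl = pd.DataFrame({"a": a, "b": b, "w": w})
        assert models.vif(tbl)["w"] == pytest.approx(10.0, abs=1e-6)

    def test_duplicated_column_infinite(self, gaussian_table):
        tbl = gaussian_table[["f0", "f1"]].copy()
        tbl["dup"] = tbl["f0"]
        v = models.vif(tbl)
        assert np.isinf(v["f0"]) and np.isinf(v["dup"])

    def test_agrees_with_inverse_correlation_diagonal(self, gaussian_table):
        v = models.vif(gaussian_table).to_numpy()
        z = models.zscore(gaussian_table).to_numpy()
        corr = np.corrcoef(z, rowvar=False)
        np.testing.assert_allclose(v, np.diag(np.linalg.inv(corr)), atol=1e-8)


class TestScreening:
    def test_clean_table_untouched(self, rng):
        n = 40
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(2 * x["a"] + rng.normal(0, 0.5, n))
        kept, report = models.screen_variables(x, y)
        assert list(kept.columns) == ["a", "b"]
        assert report.empty

    def test_single_point_leverage_feature_flagged(self, rng):
        n = 40
        y = pd.Series(rng.normal(size=n))
        spike = np.zeros(n)
        spike[7] = 1.0
        y[7] += 8.0  # one extreme image drives the apparent relationship
        x = pd.DataFrame({"spike": spike, "ok": rng.normal(size=n)})
        kept, report = models.screen_variables(x, y)
        assert "spike" not in kept.columns
        assert report.iloc[0]["feature"] == "spike"
        assert report.iloc[0]["max_cooks_d"] > 0.1

    def test_report_lists_diagnostics(self, rng):
        n = 30
        y = pd.Series(rng.normal(size=n))
        spike = np.zeros(n)
        spike[3] = 1.0
        y[3] += 10.0
        x = pd.DataFrame({"s": spike})
        _, report = models.screen_variables(x, y)
        assert set(report.columns) >= {"feature", "max_cooks_d", "reason"}


class TestBackwardElimination:
    def test_exact_linear_relationship_retained(self, rng):
        n = 20
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = pd.Series(1.5 * x1 - 2.0 * x2)
        tbl = pd.DataFrame({"x1": x1, "x2": x2})
        res = models.backward_eliminate(tbl, y)
        assert set(res.retained) == {"x1", "x2"}
        assert res.rsquared == pytest.approx(1.0)

    def test_planted_support_recovered(self, rng):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(
                r.normal(size=(40, 6)), columns=[f"x{i}" for i in range(6)]
            )
            y = pd.Series(2.0 * X["x0"] + r.normal(0, 0.3, 40))
            res = models.backward_eliminate(X, y)
            if "x0" in res.retained:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_null_model_type_I_rate(self):
        # with pure-noise y, each predictor survives roughly at the p threshold
        retained = 0
        total = 0
        for seed in range(120):
            r = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(r.normal(size=(30, 4)), columns=list("abcd"))
            y = pd.Series(r.normal(size=30))
            res = models.backward_eliminate(X, y)
            retained += len(res.retained)
            total += 4
        rate = retained / total
        assert 0.02 < rate < 0.25  # near the 0.1 threshold, allowing selection noise

    def test_retained_ps_below_threshold_and_vifs_below_bound(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 8)), columns=[f"x{i}" for i in range(8)])
        X["x7"] = X["x0"] + 0.2 * rng.normal(size=40)  # collinear pair
        y = pd.Series(X["x0"] + 0.5 * X["x3"] + rng.normal(0, 0.5, 40))
        res = models.backward_eliminate(X, y)
        assert (res.pvalues <= 0.1 + 1e-12).all()
        assert (res.vifs < 1.25).all()

    def test_p_ge_n_prereduction(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 30)), columns=[f"x{i}" for i in range(30)])
        y = pd.Series(3 * X["x4"] + rng.normal(0, 0.3, 20))
        res = models.backward_eliminate(X, y)
        assert "x4" in res.retained
        assert any("pre-ranking" in t["reason"] for t in res.elimination_trace)

    def test_forced_entry_agrees_on_recovery_suite(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 5)), columns=[f"x{i}" for i in range(5)])
            y = pd.Series(1.5 * X["x1"] - X["x2"] + r.normal(0, 0.4, 40))
            back = models.backward_eliminate(X, y)
            forced = models.PreferenceRegression(
                X, y, screen=False, forced_entry=True
            ).fit()
            assert set(back.retained) == set(forced.retained)


class TestFitMlr:
    def test_exact_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = pd.Series(2 * X["a"] - X["b"])
        res = models.fit_mlr(X, y)
        assert res.rsquared == pytest.approx(1.0)

    def test_bivariate_closed_form(self):
        # 6-point dataset solved with the textbook least-squares formulas
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 2.5, 3.1, 4.2, 4.4, 5.6])
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        beta = (zx * zy).sum() / (zx * zx).sum()
        resid = zy - beta * zx
        s2 = (resid**2).sum() / 4
        se = np.sqrt(s2 / (zx * zx).sum())
        tbl = pd.DataFrame({"x": x})
        res = models.fit_mlr(tbl, pd.Series(y))
        assert res.params["x"] == pytest.approx(beta, rel=1e-12)
        assert res.tvalues["x"] == pytest.approx(beta / se, rel=1e-12)
        assert res.fvalue == pytest.approx((beta / se) ** 2, rel=1e-9)

    def test_adjusted_r2_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + rng.normal(0, 1, 25))
        res = models.fit_mlr(X, y)
        n, p = 25, 3
        expect = 1 - (1 - res.rsquared) * (n - 1) / (n - p - 1)
        assert res.rsquared_adj == pytest.approx(expect, rel=1e-12)


class TestPlsr:
    def test_single_predictor_full_recovery(self, rng):
        x = rng.normal(size=30)
        tbl = pd.DataFrame({"x": x})
        y = pd.Series(2.0 * x)
        res = models.plsr_fit(tbl, y, n_components=1)
        assert res.pct_variance_explained == pytest.approx(100.0, abs=1e-8)

    def test_full_rank_equals_ols(self, rng):
        n, p = 20, 5
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        y = pd.Series(X.to_numpy() @ rng.normal(size=p) + rng.normal(0, 0.5, n))
        res = models.plsr_fit(X, y, n_components=p)
        # OLS fitted values on the same z-scored data
        Xz = models.zscore(X).to_numpy()
        yz = models.zscore(y).to_numpy()
        beta = np.linalg.lstsq(Xz, yz, rcond=None)[0]
        r2_ols = 1 - ((yz - Xz @ beta) ** 2).sum() / (yz**2).sum()
        assert res.pct_variance_explained == pytest.approx(100 * r2_ols, abs=1e-8)
        np.testing.assert_allclose(res.coef.to_numpy(), beta, atol=1e-8)

    def test_matches_sklearn_plsregression(self, rng):
        n, p, k = 25, 6, 3
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        y = pd.Series(X["x0"] - X["x3"] + rng.normal(0, 0.4, n))
        res = models.plsr_fit(X, y, n_components=k)
        sk = PLSRegression(n_components=k, scale=False)
        Xz = models.zscore(X).to_numpy()
        yz = models.zscore(y).to_numpy()
        sk.fit(Xz, yz)
        np.testing.assert_allclose(
            res.coef.to_numpy(), sk.coef_.ravel(), atol=1e-8
        )

    def test_variance_explained_nondecreasing_in_components(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"x{i}" for i in range(6)])
        y = pd.Series(X["x1"] + rng.normal(0, 1, 20))
        pcts = [
            models.plsr_fit(X, y, n_components=k).pct_variance_explained
            for k in range(1, 6)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(pcts, pcts[1:]))

    def test_cv_selects_planted_two_factor_model(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n, p = 40, 20
            t1, t2 = r.normal(size=(2, n))
            load1, load2 = r.normal(size=(2, p))
            X = pd.DataFrame(
                np.outer(t1, load1) + np.outer(t2, load2) + 0.1 * r.normal(size=(n, p)),
                columns=[f"x{i}" for i in range(p)],
            )
            y = pd.Series(2 * t1 + 1.5 * t2 + 0.2 * r.normal(size=n))
            res = models.plsr_fit(X, y)
            if res.n_components == 2:
                hits += 1
        assert hits >= 0.8 * n_seeds


class TestVip:
    def test_mean_square_is_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 7)), columns=[f"x{i}" for i in range(7)])
        y = pd.Series(X["x2"] + 0.5 * X["x5"] + rng.normal(0, 0.5, 30))
        res = models.plsr_fit(X, y)
        assert (res.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_single_predictive_feature_has_max_vip(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"x{i}" for i in range(6)])
        y = pd.Series(3 * X["x4"] + rng.normal(0, 0.3, 40))
        res = models.plsr_fit(X, y)
        assert res.vip.idxmax() == "x4"
        assert res.signs["x4"] > 0

    def test_identical_copies_equal_vip(self, rng):
        x = rng.normal(size=25)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        y = pd.Series(2 * x + rng.normal(0, 0.2, 25))
        res = models.plsr_fit(X, y, n_components=1)
        np.testing.assert_allclose(res.vip.to_numpy(), 1.0, atol=1e-10)


class TestPermutation:
    def test_planted_signal_beats_null(self, rng):
        n, p = 40, 8
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        beta = np.zeros(p)
        beta[:3] = [1.0, 0.8, -0.6]
        signal = X.to_numpy() @ beta
        noise = rng.normal(size=n)
        y = pd.Series(signal + noise * np.std(signal) / np.std(noise) * 0.65)
        summ = models.permutation_null(X, y, n_perm=300, seed=9)
        assert summ.observed > np.percentile(summ.null, 99)
        assert summ.pvalue < 0.01

    def test_null_data_unremarkable_z(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 5)), columns=[f"x{i}" for i in range(5)])
        y = pd.Series(rng.normal(size=25))
        summ = models.permutation_null(X, y, n_perm=200, seed=3)
        assert abs(summ.zscore) < 3.5
        assert 0 < summ.pvalue <= 1

    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = pd.Series(X["a"] + rng.normal(0, 1, 20))
        s1 = models.permutation_null(X, y, n_perm=50, seed=11)
        s2 = models.permutation_null(X, y, n_perm=50, seed=11)
        np.testing.assert_array_equal(s1.null, s2.null)

    def test_shuffle_preserves_y_multiset(self, rng):
        # the null machinery must only permute, never resample
        yv = rng.normal(size=15)
        out = np.random.default_rng(0).permutation(yv)
        assert sorted(out) == sorted(yv)

    def test_summary_table_runs(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = pd.Series(X["a"] + rng.normal(0, 0.5, 20))
        res = models.plsr_fit(X, y)
        assert "components" in res.summary()
        mlr = models.backward_eliminate(X, y)
        assert "adj. R^2" in mlr.summary()
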