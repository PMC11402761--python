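"""Correlation, OLS, stepwise selection, VIF, split and validation.

Independent oracles: hand-computed correlations, a normal-equations
solver for OLS, exhaustive subset enumeration for stepwise stability,
and auxiliary regressions for VIF.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from sanibound.assoc_stats import (
    SplitSpec,
    correlation_matrix,
    ols_fit,
    split_train_validation,
    stepwise_select,
    validate_fit,
    vif,
)
from sanibound.well_data import SchemaError, WellDataError, WellTable


def table(**cols):
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"no": [str(i) for i in range(n)],
                       "lon": np.zeros(n), "lat": np.zeros(n), **cols})
    return WellTable(df)


class TestCorrelation:
    def test_hand_computed_example(self):
        t = table(x=[1.0, 2.0, 3.0], y=[6.0, 4.0, 5.0])
        c = correlation_matrix(t, ["x", "y"])
        assert c[("x", "y")] == pytest.approx(-0.5, abs=1e-12)

    def test_perfect_linear_relation(self):
        t = table(x=[1.0, 2.0, 3.0], y=[2.0, 4.0, 6.0])
        c = correlation_matrix(t, ["x", "y"])
        assert c[("x", "y")] == pytest.approx(1.0)
        assert c[("x", "x")] == 1.0

    def test_constant_variable_reported_undefined(self):
        t = table(x=[1.0, 2.0, 3.0], c=[5.0, 5.0, 5.0])
        m = correlation_matrix(t, ["x", "c"])
        assert np.isnan(m[("x", "c")])

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        base = correlation_matrix(table(x=x, y=y), ["x", "y"])[("x", "y")]
        up = correlation_matrix(table(x=3.0 * x + 7, y=y), ["x", "y"])
        dn = correlation_matrix(table(x=-2.0 * x, y=y), ["x", "y"])
        assert up[("x", "y")] == pytest.approx(base, abs=1e-12)
        assert dn[("x", "y")] == pytest.approx(-base, abs=1e-12)

    def test_p_value_from_t_transform(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        m = correlation_matrix(table(x=x, y=y), ["x", "y"])
        r = m[("x", "y")]
        tstat = r * np.sqrt(28 / (1 - r**2))
        assert m.p[0, 1] == pytest.approx(2 * stats.t.sf(abs(tstat), 28),
                                          rel=1e-9)


def normal_equations(y, X):
    """Independent least-squares oracle: beta = (X'X)^-1 X'y."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestOls:
    def test_noiseless_line(self):
        x = np.arange(10.0)
        f = ols_fit(table(x=x, y=2.0 * x), "y", ["x"])
        assert f.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert f.intercept == pytest.approx(0.0, abs=1e-10)
        assert f.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k", [(20, 2), (50, 5), (200, 10)])
    def test_matches_normal_equations_oracle(self, rng, n, k):
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        names = [f"x{i}" for i in range(k)]
        f = ols_fit(table(y=y, **dict(zip(names, X.T))), "y", names)
        beta = normal_equations(y, X)
        assert f.intercept == pytest.approx(beta[0], abs=1e-8)
        for i, nm in enumerate(names):
            assert f.coefficients[nm] == pytest.approx(beta[i + 1], abs=1e-8)

    def test_t_equals_coefficient_over_se(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=30)
        names = ["a", "b", "c"]
        f = ols_fit(table(y=y, **dict(zip(names, X.T))), "y", names)
        for nm in names:
            assert f.t[nm] == pytest.approx(f.coefficients[nm] / f.se[nm],
                                            rel=1e-10)

    def test_published_transmissivity_t_statistic(self, published_fit):
        c = published_fit.coefficients["transmissivity_m2day"]
        se = published_fit.se["transmissivity_m2day"]
        assert round(c / se, 3) == 1.985
        assert published_fit.t["transmissivity_m2day"] == 1.985

    def test_singular_design_names_collinear_columns(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(WellDataError, match="collinear"):
            ols_fit(table(y=rng.normal(size=20), a=x, b=2.0 * x), "y",
                    ["a", "b"])

    def test_too_few_rows(self, rng):
        t = table(y=[1.0, 2.0, 3.0], a=[1.0, 2.0, 2.5], b=[0.0, 1.0, 0.5])
        with pytest.raises(WellDataError, match="n > k"):
            ols_fit(t, "y", ["a", "b"])


def stable_subsets(t, response, candidates, p_enter, p_remove):
    """All stepwise-stable subsets by exhaustive enumeration.

    A subset is stable when no excluded candidate would enter
    (added p >= p_enter) and no included predictor would be removed
    (own p <= p_remove).
    """
    out = []
    for r in range(len(candidates) + 1):
        for sub in itertools.combinations(candidates, r):
            sub = list(sub)
            if sub:
                fit = ols_fit(t, response, sub)
                if any(fit.p[c] > p_remove for c in sub):
                    continue
            enters = False
            for c in candidates:
                if c in sub:
                    continue
                f2 = ols_fit(t, response, sub + [c])
                if f2.p[c] < p_enter:
                    enters = True
                    break
            if not enters:
                out.append(tuple(sorted(sub)))
    return out


class TestStepwise:
    def test_dominant_predictor_selected_alone(self, rng):
        n = 100
        x = rng.normal(size=n)
        noise = {f"n{i}": rng.normal(size=n) for i in range(3)}
        t = table(y=3.0 * x, x=x, **noise)
        f = stepwise_select(t, "y", ["n0", "x", "n1", "n2"])
        assert f.predictors == ("x",)
        assert f.trace[0][:2] == ("add", "x")

    def test_matches_exhaustive_stability_oracle(self, rng):
        n = 60
        X = rng.normal(size=(n, 5))
        y = 2.0 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(size=n)
        names = [f"x{i}" for i in range(5)]
        t = table(y=y, **dict(zip(names, X.T)))
        f = stepwise_select(t, "y", names)
        stable = stable_subsets(t, "y", names, 0.05, 0.10)
        assert tuple(sorted(f.predictors)) in stable
        # with this signal strength the true set is the unique stable one
        assert stable == [("x0", "x1")]

    def test_retained_predictors_respect_p_remove(self, rng):
        n = 80
        X = rng.normal(size=(n, 4))
        y = X[:, 0] + 0.3 * X[:, 1] + rng.normal(size=n)
        names = ["a", "b", "c", "d"]
        t = table(y=y, **dict(zip(names, X.T)))
        f = stepwise_select(t, "y", names)
        assert set(f.predictors) <= set(names)
        assert all(f.p[c] <= 0.10 for c in f.predictors)

    def test_pure_noise_returns_intercept_only(self, rng):
        t = table(y=rng.normal(size=50), a=rng.normal(size=50))
        f = stepwise_select(t, "y", ["a"], p_enter=1e-6, p_remove=1e-5)
        assert f.predictors == ()
        assert f.intercept == pytest.approx(float(t.frame["y"].mean()))

    def test_threshold_ordering_enforced(self, rng):
        t = table(y=rng.normal(size=20), a=rng.normal(size=20))
        with pytest.raises(WellDataError):
            stepwise_select(t, "y", ["a"], p_enter=0.2, p_remove=0.1)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        v = vif(table(a=a, b=b), ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=1e-12)
        assert v["b"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_collinearity_is_infinite(self, rng):
        x = rng.normal(size=25)
        v = vif(table(a=x, b=2.0 * x), ["a", "b"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_near_collinearity_matches_auxiliary_regression(self, rng):
        import statsmodels.api as sm

        x1 = rng.normal(size=400)
        x2 = x1 + rng.normal(scale=0.1, size=400)
        x3 = rng.normal(size=400)
        t = table(a=x1, b=x2, c=x3)
        v = vif(t, ["a", "b", "c"])
        # independent auxiliary-regression oracle
        X = sm.add_constant(np.column_stack([x2, x3]))
        r2 = sm.OLS(x1, X).fit().rsquared
        assert v["a"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)
        assert v["a"] > 20  # strongly inflated


class TestSplit:
    @pytest.mark.parametrize("n,frac,sizes", [(112, 0.8, (90, 22)),
                                              (10, 0.5, (5, 5)),
                                              (28, 0.8, (22, 6))])
    def test_partition_sizes(self, rng, n, frac, sizes):
        t = table(x=rng.normal(size=n))
        tr, va = split_train_validation(t, SplitSpec(frac, seed=0))
        assert (len(tr), len(va)) == sizes

    def test_same_seed_reproduces_partition(self, rng):
        t = table(x=rng.normal(size=30))
        s1, s2 = SplitSpec(0.8, seed=9), SplitSpec(0.8, seed=9)
        split_train_validation(t, s1)
        split_train_validation(t, s2)
        assert s1.train_indices == s2.train_indices

    def test_partition_is_disjoint_and_complete(self, rng):
        t = table(x=rng.normal(size=53))
        s = SplitSpec(0.7, seed=3)
        split_train_validation(t, s)
        tr, va = set(s.train_indices), set(s.validation_indices)
        assert tr.isdisjoint(va)
        assert tr | va == set(range(53))

    def test_fraction_domain(self):
        with pytest.raises(WellDataError):
            SplitSpec(1.0)


class TestValidate:
    def test_printed_columns_reproduce_published_r2(self, wells28):
        rep = validate_fit(None, wells28, use_stored_predictions=True)
        assert rep.n == 28
        assert rep.r_squared == pytest.approx(0.85, abs=0.005)

    def test_perfect_fit_scores_one(self, rng):
        x = rng.normal(size=20)
        t = table(gwqi_actual=2.0 * x + 1.0, x=x)
        f = ols_fit(t, "gwqi_actual", ["x"])
        assert validate_fit(f, t).r_squared == pytest.approx(1.0)

    def test_constant_predictions_undefined(self, wells28):
        t = wells28.copy()
        t.frame["gwqi_predicted"] = 5.0
        rep = validate_fit(None, t, use_stored_predictions=True)
        assert np.isnan(rep.r_squared)

    def test_missing_predictor_named(self, published_fit, rng):
        t = table(gwqi_actual=rng.normal(size=10))
        with pytest.raises(SchemaError, match="depth_m"):
            validate_fit(published_fit, t)

    def test_identity_variant_penalizes_offset(self, rng):
        x = rng.normal(size=50)
        t = table(gwqi_actual=x, x=x)
        f = ols_fit(t, "gwqi_actual", ["x"])
        t2 = t.copy()
        t2.frame["gwqi_predicted"] = x + 10.0  # shifted predictions
        corr = validate_fit(None, t2, use_stored_predictions=True)
        ident = validate_fit(None, t2, use_stored_predictions=True,
                             about_identity=True)
        assert corr.r_squared == pytest.approx(1.0)
        assert ident.r_squared < 0.0  # far off the y = x line


class TestUnbiasedness:
    def test_ols_recovers_generating_coefficients_on_average(self, rng):
        # small Monte-Carlo check of unbiasedness at modest n
        n, reps = 40, 300
        beta = np.array([1.0, -2.0, 0.5])
        est = np.empty((reps, 3))
        for i in range(reps):
            X = rng.normal(size=(n, 3))
            y = X @ beta + rng.normal(size=n)
            est[i] = normal_equations(y, X)[1:]
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0) - beta) < 3 * se)
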