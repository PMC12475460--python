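"""Scaled regressions, one-sided tails, Bonferroni, and JZS Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from offload.bayesfactor import (
    DEFAULT_PRIOR_SCALE,
    RegressionSpec,
    bonferroni,
    fit_model,
    jzs_bf_vs_null,
    jzs_inclusion_bf,
    one_sided_p_from_t,
    regression_table,
    scale_columns,
)
from offload.errors import NumericalError


def finegrid_log_bf(r2, n, p, r=DEFAULT_PRIOR_SCALE, n_points=1_000_001):
    """Independent oracle: trapezoid quadrature of the JZS marginal on a
    10^6-point grid over u = g/(1+g)."""
    u = np.linspace(1e-9, 1 - 1e-9, n_points)
    g = u / (1 - u)
    b = n * r * r / 2.0
    logf = (
        0.5 * (n - p - 1) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p(g * (1 - r2))
        + 0.5 * np.log(b)
        - gammaln(0.5)
        - 1.5 * np.log(g)
        - b / g
        - 2 * np.log1p(-u)
    )
    m = logf.max()
    return m + np.log(np.trapezoid(np.exp(logf - m), u))


def make_regression_data(n, slope, seed, n_pred=4):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_pred))
    y = slope * X[:, 0] + rng.normal(0, 0.5, n)
    return X, y


def _r2(X, y):
    d = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ coef
    return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)


class TestScaleColumns:
    def test_linear_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "g": [0, 1, 0]})
        out = scale_columns(df, ["a"])
        assert out["a"].tolist() == [-1.0, 0.0, 1.0]
        assert out["g"].tolist() == [0, 1, 0]  # untouched

    def test_idempotent(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 2, 50)})
        once = scale_columns(df, ["a"])
        twice = scale_columns(once, ["a"])
        assert np.allclose(once["a"], twice["a"], atol=1e-12)

    def test_postcondition_moments(self, rng):
        df = pd.DataFrame({"a": rng.normal(100, 17, 40)})
        out = scale_columns(df, ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_names_column(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(NumericalError, match="flat"):
            scale_columns(df, ["flat"])


class TestTails:
    @pytest.mark.parametrize(
        "t,df,direction,expected,tol",
        [(-2.753, 29, "-", 0.005, 0.0005), (-1.972, 29, "-", 0.029, 0.001),
         (0.0, 29, "-", 0.5, 1e-12), (0.0, 5, "+", 0.5, 1e-12)],
    )
    def test_examples(self, t, df, direction, expected, tol):
        assert one_sided_p_from_t(t, df, direction) == pytest.approx(
            expected, abs=tol
        )

    def test_directions_sum_to_one(self):
        p_minus = one_sided_p_from_t(-1.3, 20, "-")
        p_plus = one_sided_p_from_t(-1.3, 20, "+")
        assert p_minus + p_plus == pytest.approx(1.0, rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.005, 6, 0.030), (0.5, 6, 1.0), (0.012, 6, 0.072)]
    )
    def test_examples(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.2, 6)
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestFitModel:
    def _table(self, n, slope, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "abs_reminder_bias": rng.normal(1.0, 0.8, n),
                "age": rng.normal(30, 8, n),
                "gender": rng.integers(0, 2, n),
                "tiv": rng.normal(1400, 120, n),
            }
        )
        z = (df["abs_reminder_bias"] - df["abs_reminder_bias"].mean()) / df[
            "abs_reminder_bias"
        ].std(ddof=1)
        df["fa_slf_l"] = slope * z + rng.normal(0, 0.8, n)
        return df

    def test_perfect_fit_identity(self):
        rng = np.random.default_rng(0)
        df = self._table(34, 0.0, 1)
        z = (df["abs_reminder_bias"] - df["abs_reminder_bias"].mean()) / df[
            "abs_reminder_bias"
        ].std(ddof=1)
        df["fa_slf_l"] = z  # outcome exactly the scaled index
        res = fit_model(RegressionSpec("slf_l", "abs_reminder_bias", "+"), df)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.p_uncorrected == pytest.approx(0.0, abs=1e-12)
        assert res.bf10 == np.inf

    def test_matches_normal_equations_oracle(self):
        """beta must equal the closed-form normal-equations solution on
        the standardized design, to 1e-10."""
        df = self._table(34, 0.35, seed=8)
        res = fit_model(
            RegressionSpec("slf_l", "abs_reminder_bias", "+"), df
        )

        cont = ["fa_slf_l", "abs_reminder_bias", "age", "tiv"]
        z = df.copy()
        for c in cont:
            z[c] = (df[c] - df[c].mean()) / df[c].std(ddof=1)
        X = np.column_stack(
            [np.ones(len(z)), z["abs_reminder_bias"], z["age"], z["gender"],
             z["tiv"]]
        )
        beta_hand = np.linalg.solve(X.T @ X, X.T @ z["fa_slf_l"].to_numpy())
        assert res.beta == pytest.approx(beta_hand[1], abs=1e-10)

    def test_residual_df(self):
        res = fit_model(
            RegressionSpec("slf_l", "abs_reminder_bias", "-"),
            self._table(34, 0.2, 3),
        )
        assert res.df == 29
        assert res.p_fwe == pytest.approx(
            min(1.0, 6 * res.p_uncorrected), abs=1e-12
        )

    def test_collinear_design_rejected(self):
        df = self._table(34, 0.2, 3)
        df["tiv"] = df["age"] * 2.0  # exact collinearity
        with pytest.raises(NumericalError):
            fit_model(RegressionSpec("slf_l", "abs_reminder_bias", "-"), df)

    def test_outcome_scale_invariance(self):
        """Multiplying the raw outcome by a positive constant changes
        nothing after standardization."""
        df = self._table(34, 0.35, seed=8)
        base = fit_model(
            RegressionSpec("slf_l", "abs_reminder_bias", "-"), df
        )
        df2 = df.copy()
        df2["fa_slf_l"] = df2["fa_slf_l"] * 437.0
        scaled = fit_model(
            RegressionSpec("slf_l", "abs_reminder_bias", "-"), df2
        )
        assert scaled.beta == pytest.approx(base.beta, rel=1e-10)
        assert scaled.t == pytest.approx(base.t, rel=1e-10)
        assert scaled.p_uncorrected == pytest.approx(
            base.p_uncorrected, rel=1e-10
        )
        assert scaled.bf10 == pytest.approx(base.bf10, rel=1e-8)

    def test_regression_table_covers_grid(self):
        df = self._table(40, 0.3, 5)
        df["meta_bias"] = np.random.default_rng(2).normal(0, 5, 40)
        table = regression_table(
            df, tracts=["slf_l"], indices=["abs_reminder_bias", "meta_bias"]
        )
        assert len(table) == 2
        assert set(table["index"]) == {"abs_reminder_bias", "meta_bias"}


class TestJzs:
    def test_self_comparison_is_exactly_one(self):
        X, y = make_regression_data(30, 0.3, 1)
        assert jzs_inclusion_bf(X, X, y) == 1.0

    def test_matches_finegrid_oracle_to_four_significant_digits(self):
        """Adaptive quadrature against the 10^6-point trapezoid oracle on
        seeded n = 20 datasets."""
        for seed in (1, 2, 3):
            X, y = make_regression_data(20, 0.4, seed)
            bf = jzs_inclusion_bf(X, X[:, 1:], y)
            log_oracle = finegrid_log_bf(_r2(X, y), 20, 4) - finegrid_log_bf(
                _r2(X[:, 1:], y), 20, 3
            )
            assert bf == pytest.approx(np.exp(log_oracle), rel=5e-5)

    def test_transitivity_identity(self):
        """BF(full:reduced) * BF(reduced:null) = BF(full:null)."""
        X, y = make_regression_data(34, 0.35, 11)
        full_vs_red = jzs_inclusion_bf(X, X[:, 1:], y)
        red_vs_null = jzs_bf_vs_null(_r2(X[:, 1:], y), 34, 3)
        full_vs_null = jzs_bf_vs_null(_r2(X, y), 34, 4)
        assert full_vs_red * red_vs_null == pytest.approx(
            full_vs_null, rel=1e-6
        )

    def test_null_predictor_median_bf_below_one(self):
        """A pure-noise predictor (true slope 0, n = 34) is evidence for
        the reduced model in the median over 1000 seeds."""
        bfs = []
        rng = np.random.default_rng(555)
        for _ in range(1000):
            X = rng.standard_normal((34, 4))
            y = 0.2 * X[:, 1] + rng.normal(0, 0.5, 34)  # x0 is pure noise
            bfs.append(jzs_inclusion_bf(X, X[:, 1:], y))
        assert np.median(bfs) < 1.0

    def test_non_nested_designs_rejected(self):
        rng = np.random.default_rng(4)
        X_full = rng.standard_normal((30, 3))
        X_other = rng.standard_normal((30, 2))
        with pytest.raises(NumericalError, match="nested"):
            jzs_inclusion_bf(X_full, X_other, rng.standard_normal(30))

    def test_evidence_accumulates_with_n(self):
        """With a fixed true slope the BF grows with n; with slope 0 it
        shrinks (median over seeds, ladder n in {34, 100, 500})."""
        med = {}
        for slope in (0.35, 0.0):
            for n in (34, 100, 500):
                bfs = []
                for seed in range(30):
                    X, y = make_regression_data(n, slope, 7000 + seed)
                    bfs.append(jzs_inclusion_bf(X, X[:, 1:], y))
                med[(slope, n)] = np.median(bfs)
        assert med[(0.35, 34)] < med[(0.35, 100)] < med[(0.35, 500)]
        assert med[(0.0, 34)] > med[(0.0, 500)]
        assert med[(0.0, 500)] < 0.5


def test_parameter_recovery_over_replicates():
    """Across 1000 synthetic datasets (n = 34, true standardized slope
    0.35) the mean estimated slope is unbiased within 3 SEs."""
    betas = []
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = 34
        X = rng.standard_normal((n, 4))
        y = 0.35 * X[:, 0] + rng.normal(0, 0.5, n)
        d = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(d, y, rcond=None)
        betas.append(coef[1])
    betas = np.asarray(betas)
    se = betas.std(ddof=1) / np.sqrt(len(betas))
    assert abs(betas.mean() - 0.35) < 3 * se
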