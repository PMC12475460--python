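"""Covariate-controlled regressions with JZS inclusion Bayes factors.

Each white-matter tract's mean fractional anisotropy (FA) is regressed on
one behavioral index with age, gender and total intracranial volume (TIV)
as covariates:

    FA (scaled) ~ index (scaled) + age (scaled) + gender + TIV (scaled)

All continuous variables are standardized (mean 0, SD 1, n-1 denominator)
before fitting, so the index coefficient is a standardized slope. Each
tract x index cell reports the OLS beta, SE, t, residual df (n - 5), the
one-sided uncorrected p in the hypothesized direction, a Bonferroni
family-wise correction across the indices tested per tract, and a JZS
inclusion Bayes factor.

JZS Bayes factor
----------------
Under the Jeffreys-Zellner-Siow setup a linear model with p standardized
predictors and coefficient-of-determination R^2 has evidence against the
intercept-only null

    BF(M : null) = \\int_0^inf (1+g)^{(n-p-1)/2}
                   [1 + g(1-R^2)]^{-(n-1)/2} pi(g) dg,

where the mixing variable g carries an inverse-gamma(1/2, n r^2 / 2)
prior — equivalently an independent Cauchy(0, r) prior on each
standardized slope. The default scale r = sqrt(2)/4 is the conventional
"medium" prior for regression slopes. The inclusion Bayes factor for a
predictor is the ratio of two such null-based factors:

    BF10 = BF(full : null) / BF(reduced : null),

with the reduced model containing only the covariates. The integral is
evaluated by adaptive quadrature in log space after the substitution
u = g / (1 + g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import gammaln

from .errors import NumericalError

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "RegressionSpec",
    "RegressionResult",
    "scale_columns",
    "one_sided_p_from_t",
    "bonferroni",
    "jzs_bf_vs_null",
    "jzs_inclusion_bf",
    "fit_model",
    "regression_table",
]

#: Cauchy prior scale on standardized slopes ("medium" for regression).
DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 4.0

#: Hypothesized sign of each index's effect on tract FA: better organized
#: tracts are predicted to carry *less* offloading bias and *lower*
#: (more conservative) confidence.
DEFAULT_DIRECTIONS = {
    "confidence_internal": "-",
    "meta_bias": "-",
    "reminder_bias": "-",
    "abs_meta_bias": "-",
    "abs_reminder_bias": "-",
}


@dataclass
class RegressionSpec:
    tract: str
    index: str
    direction: str = "-"
    n_comparisons_per_tract: int = 6
    prior_scale: float = DEFAULT_PRIOR_SCALE

    def __post_init__(self):
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")
        if self.n_comparisons_per_tract < 1:
            raise ValueError("n_comparisons_per_tract must be >= 1")


@dataclass
class RegressionResult:
    tract: str
    index: str
    beta: float
    se: float
    t: float
    df: int
    p_uncorrected: float
    p_fwe: float
    bf10: float


def scale_columns(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Standardize the named columns to mean 0, SD 1 (ddof=1).

    Other columns (e.g. gender) pass through untouched. Raises on a
    zero-variance column, naming it.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise NumericalError(f"cannot scale zero-variance column {col!r}")
        out[col] = (x - x.mean()) / sd
    return out


def one_sided_p_from_t(t: float, df: float, direction: str) -> float:
    """Student-t tail probability in the stated direction ('+' or '-')."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if direction in ("+", "greater"):
        return float(stats.t.sf(t, df))
    if direction in ("-", "less"):
        return float(stats.t.cdf(t, df))
    raise ValueError("direction must be '+' or '-'")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni family-wise correction: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    """R^2 of an OLS fit of y on [1, X]."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise NumericalError("rank-deficient design (collinear predictors)")
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise NumericalError("outcome has zero variance")
    return 1.0 - float(resid @ resid) / sst


def _log_jzs_integral(r2: float, n: int, p: int, prior_scale: float) -> float:
    """log BF(M : null) for a model with p predictors and given R^2."""
    if r2 >= 1.0 - 1e-12:
        return np.inf  # saturated fit: evidence against the null diverges
    b = n * prior_scale**2 / 2.0
    log_prior_const = 0.5 * np.log(b) - gammaln(0.5)

    def log_f(u):
        g = u / (1.0 - u)
        return (
            0.5 * (n - p - 1) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2))
            + log_prior_const
            - 1.5 * np.log(g)
            - b / g
            - 2.0 * np.log1p(-u)  # Jacobian dg/du = 1/(1-u)^2
        )

    # locate the integrand's peak on a coarse grid for stable rescaling
    us = np.linspace(1e-8, 1 - 1e-8, 801)
    with np.errstate(over="ignore"):
        logs = log_f(us)
    m = float(np.max(logs))
    val, err = integrate.quad(
        lambda u: np.exp(log_f(u) - m), 0.0, 1.0, limit=200
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * val:
        raise NumericalError(
            f"JZS integration failed (value={val}, abs err={err})"
        )
    return m + np.log(val)


def jzs_bf_vs_null(
    r2: float, n: int, n_predictors: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """JZS Bayes factor of a p-predictor linear model against the
    intercept-only null, from its R^2."""
    if n_predictors == 0:
        return 1.0
    if n <= n_predictors + 1:
        raise NumericalError("need n > number of predictors + 1")
    if not 0 <= r2 <= 1:
        raise NumericalError(f"R^2 must be in [0, 1], got {r2}")
    return float(np.exp(_log_jzs_integral(r2, n, n_predictors, prior_scale)))


def _check_nested(X_full: np.ndarray, X_reduced: np.ndarray) -> None:
    if X_reduced.size == 0:
        return
    # every reduced column must lie in the full design's column span
    coef, _, _, _ = np.linalg.lstsq(X_full, X_reduced, rcond=None)
    resid = X_reduced - X_full @ coef
    scale = max(1.0, float(np.abs(X_reduced).max()))
    if np.abs(resid).max() > 1e-8 * scale:
        raise NumericalError("designs are not nested")


def jzs_inclusion_bf(
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    y: np.ndarray,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """Inclusion Bayes factor: evidence for the full over the reduced model.

    Both designs exclude the intercept (added internally) and the reduced
    design must be nested in the full one. ``bf10 > 1`` favors including
    the extra predictor(s).
    """
    X_full = np.atleast_2d(np.asarray(X_full, dtype=float))
    X_reduced = np.asarray(X_reduced, dtype=float)
    if X_reduced.ndim == 1:
        X_reduced = X_reduced.reshape(len(X_reduced), -1)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p_full, p_red = X_full.shape[1], X_reduced.shape[1] if X_reduced.size else 0
    if p_red > p_full:
        raise NumericalError("reduced design has more predictors than full")
    if p_full == p_red and np.array_equal(X_full, X_reduced):
        return 1.0
    _check_nested(X_full, X_reduced)

    log_bf_full = _log_jzs_integral(
        _r_squared(X_full, y), n, p_full, prior_scale
    )
    if p_red == 0:
        return float(np.exp(log_bf_full))
    log_bf_red = _log_jzs_integral(
        _r_squared(X_reduced, y), n, p_red, prior_scale
    )
    if np.isinf(log_bf_full) and np.isinf(log_bf_red):
        raise NumericalError(
            "both models fit perfectly; inclusion evidence undefined"
        )
    return float(np.exp(log_bf_full - log_bf_red))


def fit_model(spec: RegressionSpec, subjects: pd.DataFrame) -> RegressionResult:
    """Fit one tract x index model on a merged subject table.

    ``subjects`` must hold ``fa_<tract>``, the behavioral index column,
    ``age``, ``gender`` and ``tiv`` with no missing values. Continuous
    variables are standardized here; gender enters as coded.
    """
    outcome = f"fa_{spec.tract}" if f"fa_{spec.tract}" in subjects.columns \
        else spec.tract
    needed = [outcome, spec.index, "age", "gender", "tiv"]
    for col in needed:
        if col not in subjects.columns:
            raise NumericalError(f"subject table missing column {col!r}")
    data = subjects[needed].astype(float)
    if data.isna().any().any():
        raise NumericalError("missing values in regression inputs")
    n = len(data)
    if n < 6:
        raise NumericalError("need at least 6 subjects")
    data = scale_columns(data, [outcome, spec.index, "age", "tiv"])

    X = sm.add_constant(data[[spec.index, "age", "gender", "tiv"]].to_numpy())
    res = sm.OLS(data[outcome].to_numpy(), X).fit()
    if res.df_resid != n - 5:
        raise NumericalError("rank-deficient design (collinear predictors)")
    beta, se, t = res.params[1], res.bse[1], res.tvalues[1]
    p_unc = one_sided_p_from_t(float(t), res.df_resid, spec.direction)

    X_full = data[[spec.index, "age", "gender", "tiv"]].to_numpy()
    X_red = data[["age", "gender", "tiv"]].to_numpy()
    bf10 = jzs_inclusion_bf(X_full, X_red, data[outcome].to_numpy(),
                            spec.prior_scale)
    return RegressionResult(
        tract=spec.tract,
        index=spec.index,
        beta=float(beta),
        se=float(se),
        t=float(t),
        df=int(res.df_resid),
        p_uncorrected=p_unc,
        p_fwe=bonferroni(p_unc, spec.n_comparisons_per_tract),
        bf10=bf10,
    )


def regression_table(
    subjects: pd.DataFrame,
    tracts=None,
    indices=None,
    directions: dict[str, str] | None = None,
    n_comparisons_per_tract: int = 6,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> pd.DataFrame:
    """The full tract x index regression grid (the machine twin of a
    brain-behavior summary table)."""
    if tracts is None:
        tracts = [c[3:] for c in subjects.columns if c.startswith("fa_")]
    if indices is None:
        indices = list(DEFAULT_DIRECTIONS)
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    rows = []
    for tract in tracts:
        for index in indices:
            spec = RegressionSpec(
                tract=tract,
                index=index,
                direction=directions.get(index, "-"),
                n_comparisons_per_tract=n_comparisons_per_tract,
                prior_scale=prior_scale,
            )
            r = fit_model(spec, subjects)
            rows.append(r.__dict__)
    return pd.DataFrame(rows)
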