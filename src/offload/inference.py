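"""Group-level behavioral test battery.

Implements the frequentist tests run on a cohort's indices table: a 2x2
ANOVA of (actual vs self-judged) accuracy across (internal vs external)
strategy conditions, Welch's unequal-variance t-test for the post-hoc
condition contrast, a one-sided one-sample t-test on the reminder bias
(directional prediction: OIP > AIP, i.e. people over-use reminders), and
one-sided Pearson correlations between reminder bias and metacognitive
measures (directional prediction: more under-confidence, more pro-reminder
bias).

One-sided p-values are computed in the pre-registered direction only;
when the observed effect lies in that direction they equal half the
two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import NumericalError, SchemaError

__all__ = [
    "TestResult",
    "anova_2x2",
    "welch_t",
    "one_sample_t_one_sided",
    "pearson_one_sided",
    "behavioral_battery",
]

_DIRECTIONS = {"greater": "greater", "less": "less", "+": "greater",
               "-": "less", "positive": "greater", "negative": "less"}


def _alt(direction: str) -> str:
    try:
        return _DIRECTIONS[direction]
    except KeyError:
        raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    sidedness: str  # "one" or "two"
    estimate: float | None = None
    ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "estimate": self.estimate,
            "ci": list(self.ci) if self.ci is not None else None,
        }


def anova_2x2(long: pd.DataFrame) -> dict[str, TestResult]:
    """Two-way ANOVA of value ~ condition x measure.

    ``long`` needs columns ``value`` (accuracy-like percent), ``condition``
    (internal/external) and ``measure`` (actual/self-judged). The four
    cells are treated as independent groups — a plain factorial
    decomposition, with error df = N - 4.
    """
    for col in ("value", "condition", "measure"):
        if col not in long.columns:
            raise SchemaError(f"ANOVA table missing column {col!r}")
    cells = long.groupby(["condition", "measure"], observed=True).size()
    if len(cells) < 4 or (cells == 0).any():
        raise NumericalError("2x2 ANOVA requires observations in all 4 cells")
    model = smf.ols("value ~ C(condition) * C(measure)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_err = float(table.loc["Residual", "df"])
    out = {}
    for key, row_name in (
        ("condition", "C(condition)"),
        ("measure", "C(measure)"),
        ("interaction", "C(condition):C(measure)"),
    ):
        out[key] = TestResult(
            statistic=float(table.loc[row_name, "F"]),
            df=df_err,
            p_value=float(table.loc[row_name, "PR(>F)"]),
            sidedness="two",
        )
    return out


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degrees of freedom follow the Welch-Satterthwaite approximation and
    are generally fractional.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise NumericalError("both samples need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise NumericalError("undefined test: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        sidedness="two",
        estimate=float(a.mean() - b.mean()),
        ci=(float(ci.low), float(ci.high)),
    )


def one_sample_t_one_sided(differences, direction: str = "greater") -> TestResult:
    """One-sided one-sample t-test of mean(differences) against zero."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise NumericalError("need n >= 2")
    if np.var(d, ddof=1) == 0:
        raise NumericalError("undefined test: zero variance")
    res = stats.ttest_1samp(d, 0.0, alternative=_alt(direction))
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(d) - 1),
        p_value=float(res.pvalue),
        sidedness="one",
        estimate=float(d.mean()),
    )


def pearson_one_sided(x, y, direction: str = "less") -> TestResult:
    """One-sided Pearson correlation test; df = n - 2.

    The p-value is the directional tail of t = r * sqrt(df / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise NumericalError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise NumericalError("undefined correlation: zero variance")
    res = stats.pearsonr(x, y, alternative=_alt(direction))
    r = float(res.statistic)
    df = len(x) - 2
    return TestResult(
        statistic=r,
        df=float(df),
        p_value=float(res.pvalue),
        sidedness="one",
        estimate=r,
    )


def behavioral_battery(indices: pd.DataFrame) -> dict[str, dict]:
    """Run the full behavioral test battery on an indices table.

    Returns a JSON-serializable report keyed by test name:

    * ``anova_*`` — 2x2 condition x measure ANOVA on actual accuracy and
      prospective confidence;
    * ``welch_external_vs_internal`` — post-hoc accuracy contrast;
    * ``reminder_bias_gt_zero`` — one-sided t on OIP - AIP;
    * ``reminder_vs_meta_bias`` / ``reminder_vs_confidence`` — one-sided
      (negative-direction) correlations.

    Subjects with a missing AIP are dropped from AIP-dependent tests only.
    """
    if "confidence_external" in indices.columns:
        conf_ext = indices["confidence_external"]
    else:
        conf_ext = None
    rows = []
    for _, r in indices.iterrows():
        rows.append({"value": r["acc_fi"], "condition": "internal",
                     "measure": "actual"})
        rows.append({"value": r["acc_fe"], "condition": "external",
                     "measure": "actual"})
        rows.append({"value": r["confidence_internal"],
                     "condition": "internal", "measure": "self-judged"})
    if conf_ext is not None:
        for v in conf_ext:
            rows.append({"value": v, "condition": "external",
                         "measure": "self-judged"})
    long = pd.DataFrame(rows)

    report: dict[str, dict] = {}
    if conf_ext is not None:
        for key, res in anova_2x2(long).items():
            report[f"anova_{key}"] = res.to_dict()
    report["welch_external_vs_internal"] = welch_t(
        indices["acc_fe"], indices["acc_fi"]
    ).to_dict()

    complete = indices.dropna(subset=["reminder_bias"])
    report["reminder_bias_gt_zero"] = one_sample_t_one_sided(
        complete["reminder_bias"], "greater"
    ).to_dict()
    report["reminder_vs_meta_bias"] = pearson_one_sided(
        complete["reminder_bias"], complete["meta_bias"], "less"
    ).to_dict()
    report["reminder_vs_confidence"] = pearson_one_sided(
        complete["reminder_bias"], complete["confidence_internal"], "less"
    ).to_dict()
    return report
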