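"""Psychometric estimation of the actual indifference point (AIP).

A subject's free-trial choices (external target value v, chose_external)
are modelled as independent Bernoulli draws with

    P(external | v) = Phi((v - aip) / spread)

where Phi is the standard normal CDF. The location parameter ``aip`` is
the 50% point — the value at which the subject is behaviorally indifferent
between internal memory and external reminders — and ``spread`` is the
inverse steepness of the choice curve. Both are estimated by maximum
likelihood.

With the task's seven free trials the likelihood can be degenerate:

* perfectly separable choices (every external choice above every internal
  one) drive ``spread`` to its lower bound and leave the location
  likelihood flat across the separating gap; the fit reports the gap
  midpoint — the symmetry point of the limiting likelihood — and flags
  ``converged=False``;
* all-identical choices identify nothing; ``aip``/``spread`` are NaN.

``spread`` is bounded to [0.05, 50] points so the optimizer cannot
diverge on sparse data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr

__all__ = ["PsychometricFit", "fit_psychometric", "apply_exclusions",
           "SPREAD_BOUNDS"]

SPREAD_BOUNDS = (0.05, 50.0)


@dataclass
class PsychometricFit:
    """Result of the cumulative-normal choice-curve fit for one subject."""

    aip: float
    spread: float
    log_likelihood: float
    converged: bool
    value_choice_correlation: float
    n_trials_used: int

    def predict(self, v) -> np.ndarray:
        """Fitted P(choose external | target value v)."""
        return ndtr((np.asarray(v, dtype=float) - self.aip) / self.spread)


def _neg_log_lik(params, v, y):
    aip, log_spread = params
    z = (v - aip) / np.exp(log_spread)
    # log Phi(z) for y=1, log Phi(-z) for y=0, both via log_ndtr for stability
    return -(np.sum(log_ndtr(z[y])) + np.sum(log_ndtr(-z[~y])))


def _point_biserial(v, y):
    """Pearson correlation of value with the 0/1 choice; 0.0 if undefined."""
    if np.ptp(v) == 0 or y.all() or not y.any():
        return 0.0
    return float(np.corrcoef(v, y.astype(float))[0, 1])


def fit_psychometric(choices) -> PsychometricFit:
    """Maximum-likelihood psychometric fit of P(external | value).

    Parameters
    ----------
    choices
        Iterable of ``(target_value, chose_external)`` pairs (or a
        2-column array-like). At least two trials are required.

    Returns
    -------
    PsychometricFit
        ``aip`` may legitimately fall outside the tested value range
        [2, 8]; extrapolated locations are reported as-is. Degenerate
        data yield ``converged=False`` (see module docstring).
    """
    arr = np.asarray(list(choices), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("choices must be (target_value, chose_external) pairs")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 trials to fit a choice curve")
    v = arr[:, 0]
    y = arr[:, 1].astype(bool)
    n = len(v)
    corr = _point_biserial(v, y)

    if y.all() or not y.any():
        warnings.warn(
            "degenerate fit: all choices identical; aip is undefined",
            stacklevel=2,
        )
        return PsychometricFit(
            aip=np.nan, spread=np.nan, log_likelihood=0.0, converged=False,
            value_choice_correlation=corr, n_trials_used=n,
        )
    if len(np.unique(v)) < 2:
        warnings.warn(
            "non-identifiable fit: mixed choices at a single value",
            stacklevel=2,
        )

    lo, hi = SPREAD_BOUNDS
    separable = v[y].min() > v[~y].max()
    if separable:
        mid = 0.5 * (v[y].min() + v[~y].max())
        nll = _neg_log_lik([mid, np.log(lo)], v, y)
        warnings.warn(
            "separable choices: spread at lower bound, aip set to the "
            "midpoint of the separating gap",
            stacklevel=2,
        )
        return PsychometricFit(
            aip=float(mid), spread=lo, log_likelihood=float(-nll),
            converged=False, value_choice_correlation=corr, n_trials_used=n,
        )

    # multistart: coarse grid seeds a bounded quasi-Newton refinement
    starts = []
    for a0 in np.linspace(v.min() - 1, v.max() + 1, 9):
        for s0 in (0.3, 1.0, 3.0):
            starts.append((a0, np.log(s0)))
    best = None
    bounds = [(v.min() - 100.0, v.max() + 100.0), (np.log(lo), np.log(hi))]
    start_vals = [(s, _neg_log_lik(s, v, y)) for s in starts]
    start_vals.sort(key=lambda t: t[1])
    for s0, _ in start_vals[:4]:
        res = optimize.minimize(
            _neg_log_lik, x0=s0, args=(v, y), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    aip = float(best.x[0])
    spread = float(np.exp(best.x[1]))
    return PsychometricFit(
        aip=aip,
        spread=spread,
        log_likelihood=float(-best.fun),
        converged=bool(best.success),
        value_choice_correlation=corr,
        n_trials_used=n,
    )


def fit_cohort(trials: pd.DataFrame) -> dict[str, PsychometricFit]:
    """Fit every subject's free-trial choice curve from a trials table."""
    free = trials[trials["condition"] == "free"]
    fits: dict[str, PsychometricFit] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, grp in free.groupby("subject_id", sort=True):
            pairs = list(
                zip(grp["target_value"].astype(float),
                    grp["chose_external"].astype(bool))
            )
            fits[sid] = fit_psychometric(pairs)
    return fits


def apply_exclusions(
    fits: dict[str, PsychometricFit],
) -> tuple[dict[str, PsychometricFit], dict[str, PsychometricFit], pd.DataFrame]:
    """Apply the pre-analysis exclusion rule.

    Subjects whose value <-> choice correlation is strictly negative are
    excluded (their choices run against the reward gradient, implying a
    random or counter-rational strategy). A correlation of exactly zero,
    or one undefined because choices or values do not vary, keeps the
    subject.

    Returns ``(kept, excluded, report)``; the report lists each excluded
    subject with its correlation.
    """
    kept, excluded, rows = {}, {}, []
    for sid, fit in fits.items():
        if fit.value_choice_correlation < 0:
            excluded[sid] = fit
            rows.append(
                {"subject_id": sid,
                 "value_choice_correlation": fit.value_choice_correlation}
            )
        else:
            kept[sid] = fit
    report = pd.DataFrame(rows, columns=["subject_id",
                                         "value_choice_correlation"])
    return kept, excluded, report


def fits_frame(fits: dict[str, PsychometricFit]) -> pd.DataFrame:
    """Per-subject fit table (exportable to CSV)."""
    return pd.DataFrame(
        [
            {
                "subject_id": sid,
                "aip": f.aip,
                "spread": f.spread,
                "converged": f.converged,
                "value_choice_correlation": f.value_choice_correlation,
            }
            for sid, f in fits.items()
        ]
    )
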