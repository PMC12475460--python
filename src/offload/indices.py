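"""Behavioral indices of metacognition-driven cognitive offloading.

Seven per-subject indices are computed from trial-level data, a
psychometric fit, and a prospective confidence rating:

* ``acc_fi`` / ``acc_fe`` — percent of targets handled correctly in the
  forced-internal / forced-external trials (ratio of summed corrects to
  summed targets, x100);
* ``oip`` — optimal indifference point, ``10 * ACC_FI / ACC_FE`` points:
  the external target value at which a reward-maximizing agent is
  indifferent between the 10-point internal strategy and reminders;
* ``aip`` — actual indifference point, the 50% point of the fitted
  choice curve;
* ``reminder_bias = oip - aip`` (positive = over-reliance on reminders)
  and its absolute value;
* ``meta_bias = confidence_internal - acc_fi`` in percentage points
  (negative = under-confidence) and its absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import MissingDataError, NumericalError
from .psychometrics import PsychometricFit

__all__ = [
    "SubjectIndices",
    "compute_accuracy",
    "compute_oip",
    "expected_points",
    "compute_indices",
    "indices_table",
]


@dataclass
class SubjectIndices:
    acc_fi: float
    acc_fe: float
    oip: float
    aip: float
    reminder_bias: float
    abs_reminder_bias: float
    confidence_internal: float
    meta_bias: float
    abs_meta_bias: float


def compute_accuracy(trials: pd.DataFrame, condition: str) -> float:
    """Percent correct over all trials of one forced condition.

    Pools targets across trials: ``100 * sum(n_correct) / sum(n_targets)``.
    With a constant number of targets per trial this equals the mean of
    per-trial percentages.
    """
    sub = trials[trials["condition"] == condition]
    if len(sub) == 0:
        raise MissingDataError(f"no trials with condition {condition!r}")
    total = int(sub["n_targets"].sum())
    if total == 0:
        raise MissingDataError(f"condition {condition!r} has zero targets")
    return 100.0 * float(sub["n_correct"].sum()) / total


def compute_oip(acc_fi: float, acc_fe: float) -> float:
    """Optimal indifference point in points: 10 * ACC_FI / ACC_FE.

    Accuracies may be given as percent or as proportions, as long as both
    use the same scale (the ratio is scale-free).
    """
    if acc_fe <= 0:
        raise NumericalError("OIP undefined: external accuracy is zero")
    if acc_fi < 0:
        raise NumericalError("internal accuracy must be non-negative")
    return 10.0 * acc_fi / acc_fe


def expected_points(value: float, accuracy: float) -> float:
    """Expected reward per target: value x accuracy, accuracy in percent."""
    if value < 0:
        raise ValueError("value must be non-negative")
    if not 0 <= accuracy <= 100:
        raise ValueError("accuracy must be in [0, 100]")
    return value * accuracy / 100.0


def compute_indices(
    trials: pd.DataFrame,
    fit: PsychometricFit,
    confidence_internal: float,
) -> SubjectIndices:
    """Assemble all behavioral indices for one subject.

    ``trials`` must contain both forced conditions for this subject.
    If the psychometric fit did not converge, the AIP-dependent fields
    (aip, reminder_bias, abs_reminder_bias) are NaN — downstream analyses
    see the missingness rather than a fabricated indifference point.
    """
    acc_fi = compute_accuracy(trials, "forced_internal")
    acc_fe = compute_accuracy(trials, "forced_external")
    oip = compute_oip(acc_fi, acc_fe)
    if fit.converged and np.isfinite(fit.aip):
        aip = float(fit.aip)
    elif np.isfinite(fit.aip):
        # separable-but-located fit: keep the tie-broken location
        aip = float(fit.aip)
    else:
        aip = np.nan
    rb = oip - aip
    mb = confidence_internal - acc_fi
    return SubjectIndices(
        acc_fi=acc_fi,
        acc_fe=acc_fe,
        oip=oip,
        aip=aip,
        reminder_bias=rb,
        abs_reminder_bias=abs(rb),
        confidence_internal=float(confidence_internal),
        meta_bias=mb,
        abs_meta_bias=abs(mb),
    )


def indices_table(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    fits: dict[str, PsychometricFit],
) -> pd.DataFrame:
    """Per-subject indices for every subject present in ``fits``.

    Subjects are processed in the order of the subject table; subjects
    without a fit (e.g. excluded) are skipped.
    """
    rows = []
    for _, srow in subjects.iterrows():
        sid = srow["subject_id"]
        if sid not in fits:
            continue
        sub_trials = trials[trials["subject_id"] == sid]
        idx = compute_indices(sub_trials, fits[sid],
                              float(srow["confidence_internal"]))
        rows.append({"subject_id": sid, **asdict(idx)})
    return pd.DataFrame(rows)
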