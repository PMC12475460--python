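"""Synthetic cohort generator for the cognitive-offloading task.

Emulates the statistical structure of a delayed-intention offloading
experiment: each subject completes a small number of forced-internal and
forced-external trials (accuracy measured as targets correctly handled out
of ``targets_per_trial``) plus free-choice trials in which an external
target value v in [2, 8] trades off against the fixed 10-point internal
reward, and the subject chooses the reminder strategy with probability
increasing in v.

Generative model, per subject:

* internal / external accuracy are drawn from bounded distributions on
  [0, 100] whose *realized* mean and SD equal the configured moments
  (see :func:`_sample_bounded`);
* the optimal indifference point is ``OIP = 10 * ACC_FI / ACC_FE``;
* metacognitive bias b ~ Normal(mu_b, sd_b); prospective confidence for
  internal memory is ``clamp(ACC_FI + b, 0, 100)``;
* the actual indifference point is
  ``AIP = OIP - (bias_coupling * b + eps)``, eps ~ Normal(0, aip_noise_sd),
  so with negative coupling, under-confident subjects (b < 0) sit below
  their OIP and show a pro-reminder bias;
* free-trial choices are Bernoulli with
  ``P(external | v) = logistic(choice_slope * (v - AIP))``;
* per-tract fractional anisotropy is linear in one standardized behavioral
  index plus age/TIV slopes, a gender offset and Gaussian noise, mapped
  into (0, 1) by a fixed affine transform (harmless downstream, where all
  continuous variables are re-standardized).

The default configuration reproduces the study conditions this package
analyzes: internal accuracy ~ (60.36, 15.54), external accuracy ~
(95.66, 8.40), group reminder bias mean 0.586 with SD 2.036, and a
reminder-bias <-> metacognitive-bias correlation of -0.384 in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, SchemaError

__all__ = [
    "CohortConfig",
    "TrialRecord",
    "SubjectGroundTruth",
    "TRACTS",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: White-matter tracts carried by the subject table (FA columns fa_<tract>).
TRACTS = ("slf_l", "slf_r", "cb_l", "cb_r", "fornix", "uf_l", "uf_r")

TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "condition",
    "target_value",
    "n_targets",
    "n_correct",
    "chose_external",
]
SUBJECT_COLUMNS = [
    "subject_id",
    "confidence_internal",
    "confidence_external",
    "age",
    "gender",
    "tiv",
] + [f"fa_{t}" for t in TRACTS]

CONDITIONS = ("forced_internal", "forced_external", "free")


def _default_tract_effects() -> dict[str, tuple[str, float]]:
    # tract -> (behavioral index driving its FA, standardized slope)
    return {
        "slf_l": ("abs_reminder_bias", -0.437),
        "slf_r": ("abs_reminder_bias", -0.351),
        "cb_l": ("abs_reminder_bias", -0.331),
        "cb_r": ("abs_reminder_bias", -0.383),
        "fornix": ("confidence_internal", -0.322),
        "uf_l": ("abs_reminder_bias", 0.0),
        "uf_r": ("abs_reminder_bias", 0.0),
    }


def _default_covariate_effects() -> dict[str, float]:
    return {"age": 0.10, "tiv": 0.10, "gender": 0.10}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    The bias parameters are jointly calibrated so that, in expectation,
    reminder bias = ``bias_coupling * meta_bias + eps`` has mean 0.586 and
    SD 2.036 and correlates -0.384 with meta bias:
    ``bias_coupling * meta_bias_sd = -0.384 * 2.0357`` and
    ``aip_noise_sd = 2.0357 * sqrt(1 - 0.384^2)``.
    """

    n_subjects: int = 34
    n_free_trials: int = 7
    n_forced_internal: int = 3
    n_forced_external: int = 3
    targets_per_trial: int = 7
    acc_fi_mean: float = 60.3642
    acc_fi_sd: float = 15.54
    acc_fe_mean: float = 95.6583
    acc_fe_sd: float = 8.4020
    meta_bias_mean: float = -3.7482
    meta_bias_sd: float = 5.0
    bias_coupling: float = -0.156342
    aip_noise_sd: float = 1.87962
    choice_slope: float = 2.0
    tract_effects: dict[str, tuple[str, float]] = field(
        default_factory=_default_tract_effects
    )
    covariate_effects: dict[str, float] = field(
        default_factory=_default_covariate_effects
    )
    fa_noise_sd: float = 0.50
    age_mean: float = 28.47
    age_sd: float = 8.82
    tiv_mean: float = 1400.0
    tiv_sd: float = 130.0
    seed: int = 1234

    def validate(self) -> None:
        for name in ("acc_fi_sd", "acc_fe_sd", "meta_bias_sd", "aip_noise_sd",
                     "fa_noise_sd", "age_sd", "tiv_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_free_trials < 2:
            raise ConfigError("n_free_trials must be >= 2")
        if self.targets_per_trial < 1:
            raise ConfigError("targets_per_trial must be >= 1")
        if self.choice_slope <= 0:
            raise ConfigError("choice_slope must be > 0")
        for mean_name in ("acc_fi_mean", "acc_fe_mean"):
            m = getattr(self, mean_name)
            if not 0 < m < 100:
                raise ConfigError(f"{mean_name} must lie strictly in (0, 100)")
        known = {"acc_fi", "acc_fe", "oip", "aip", "reminder_bias",
                 "abs_reminder_bias", "confidence_internal", "meta_bias",
                 "abs_meta_bias"}
        for tract, (index, _slope) in self.tract_effects.items():
            if tract not in TRACTS:
                raise ConfigError(f"unknown tract {tract!r}")
            if index not in known:
                raise ConfigError(f"unknown behavioral index {index!r} for {tract}")


@dataclass
class TrialRecord:
    """One task trial; target_value/chose_external apply to free trials only."""

    subject_id: str
    trial_index: int
    condition: str
    n_targets: int
    n_correct: int
    target_value: int | None = None
    chose_external: bool | None = None


@dataclass
class SubjectGroundTruth:
    """Generative (latent) quantities behind one subject's observed data."""

    subject_id: str
    true_acc_fi: float
    true_acc_fe: float
    true_oip: float
    true_aip: float
    true_meta_bias: float
    confidence_internal: float
    confidence_external: float
    age: float
    gender: int
    tiv: float
    fa: dict[str, float]


def _sample_bounded(rng, n, mean, sd, lo=0.0, hi=100.0):
    """Draw n values on [lo, hi] whose population mean/SD equal mean/sd.

    Primary family: truncated normal with parent parameters solved so that
    the realized (post-truncation) moments match the targets. Near a bound
    the requested SD can exceed anything a truncated normal can deliver
    (e.g. ceiling-level accuracy with a long lower tail); there a
    moment-matched scaled Beta is used instead, which reaches any moment
    pair with variance < (mean-lo)(hi-mean).
    """
    span = hi - lo
    m01 = (mean - lo) / span
    v01 = (sd / span) ** 2
    if v01 >= m01 * (1 - m01):
        raise ConfigError(
            f"no distribution on [{lo},{hi}] has mean {mean} and sd {sd}"
        )

    def moment_gap(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        tm, tv = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [tm - mean, np.sqrt(tv) - sd]

    sol = optimize.root(moment_gap, x0=[mean, np.log(sd)], method="hybr")
    if sol.success and np.max(np.abs(sol.fun)) < 1e-6:
        mu, sigma = sol.x[0], np.exp(sol.x[1])
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                                   random_state=rng)
    # ceiling/floor regime: Beta with the exact target moments
    nu = m01 * (1 - m01) / v01 - 1
    alpha, beta = m01 * nu, (1 - m01) * nu
    return lo + span * stats.beta.rvs(alpha, beta, size=n, random_state=rng)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[TrialRecord], list[SubjectGroundTruth]]:
    """Simulate a full cohort of agents performing the offloading task.

    Returns the trial-level records and the per-subject ground truth.
    Deterministic given ``config`` (including ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    acc_fi = _sample_bounded(rng, n, config.acc_fi_mean, config.acc_fi_sd)
    acc_fe = _sample_bounded(rng, n, config.acc_fe_mean, config.acc_fe_sd)
    meta_bias = rng.normal(config.meta_bias_mean, config.meta_bias_sd, n)
    aip_noise = rng.normal(0.0, config.aip_noise_sd, n)

    oip = 10.0 * acc_fi / acc_fe
    # reminder bias (oip - aip) = coupling * meta_bias + noise
    aip = oip - (config.bias_coupling * meta_bias + aip_noise)
    conf_int = np.clip(acc_fi + meta_bias, 0.0, 100.0)
    conf_ext = np.clip(acc_fe + rng.normal(0.0, config.meta_bias_sd, n),
                       0.0, 100.0)

    age = rng.normal(config.age_mean, config.age_sd, n)
    gender = rng.integers(0, 2, n)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, n)

    index_pool = {
        "acc_fi": acc_fi,
        "acc_fe": acc_fe,
        "oip": oip,
        "aip": aip,
        "reminder_bias": oip - aip,
        "abs_reminder_bias": np.abs(oip - aip),
        "confidence_internal": conf_int,
        "meta_bias": meta_bias,
        "abs_meta_bias": np.abs(meta_bias),
    }

    def _z(x):
        s = np.std(x, ddof=1) if len(x) > 1 else 1.0
        return (x - np.mean(x)) / s if s > 0 else np.zeros_like(x)

    fa_cols: dict[str, np.ndarray] = {}
    cov = config.covariate_effects
    for tract in TRACTS:
        index_name, slope = config.tract_effects.get(
            tract, ("abs_reminder_bias", 0.0)
        )
        raw = (
            slope * _z(index_pool[index_name])
            + cov.get("age", 0.0) * _z(age)
            + cov.get("tiv", 0.0) * _z(tiv)
            + cov.get("gender", 0.0) * gender
            + rng.normal(0.0, config.fa_noise_sd, n)
        )
        # fixed affine map into (0, 1); ~8 raw SDs of headroom either side
        fa_cols[tract] = 0.5 + 0.06 * raw

    subjects: list[SubjectGroundTruth] = []
    trials: list[TrialRecord] = []
    values = np.arange(2, 9)
    for i in range(n):
        sid = f"S{i + 1:03d}"
        subjects.append(
            SubjectGroundTruth(
                subject_id=sid,
                true_acc_fi=float(acc_fi[i]),
                true_acc_fe=float(acc_fe[i]),
                true_oip=float(oip[i]),
                true_aip=float(aip[i]),
                true_meta_bias=float(meta_bias[i]),
                confidence_internal=float(conf_int[i]),
                confidence_external=float(conf_ext[i]),
                age=float(age[i]),
                gender=int(gender[i]),
                tiv=float(tiv[i]),
                fa={t: float(fa_cols[t][i]) for t in TRACTS},
            )
        )
        k = 0
        for cond, acc in (
            ("forced_internal", acc_fi[i]),
            ("forced_external", acc_fe[i]),
        ):
            n_rep = (config.n_forced_internal if cond == "forced_internal"
                     else config.n_forced_external)
            for _ in range(n_rep):
                k += 1
                trials.append(
                    TrialRecord(
                        subject_id=sid,
                        trial_index=k,
                        condition=cond,
                        n_targets=config.targets_per_trial,
                        n_correct=int(
                            rng.binomial(config.targets_per_trial, acc / 100.0)
                        ),
                    )
                )
        vs = rng.choice(values, size=config.n_free_trials, replace=True)
        for v in vs:
            k += 1
            p_ext = 1.0 / (1.0 + np.exp(-config.choice_slope * (v - aip[i])))
            trials.append(
                TrialRecord(
                    subject_id=sid,
                    trial_index=k,
                    condition="free",
                    n_targets=config.targets_per_trial,
                    n_correct=int(
                        rng.binomial(
                            config.targets_per_trial,
                            (acc_fe[i] if rng.random() < p_ext else acc_fi[i])
                            / 100.0,
                        )
                    ),
                    target_value=int(v),
                    chose_external=bool(rng.random() < p_ext),
                )
            )
    return trials, subjects


def trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame in the canonical column order."""
    df = pd.DataFrame([asdict(t) for t in trials])
    return df[TRIAL_COLUMNS]


def subjects_frame(subjects: list[SubjectGroundTruth]) -> pd.DataFrame:
    """Observable subject table (ground-truth latents are dropped)."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "confidence_internal": s.confidence_internal,
            "confidence_external": s.confidence_external,
            "age": s.age,
            "gender": s.gender,
            "tiv": s.tiv,
        }
        row.update({f"fa_{t}": s.fa[t] for t in TRACTS})
        rows.append(row)
    return pd.DataFrame(rows)[SUBJECT_COLUMNS]


def write_cohort(trials, subjects, path) -> tuple[Path, Path]:
    """Write trials.csv and subjects.csv under directory ``path``.

    ``trials``/``subjects`` may be record lists or DataFrames already in
    the canonical schema. Floats are written at full precision; cells that
    do not apply (target_value / chose_external off free trials) are empty.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tdf = trials if isinstance(trials, pd.DataFrame) else trials_frame(trials)
    sdf = (subjects if isinstance(subjects, pd.DataFrame)
           else subjects_frame(subjects))
    tdf = tdf.copy()
    # booleans serialize as 1/0 so the round trip is type-stable
    tdf["chose_external"] = tdf["chose_external"].map(
        lambda x: "" if pd.isna(x) else int(bool(x))
    )
    tdf["target_value"] = tdf["target_value"].map(
        lambda x: "" if pd.isna(x) else int(x)
    )
    tpath, spath = path / "trials.csv", path / "subjects.csv"
    tdf.to_csv(tpath, index=False)
    sdf.to_csv(spath, index=False)
    return tpath, spath


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column(s) {missing}")


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort directory written by :func:`write_cohort`.

    Returns ``(trials, subjects)`` DataFrames. Condition labels are
    case-normalized; schema violations raise :class:`SchemaError` naming
    the offending column and row.
    """
    path = Path(path)
    tpath, spath = path / "trials.csv", path / "subjects.csv"
    for p in (tpath, spath):
        if not p.exists():
            raise SchemaError(f"missing input file: {p}")
    trials = pd.read_csv(tpath, dtype={"subject_id": str})
    subjects = pd.read_csv(spath, dtype={"subject_id": str})
    _require_columns(trials, TRIAL_COLUMNS, "trials.csv")
    _require_columns(subjects, SUBJECT_COLUMNS, "subjects.csv")

    trials = trials.copy()
    trials["condition"] = trials["condition"].astype(str).str.strip().str.lower()
    bad = ~trials["condition"].isin(CONDITIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"trials.csv: unknown condition "
            f"{trials['condition'].iloc[row]!r} at row {row}"
        )
    for col in ("trial_index", "n_targets", "n_correct"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"trials.csv: non-numeric {col} at row {row}")
        trials[col] = vals.astype(int)
    if (trials["n_correct"] > trials["n_targets"]).any() or (
        trials["n_correct"] < 0
    ).any():
        row = int(
            np.flatnonzero(
                ((trials["n_correct"] > trials["n_targets"])
                 | (trials["n_correct"] < 0)).to_numpy()
            )[0]
        )
        raise SchemaError(
            f"trials.csv: n_correct outside [0, n_targets] at row {row}"
        )

    free = trials["condition"] == "free"
    for col in ("target_value", "chose_external"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        missing_on_free = free & vals.isna()
        if missing_on_free.any():
            row = int(np.flatnonzero(missing_on_free.to_numpy())[0])
            raise SchemaError(
                f"trials.csv: {col} missing on free trial at row {row}"
            )
        present_off_free = ~free & vals.notna()
        if present_off_free.any():
            row = int(np.flatnonzero(present_off_free.to_numpy())[0])
            raise SchemaError(
                f"trials.csv: {col} set on a non-free trial at row {row}"
            )
        trials[col] = vals
    trials["chose_external"] = trials["chose_external"].map(
        lambda x: bool(int(x)) if pd.notna(x) else None
    )
    trials["target_value"] = trials["target_value"].map(
        lambda x: int(x) if pd.notna(x) else None
    )

    for col in SUBJECT_COLUMNS[1:]:
        vals = pd.to_numeric(subjects[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"subjects.csv: non-numeric {col} at row {row}")
        subjects[col] = vals
    return trials, subjects
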