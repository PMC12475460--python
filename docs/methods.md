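# Methods

`offload` analyzes metacognition-driven cognitive offloading in a
delayed-intention task: participants either hold intentions in internal
memory (worth 10 points per correct target) or offload them to external
reminders (worth a variable 2–8 points), and the analysis asks how far
each person's strategy choices deviate from the reward-maximizing policy,
and whether that deviation relates to white-matter microstructure.

## Behavioral model

For a subject with forced-internal accuracy `ACC_FI` and forced-external
accuracy `ACC_FE` (percent), the **optimal indifference point** is

    OIP = 10 · ACC_FI / ACC_FE   (points),

the external value at which expected reward is equal under either
strategy (`v · ACC_FE = 10 · ACC_FI` at `v = OIP`). The **actual
indifference point** (AIP) is the 50% point of the subject's choice
curve, modelled as a cumulative-normal psychometric function

    P(choose external | v) = Φ((v − AIP) / σ),

fitted by maximum likelihood over the subject's free-choice trials.
**Reminder bias** is `OIP − AIP` (positive = over-reliance on reminders);
**metacognitive bias** is prospective confidence minus `ACC_FI`
(negative = under-confidence).

### Psychometric fitting choices

* Family: cumulative normal, no guess/lapse parameters. AIP is the
  location parameter; extrapolated AIPs outside the tested range [2, 8]
  are reported as-is and are legitimate (a subject who should always or
  never offload has an indifference point outside the offered values).
* σ (`spread`) is bounded to [0.05, 50] points. With only seven free
  trials the unconstrained MLE diverges whenever the data are separable;
  the bound keeps the optimizer finite and reproducible.
* Perfectly separable choices leave the location likelihood flat across
  the separating gap once σ hits its lower bound. The fit reports the gap
  midpoint — the symmetry point of the limiting likelihood — with
  `converged=False`. All-identical choices identify nothing: AIP is NaN
  and every AIP-derived index propagates the missingness rather than
  inventing a value.
* Exclusion rule: subjects whose Pearson correlation between target value
  and the 0/1 choice is strictly negative are excluded before analysis
  (choices running against the reward gradient indicate a random or
  counter-rational strategy). An exactly-zero or undefined correlation
  (no variance in values or choices) keeps the subject; undefined
  correlations are stored as 0.

## Group inference

The test battery mirrors the standard analysis of this task family: a
2×2 ANOVA of accuracy-like scores across condition (internal/external)
and measure (actual/self-judged), Welch's unequal-variance t for the
post-hoc condition contrast, a **one-sided** one-sample t on reminder
bias (directional prediction: positive, i.e. pro-reminder), and
one-sided Pearson correlations of reminder bias with metacognitive bias
and with confidence (directional prediction: negative). The ANOVA treats
the four condition×measure scores per subject as independent cells
(plain two-way ANOVA, error df = N − 4); a full repeated-measures
decomposition is deliberately out of scope, and the reported df always
come from the data at hand. One-sided p-values are the directional tail
only; when the effect lies in the predicted direction they equal half
the two-sided p.

## Brain–behavior regressions and JZS Bayes factors

Each tract's mean fractional anisotropy (FA) is regressed on one
behavioral index with age, gender and total intracranial volume (TIV)
as covariates:

    FA (scaled) ~ index (scaled) + age (scaled) + gender + TIV (scaled).

All continuous columns are standardized (ddof = 1) first, so the index
coefficient is a standardized slope and the residual df is n − 5.
Uncorrected p-values are one-sided in the hypothesized direction
(negative by default: better-organized tracts are predicted to carry
less offloading bias and lower confidence); the family-wise correction
is Bonferroni with m = 6 comparisons per tract by default (configurable).

Evidence for including the behavioral predictor is a JZS inclusion
Bayes factor. For a model with p standardized predictors and fit R²,

    BF(M : null) = ∫₀^∞ (1+g)^{(n−p−1)/2} [1 + g(1−R²)]^{−(n−1)/2} π(g) dg,
    π(g) = InvGamma(1/2, n·r²/2),

which corresponds to independent Cauchy(0, r) priors on the standardized
slopes, with the conventional "medium" regression scale r = √2/4 as the
default. The inclusion factor is BF(full : null) / BF(reduced : null)
with the reduced model holding only the covariates. Numerically the
integral is evaluated in log space after the substitution u = g/(1+g)
(mapping (0, ∞) to (0, 1)): the peak of the log-integrand is located on
an 801-point grid and factored out before adaptive quadrature, so the
computation is overflow-proof for any n and R². A saturated fit
(R² = 1 to machine precision) returns an infinite Bayes factor; if both
compared models saturate, the inclusion evidence is undefined and an
error is raised. The test suite cross-checks this quadrature against an
independent 10⁶-point trapezoid rule on the transformed axis (agreement
to better than 4 significant digits) and verifies the transitivity
identity BF(full:reduced)·BF(reduced:null) = BF(full:null).

## Monte Carlo Bayesian power analysis

Design sensitivity is estimated by simulation at the standardized scale:
per iteration, predictor, age and TIV ~ N(0, 1), gender ~ Bernoulli(1/2),
and

    y = 0.35·x + 0.10·age + 0.10·TIV + 0.10·gender + N(0, 0.50).

Power is the fraction of 1000 iterations (34 subjects each) in which the
JZS inclusion Bayes factor for x exceeds 3. At these defaults the
estimated power is ≈ 0.90–0.92 depending on seed (Monte Carlo SE ≈ 0.009
at 1000 iterations; `mc_se = sqrt(power·(1−power)/n_iter)` is reported
with every run). The gender offset's size is nearly irrelevant because
gender appears in both compared models; a sweep over offsets
{0, 0.1, 0.5} in the tests confirms power moves by less than Monte Carlo
noise. Variables are generated already near-standard scale and are not
re-standardized inside the loop.

## Synthetic cohort generator

The generator emulates the study conditions end to end so that every
stage is testable without any participant data. Defaults (all
overridable via `CohortConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 34 | cohort size |
| `n_forced_internal` / `n_forced_external` / `n_free_trials` | 3 / 3 / 7 | trial design |
| `targets_per_trial` | 7 | targets per trial |
| `acc_fi_mean`, `acc_fi_sd` | 60.3642, 15.54 | internal accuracy (%) |
| `acc_fe_mean`, `acc_fe_sd` | 95.6583, 8.4020 | external accuracy (%) |
| `meta_bias_mean`, `meta_bias_sd` | −3.7482, 5.0 | metacognitive bias (pp) |
| `bias_coupling` | −0.156342 | slope of reminder bias on meta bias |
| `aip_noise_sd` | 1.87962 | residual SD of reminder bias (points) |
| `choice_slope` | 2.0 | logistic steepness of the choice rule (per point) |
| `fa_noise_sd` | 0.50 | residual SD of the FA linear model |

The bias parameters are one linear-Gaussian calibration: with reminder
bias = `bias_coupling·meta_bias + ε`, the defaults give a group reminder
bias of mean 0.586 and SD 2.036 and a reminder↔meta correlation of
−0.384 in expectation. `meta_bias_sd = 5` percentage points is the one
free choice (a mild, realistic miscalibration spread — about a third of
the internal-accuracy SD); the remaining three parameters then follow
algebraically from the targeted moments.

**Accuracy sampling.** Accuracies live on [0, 100] and are drawn from a
truncated normal whose *parent* parameters are solved numerically so the
*realized* (post-truncation) mean and SD equal the configured values.
Near a performance ceiling no truncated normal can deliver the requested
moments — a distribution with mean 95.66 cannot have SD 8.40 within that
family, because one-sided truncation caps the SD at a fraction of the
distance to the bound — so the sampler falls back to a moment-matched
scaled Beta (here Beta(4.67, 0.21)·100), which reproduces the moments
exactly and has the ceiling-spike-plus-left-tail shape that near-perfect
task performance actually shows. The moment-matching is what lets
moment-recovery tests run at 3-Monte-Carlo-SE tightness.

**Choice rule.** Free-trial choices are Bernoulli with
`P(external|v) = logistic(choice_slope·(v − AIP))`, target values drawn
uniformly with replacement from {2..8}. The logistic link differs from
the probit used in fitting; at these slopes the two are nearly
indistinguishable and the 50% crossing — the quantity of interest — is
identical by construction.

**FA generation.** Each tract's FA is a standardized linear effect of one
behavioral index (defaults follow the magnitudes typical of
small-to-moderate brain–behavior effects, −0.32 to −0.44 on the bias
indices, zero for the uncinate) plus age/TIV slopes of 0.10, a 0.10
gender offset and N(0, 0.50) noise, mapped into (0, 1) by the fixed
affine transform 0.5 + 0.06·raw. The map's parameters are irrelevant
downstream because the regression standardizes its outcome; it exists
only so stored FA values look like FA.

**What the generator does not emulate:** within-trial dynamics (colour
fades, circle layout, timing), item-level memory structure,
trial-order/learning effects, non-Gaussian covariate distributions, and
any spatial structure across tracts (tract FAs are conditionally
independent given the behavioral indices). Passing tests therefore show
that the *analysis* recovers what this generative structure puts in —
not that real data satisfy the structure.

**Degenerate subjects are a feature.** At the study-scale design (7 free
trials, steep choices) roughly a quarter to a third of simulated
subjects choose identically on every free trial, exactly as a real
always-offloader would; they enter accuracy/confidence analyses but drop
(as missing AIP) from reminder-bias analyses. Group tests on small
synthetic cohorts therefore run at a smaller effective n than the
nominal cohort size.

## Numerical and procedural choices

* Determinism: one `numpy.random.Generator` seeded from the config
  drives each stage; identical config ⇒ byte-identical CSV/JSON outputs
  (verified in tests). All derived seeds stay below 2³¹.
* Accuracy aggregation pools targets across trials (ratio of sums);
  with a constant target count per trial this equals the mean of
  per-trial percentages.
* Confidence is stored on the percent scale so meta bias is a direct
  subtraction.
* The psychometric optimizer is L-BFGS-B on (AIP, log σ) from the best
  few of 27 grid starts; ties from flat likelihoods are broken as
  described above.
* Bonferroni caps at 1; p-values are reported at full precision and
  rounded only for display.
* Problem sizes in the test suite (e.g. 10⁴-subject moment checks,
  10³-replicate recovery and null-BF simulations, 5×10³-replicate
  type-I calibration, 10³-iteration power runs) are chosen so the full
  suite completes in a few minutes on one CPU while keeping Monte Carlo
  error well inside each assertion's band.

## Known limitations

* The AIP estimator is noisy at 7 trials per subject; it is unbiased on
  average but individual estimates carry ~1-point errors, attenuating
  brain–behavior correlations on synthetic cohorts relative to their
  generating slopes.
* The JZS machinery treats gender as one more column under the common
  g-prior rather than giving factors a separate prior scale; for
  inclusion factors of a continuous predictor the difference is
  negligible (gender is present in both models).
* The 2×2 ANOVA ignores the within-subject structure of the four cell
  scores (see above); its p-values are approximate in that respect.
* Reported one-sided tests presuppose the stated directions; they are
  not robust to sign-flipped hypotheses by design.
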