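# Methods

## Scope and model

`motionbag` quantifies how head motion inflates brain-age-gap (BAG)
estimates. The analysis chain is:

1. **Feature normalization.** Per-feature z-scoring with training-cohort
   mean and sample SD (n−1 denominator). Zero-variance features are
   dropped with a warning at fit time and silently at apply time. Test
   scans are always standardized with training statistics — the anchoring
   is what makes repeated sessions comparable.
2. **PCA.** Thin SVD of the standardized training matrix; loadings are
   column-orthonormal, each column's sign fixed so its largest-magnitude
   entry is positive (signs affect nothing downstream except the
   reproducibility of stored models). Out-of-sample scans are projected
   through the stored loadings.
3. **Age model.** Linear regression of age on the first k scores, with
   optional L1 (lasso) or L2 (ridge) penalty; the intercept is never
   penalized. k\* is chosen by 10-fold cross-validation minimizing mean
   out-of-fold RMSE, with one seeded fold partition shared by every k and
   ties broken toward the smallest k (a numerical tolerance of
   1e−9 relative defines a tie, so noiseless data select the most
   parsimonious k). When a penalty is requested without a strength, an
   inner 5-fold grid search over 20 log-spaced values (1e−4..1e2) picks it
   by RMSE. Folds are plain seeded shuffles; age stratification is not
   applied.
4. **BAG and adjustment.** delta1 = predicted − chronological age. Because
   least-squares predictions regress to the mean age, delta1 correlates
   negatively with age by construction; the adjustment subtracts the OLS
   line of delta1 on age (beta2). Beta2 is fitted by default on the
   training cohort's out-of-fold (delta1, age) pairs — no test structure
   leaks into the adjustment and all three sessions are adjusted
   identically; `beta2_sample="test"` refits on the test sample for
   sensitivity checks (and then delta2 is exactly mean-zero and
   age-orthogonal on the test sample).
5. **Euler normalization.** euler_norm = −ln(−raw + 1), a bijection from
   (−∞, 1) to the reals fixing 0, applied after hemisphere averaging. It
   removes most of the heavy left skew of raw surface Euler numbers.
6. **Mixed models.** Every motion model is a random-intercept LMM fitted
   by REML (statsmodels MixedLM): outcome ∈ {adjusted BAG, normalized
   Euler, single PC score}, predictor ∈ {session (categorical, STAND
   reference, two treatment contrasts), visual rating 0–5 (one continuous
   slope), normalized Euler (continuous)}, grouping = subject. Wald
   t-statistics use residual degrees of freedom (n_obs − n_fixed);
   Satterthwaite correction is not implemented — with hundreds of
   observations the difference is negligible. Two adjusted R² flavours are
   reported: *conditional* (squared correlation of the outcome with fixed +
   predicted random effects, adjusted for the number of fixed slopes) and
   *marginal* (fixed effects only); single-number summaries use the
   conditional one.
7. **Per-component screen.** The session/rating LMM is fitted per PC
   score; Benjamini–Hochberg step-up (level q, default 0.05) is applied
   across components separately within each contrast, and a component
   counts as motion-affected if any of its contrasts survives. The report
   also accumulates the training explained-variance mass of the rejected
   set. The screened panel is the model's k\* components, widened to at
   least 10 so the multiplicity correction is not vacuous when k\* is
   small.
8. **Agreement.** Intra-rater agreement on the 6-point rating scale:
   exact agreement (%) plus linearly weighted Cohen's kappa. When both
   vectors are constant and identical the kappa denominator vanishes and
   the result is flagged undefined rather than numerical.
9. **Within-session protocol.** As a validation variant the age model can
   be trained on a single session of the repeated-session cohort:
   training-session scans receive out-of-fold predictions (fold
   bookkeeping is exposed so the no-self-prediction property is auditable)
   while the other sessions are predicted by a refit on the full training
   session; beta2 is then fitted on the training session's CV pairs.

## Synthetic cohorts

The generator emulates a two-dataset design: a large single-session
training cohort (one scan per subject, ages uniform on 18–50) and a
repeated-session test cohort in which every subject is scanned under
STAND/HM1/HM2 conditions. Features follow a low-rank latent model

    x_ij = mu_j + a_j (Y_i − 34) + sum_l u_il w_lj + bias_j m_is + eps_ij

with orthonormal latent directions w_l, subject random effects
u_il ~ N(0, subject_sd²), iid noise eps ~ N(0, noise_sd²), and a motion
term bias_j = motion_bias · b_j where b is a unit direction whose cosine
with the aging direction is `motion_overlap`. Ages are centered at the
fixed mid-range (34 years) rather than the realized sample mean so the
per-feature slopes are exactly the stored loadings. Training and test
cohorts generated from the same seed share the structural stream
(directions, feature means — the same "population") while subject-level
draws come from disjoint `SeedSequence` streams.

Per-scan latent severities are truncated-normal at zero around the
session means; a session mean of exactly 0 yields exactly-zero severities
(no induced motion), avoiding the half-normal artifact of truncating a
zero-mean Gaussian. Visual ratings are a piecewise-linear map of severity
(slope 1.6 levels per severity unit, Gaussian rating noise, rounded and
clamped to 0–5). The Euler surrogate draws a latent value
`euler_intercept − euler_slope·severity + noise` on the normalized scale
and returns raw = 1 − exp(−latent), the exact inverse of the
normalization, reproducing the left-skewed raw distribution.

### Default conditions and why

| parameter | default | rationale |
|---|---|---|
| n_train | 600 | large single-session training sample at desk scale |
| n_test_subjects | 200 | repeated-session cohort; 3 scans each |
| n_features / n_latent | 100 / 12 | low-rank structure dominated by a handful of directions |
| age_range | 18–50 years | young-adult training window where age effects are roughly linear |
| age_effect_scale | −0.05 units/yr | features decline with age, like grey-matter density |
| subject_sd | 0.25 units | between-subject variability ≈ 5 years of apparent brain age |
| noise_sd | 0.10 units | gives CV-RMSE ≈ 4.6 y, r ≈ 0.86 — a clean but plausible age model |
| motion_bias | −0.05 units/severity | grey-matter underestimation; with overlap 1 this is exactly +1 year of BAG per severity unit |
| motion_overlap | 1.0 | motion mimics aging — the confound of interest; 0 makes it orthogonal |
| severity_means | (0.05, 1.5, 2.5) | ordered sessions with overlapping rating distributions; low motion is clearly detectable at this design size |
| severity_sd | 0.4 | within-session severity spread |
| rating_noise_sd | 0.5 | rater imperfection: severity–rating rank correlation ≈ 0.9, weighted kappa ≈ 0.74 on re-rating |
| euler_intercept / slope / noise | −3.9 / 0.5 / 0.3 | normalized Euler ≈ −3.9 for clean scans, dropping ≈ −0.7 (HM1) and ≈ −1.2 (HM2) |

With these conditions the default experiment yields adjusted-BAG
contrasts of roughly +0.9 (HM1) and +1.7 (HM2) years and a rating slope
of roughly +0.45 years/level — the ordering and rough magnitudes of a
real induced-motion study, produced here by a known injected bias.

### What the generator does not emulate

Features are Gaussian and exactly low-rank plus noise; real morphometric
tables have heavy tails, spatial correlation structure, site effects and
nonlinear age trends. Severity is a scalar; real motion has spatially
heterogeneous effects. Ratings come from a single latent severity rather
than from image appearance. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated — that it recovers known injected
effects and stays null under no bias — not that any particular real
dataset will show effects of these magnitudes.

## Numerical choices

- CV tie-break: smallest k within a 1e−9 relative band of the minimum.
- Unregularized fits use `lstsq` with an explicit rank check; a singular
  design raises an error suggesting regularization.
- MixedLM boundary cases (zero residual or random-intercept variance) can
  make the default optimizer's Hessian singular; the fit falls back to
  derivative-free Powell, and the conditional fitted values collapse to
  the marginal ones when the random-effect covariance is singular.
- BH adjusted p-values are the standard monotone min-over-tail form,
  capped at 1, computed by `statsmodels.multipletests`; a brute-force
  step-up implementation serves as the test oracle.
- Kappa is computed on the full 6×6 table (labels 0..5) even when some
  levels are unobserved.
- All generators and fold splits are pure functions of (config, seed);
  stage seeds are spawned from the root seed via `SeedSequence`.

## Problem sizes

The shipped experiment sizes (600 training scans, 200×3 test scans, 100
features, k searched over 1..20) were chosen so a full experiment runs in
a few seconds and the complete test suite — including 500-replicate
mixed-model calibration and 40 end-to-end experiments — in roughly ten
minutes on one CPU, while keeping every effect estimate several standard
errors away from its detection threshold.

## Known limitations

- Only random intercepts: no random slopes, crossed effects or
  longitudinal terms (the repeated-session design does not need them).
- The rating model treats the 0–5 scale as linear; ordinal models are out
  of scope.
- The regularization-strength search is a plain grid; no warm-started
  path algorithms.
- The within-session protocol reuses the main model's k\* rather than
  re-selecting it per session, trading a small amount of optimality for
  comparability across protocols.
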