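# motionbag

Head motion during structural MRI acquisition systematically biases
morphometry — grey matter appears thinner and sparser in motion-corrupted
scans — and therefore inflates the **brain age gap** (BAG), the difference
between a model's predicted brain age and a person's chronological age.
Because an inflated BAG looks exactly like accelerated brain aging, motion
is a confound for any clinical BAG study: patient groups usually move more
than controls.

`motionbag` is a Python package for quantifying this confound. It
implements a standard PCA + linear-regression brain-age pipeline on tabular
morphometric features (VBM grey-matter density or cortical thickness
values), the age-bias adjustment of the resulting BAG, an Euler-number
image-quality surrogate, and random-intercept mixed-effects models that
measure how much of the adjusted BAG is explained by motion. A seeded
synthetic cohort generator emulates a repeated-session motion design —
each subject scanned three times: still (`STAND`), low induced motion
(`HM1`), high induced motion (`HM2`) — with known ground truth, so every
stage of the pipeline is testable by parameter recovery. The package is
aimed at researchers who run or audit brain-age analyses and want the
motion sensitivity of their estimates quantified.

## The model

Brain age is predicted by linear regression on principal-component scores
of z-scored features (training-cohort statistics only; test scans are
projected, never re-normalized). The number of components k\* minimizes
10-fold cross-validated RMSE; optional L1/L2 regularization is supported.
For a scan with score vector X and chronological age Y:

    delta1 = X * beta1 - Y                      # brain age gap (BAG)
    delta2 = delta1 - (b * Y + a)               # age-bias-adjusted BAG

where (b, a) is the OLS line of delta1 on Y, fitted on the training
cohort's out-of-fold predictions; delta2 has zero mean and zero age
correlation on the sample the line was fitted on.

Image quality is summarized by the surface Euler number (more negative =
worse scan), normalized as

    euler_norm = -ln(-average_euler + 1)

which maps the heavily left-skewed raw values onto an approximately
Gaussian scale.

Motion effects are estimated with random-intercept mixed models over the
repeated sessions,

    delta2     ~ session + (1 | subject)        # STAND is the reference
    delta2     ~ rating  + (1 | subject)        # visual 0-5 motion rating
    delta2     ~ euler_norm + (1 | subject)
    euler_norm ~ session / rating + (1 | subject)
    PC_i       ~ session / rating + (1 | subject)   # per-component screen

with Wald t-tests on residual degrees of freedom, and the per-component
screen corrected with Benjamini–Hochberg FDR. Intra-rater agreement of the
0–5 ratings is reported as exact agreement plus linearly weighted Cohen's
kappa.

## Worked example

One command simulates the default study (600 training subjects aged 18–50,
200 test subjects x 3 sessions, 100 features) and runs the whole analysis:

```bash
motionbag run --seed 1 --out results/demo
```

The printed report (also written to `results/demo/report.md`) begins:

```
- components: k* = 1 (searched 1..20, 10-fold CV)
- training CV: RMSE = 4.623 years, r = 0.864
- age-bias line beta2: slope = -0.2532, intercept = 8.682

### bag_session: delta2 ~ session + (1|subject)

| term | estimate | SE | t | p |
|---|---|---|---|---|
| Intercept | -0.0380 | 0.2806 | -0.14 | 0.892 |
| HM1 | 1.2081 | 0.1539 | 7.85 | 1.97e-14 |
| HM2 | 1.6816 | 0.1539 | 10.92 | 1.89e-25 |
```

Reading: the age model predicts training ages to 4.6 years (r = 0.86) by
cross-validation; relative to the still session, the low-motion session
inflates the adjusted BAG by 1.21 years and the high-motion session by
1.68 years, both far beyond their standard errors — the same individuals
look "older" when they move, purely through the motion corruption of the
features. The rating model in the same run gives 0.46 years of inflation
per visual rating level, and the Euler model 1.21 years per unit drop in
normalized Euler number, so a cheap automated quality index captures the
same confound as expert ratings.

The generator's ground truth for these conditions is 1 year of inflation
per unit latent severity, with session severity means (0.05, 1.5, 2.5) —
the fitted contrasts recover the induced ordering STAND < HM1 < HM2.

Individual stages are available as `motionbag
{simulate,train,predict,lmm,pc-tests,agreement}` and as plain library
functions (`motionbag.run_experiment` returns everything in memory).

## What it does not do

No image processing: the pipeline starts at tabular features (the VBM /
FreeSurfer steps that produce them are upstream). No BIDS ingestion, no
motion-artifact physics, and no nonlinear regressor zoo — the age model is
deliberately the interpretable PCA + linear regression standard, with a
pluggable regularization choice.
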