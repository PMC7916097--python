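# Methods

## Model

Toxicity is binary per patient (DLT yes/no) and the per-dose counts are
binomial, so the likelihood of a trial D with dose levels (x_j, t_j, n_j) is

    L(β | D) = ∏_j p(x_j)^{t_j} (1 − p(x_j))^{n_j − t_j},
    logit p(x) = β₀ + exp(β₁) · log(x / x_r).

The exponentiated slope keeps the dose–toxicity curve monotone increasing —
the standard assumption for cytotoxic agents — and makes β₁ an unconstrained
log-slope. The reference dose x_r anchors the intercept: β₀ is the log-odds
of toxicity at x = x_r. x_r should sit in the first half of the tested dose
panel; the bundled case studies use 400 (synthetic sets), 1 (Erilubin),
900 (Lapatinib), 200 (Sorafenib), 30 (Ixabepilone), 8 (Edotecarin) and
700 (E7070), in each trial's native units. Units are treated as opaque
labels — only the ratio x/x_r enters the model.

The prior is bivariate normal with mean (logit 0.1, log 1): prior toxicity
probability 0.1 at the reference dose and prior median slope 1. The default
covariance is diag(4, 4), a weakly informative choice whose marginal 95%
intervals span roughly (0.002, 0.87) for p(x_r) and (0.02, 50) for the
slope. The covariance is fully configurable; the test suite also runs
diag(4, 0.04) (slope pinned near 1) as a sensitivity setting, which
substantially shrinks all posterior-based distances — indicator values
should always be reported together with the prior that produced them.

## Precision matching

Two trials of different size produce likelihoods of different sharpness,
and any density distance would partly measure sample size rather than
disagreement. Before comparison the larger trial's likelihood is raised to
min(1, n_other/n): the bigger trial is flattened to roughly the precision
of the smaller, and at least one exponent is exactly 1. The exponents are
recorded in every report.

## The five indicators

* `d`: Hellinger distance between the two weighted likelihoods, each
  normalised over a compact support (equivalently, posteriors under a flat
  prior on that support). Default support β₀ ∈ [−10, 10], β₁ ∈ [−5, 5];
  the choice matters for weakly informative trials, since it decides how
  much prior-dominated volume the normalised likelihood spreads over, and
  it is configurable for exactly that reason.
* `dmod`: the same Hellinger kernel on the two proper-prior posteriors.
  One shared prior is applied to both trials — two different priors would
  make the distance partly a prior comparison.
* `dmtd`: the two posteriors of x** = log(x*/x_r) are estimated by Monte
  Carlo (draws from each grid posterior, mapped through the MTD formula),
  truncated, KDE-smoothed, re-evaluated on the union of their supports,
  renormalised, and compared with the same Hellinger kernel. This is a
  one-dimensional summary: two curves can differ (large d, dmod) while
  implying similar MTDs (small dmtd/dp measures), and that distinction is
  the point of reporting both levels.
* `dp1`, `dp2`: exp|Δ| − 1 applied to the medians (dp1) and KDE modes (dp2)
  of the truncated x** posteriors. Working on the log-ratio scale rather
  than the raw MTD scale avoids the severe overdispersion of
  x* = x_r·e^{x**} under heavy-tailed posteriors (the raw-scale mode is
  numerically meaningless for weakly informative trials). Both are
  invariant to a common change of reference dose, which only shifts both
  x** distributions by the same constant. dp2 is the more reliable of the
  two: the median (dp1) reacts strongly to unbalanced heavy tails, as the
  Lapatinib and Sorafenib case studies show.

## Numerical realisation

* **Posterior representation.** Dense deterministic 400×400 grid per trial;
  all likelihood work in log space with log-sigmoid forms, normalised by
  the trapezoid rule. With two parameters this is exact to quadrature error
  and removes sampler tuning entirely. Grid bounds default to prior mean
  ± 6 prior sd per axis, widened ×1.5 until < 10⁻⁶ of the mass sits on the
  boundary rows/columns; within one comparison both trials share one grid
  (union of their bounds) so densities subtract pointwise.
* **Monte Carlo.** 10⁵ draws per trial by sampling grid nodes proportional
  to quadrature mass with uniform within-cell jitter. Seeds derive from
  SeedSequence([seed, fingerprint(counts)]), so every indicator is exactly
  invariant to argument order and self-comparison reuses the identical
  stream. Default seed 20210209.
* **Truncation.** x** draws outside the empirical 10th/90th percentiles
  (linear-interpolation quantiles) are discarded — retaining 80% ± 1
  draw — before any density estimation. This trades 20% of the information
  for stability of the KDE and of the point estimates under the extreme
  tails that arise when a trial barely identifies its slope.
* **KDE.** Gaussian kernel with Silverman's rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^{−1/5} on the retained draws (the IQR
  robustification is essential: a plain-sd bandwidth oversmooths the
  right-skewed MTD posteriors and biases the mode outward), evaluated on a
  1024-point grid spanning the truncation bounds padded by 3 bandwidths,
  then renormalised to integrate to 1. A degenerate (all-equal) sample
  yields a flagged point mass rather than an error.
* **Hellinger kernel.** H² = ½Σw(√p−√q)² with trapezoid weights; inputs are
  validated to integrate to 1 within 10⁻³ and the result is clipped to
  [0, 1] against rounding. Discretised Gaussians reproduce the closed form
  sqrt(1 − exp(−Δμ²/8)) to 10⁻³ at 1024 grid points.
* **Rounding** to two decimals happens only at presentation; reports store
  full precision.

## Bundled data and the synthetic calibration sets

The three synthetic Japanese sets were constructed against one fixed
24-patient Caucasian trial to span the similarity range: synthetic-1 shares
curve and MTD (600), synthetic-2 shares the MTD but has a steeper curve,
synthetic-3 differs in both (MTD 200). They are calibration points for
interpreting the indicators, not simulations of trial conduct: the package
compares completed count tables and deliberately models nothing about the
sequential dose-escalation process that generated them, inter-patient
covariates, or late-onset toxicities. Agreement on these sets therefore
shows the indicators rank curve/MTD disagreement correctly at realistic
Phase I sample sizes (12–30 patients/arm); it does not validate any
particular escalation design. The literature case studies are per-dose
aggregates transcribed from published trials; the Edotecarin Japanese
top-dose cell is garbled in the source table ("2/62/6") and is stored as
2/6, with an `edotecarin_alt` variant (4/12, two merged cohorts) bundled
for sensitivity. Declared MTDs from the source trials are stored as
annotations only and never enter any computation.

`simulate_trial` generates per-dose binomial counts from known (β₀, β₁) for
calibration work; a 200-patient simulated trial recovers both parameters to
within 0.15, confirming the grid posterior is faithful where data are
informative.

## Reproduction of the published nine-pair table

Under the defaults above, seven of the nine bundled pairs reproduce the
published indicator values to within ±0.10 (±0.15 for the synthetic dp1),
and the synthetic ordering (similar < same-MTD < different) is strict for
d, dmod and dmtd. Two pairs resist reproduction at that band: Lapatinib
(our d/dmod/dmtd ≈ 0.37/0.22/0.25 vs 0.58/0.39/0.50) and the Sorafenib dp2
(≈ 1.35 vs 0.75), plus the E7070 flat-support d (0.79 vs 0.63). These are
exactly the heavy-tailed, weakly identified cases: the published analysis
notes both its own Eq.-level computational difficulties for the raw
likelihood distance and the instability of the median-based dp1 there, and
its Monte-Carlo/KDE/support settings are not stated. Our values are stable
across seeds (sd < 0.02 over 10 seeds), and alternative readings of the
ambiguous settings (prior covariance, MAP scale, truncate-then-fit vs
fit-then-truncate) were each checked and either fit worse overall or break
the seven agreeing pairs; the discrepancy is reported rather than tuned
away.

## Problem sizes and defaults

Default settings (grid 400², 10⁵ draws, KDE grid 1024) complete one
comparison in a few seconds and the full nine-pair table in under a minute
on one CPU; tests that only exercise contracts use reduced sizes (grid
150–200², 2–3·10⁴ draws), which the package exposes through
`GridSpec`/`ComparisonConfig` rather than hard-coding.

## Known limitations

* Aggregated counts assume exchangeable patients within dose; no covariates
  or inter-cohort drift.
* The flat-support distance d depends on the chosen compact support, and
  hence is best read comparatively across pairs analysed with one support.
* KDE-mode estimates (dp2) inherit bandwidth sensitivity; for near-flat
  truncated posteriors the mode can sit anywhere in a wide plateau.
* No decision cut-offs are built in: zone boundaries in the gradient
  display are equal thirds of the axes, a reading aid rather than a test.
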