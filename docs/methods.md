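# Methods

This note documents the statistical model behind `eegmediation`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that matter when
reproducing results.

## Study design and variable roles

The package targets a two-arm, two-visit trial: subjects are measured at
baseline and at follow-up, treatment is encoded by a numeric `dose` that
is zero everywhere except for treated subjects at follow-up, and
time-invariant confounders (education in years, disease severity on a
two-level staging scale, age at trial entry) enter every model as fixed
effects.  Group membership itself is never a fixed effect; the dose
contrast carries the treatment information.  By default the dose
contrast is 0/1 (`dose_value = 1`), so fixed-effect estimates read
directly as per-contrast effects; a dose in mg can be used instead by
setting `dose_value`.

## Spectral pipeline

* **Average reference.** Subtracting the channel mean at every sample
  makes the montage reference-free; it is rejected for single-channel
  data where the operation is undefined.
* **Bartlett cross-spectra.** Epochs (default 512 samples at 200 Hz,
  i.e. 2.56 s) are Fourier transformed without a taper and the
  cross-periodograms averaged.  One-sided normalization is chosen so
  that summing a channel's PSD over the full non-negative grid equals
  its mean squared amplitude (Parseval); a cosine of amplitude A on an
  on-grid frequency therefore shows A²/2 in its bin.  Off-grid
  frequencies are rejected with the nearest representable bin named in
  the error.
* **Analysis grid.** The reported band is internally inconsistent in the
  source material (49 bins "from 0.78 to 19.14 Hz" at "0.39 Hz"
  spacing does not close).  The package honours the bin width
  fs/T = 0.390625 Hz and the count 49, using k·fs/T for k = 2..50
  (0.78125–19.53125 Hz).  The grid is configurable.
* **Global Scale Factor.** Non-neural power scaling (skull thickness,
  impedance, amplifier gain) multiplies all spectra of a recording by a
  subject-level constant.  The package removes it as the grand mean of
  the log₁₀ spectra over all rows and bins — equivalent to dividing
  power by its geometric mean — which is exactly invertible via the
  stored `gsf`.  Whether the original software centred per channel or
  per recording is not documented; grand-mean centring was chosen and is
  the natural target for a multiplicative subject-level factor.
  Sensitivity to per-channel centring is untested.
* **Inverse projection.** Source localization itself is out of scope; a
  caller-supplied linear operator K (sources × channels) is applied as
  source PSD(f) = diag(K S(f) Kᵀ), a quadratic form on a Hermitian PSD
  matrix and hence real and non-negative.  Before the log transform,
  power is floored at 1e-12 × the matrix maximum so the log stays finite
  without distorting the scale.
* **EDF ingestion is not implemented.**  Epoch sets are exchanged as a
  .npy matrix plus JSON sidecar (fs, channel labels, epoch length);
  BIDS-style stems are accepted.  No EDF writer was available to
  round-trip-test a reader, so the matrix container is the supported
  input format.

## Whitening CCA

Both blocks are column-standardized (the cognitive scores have ranges
from 15 to 144 points, so correlation scale is the only sensible one).
Each block's correlation matrix is shrunk toward the identity,
R_λ = (1−λ)R + λI, with λ estimated by the Schäfer–Strimmer analytic
formula λ* = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r²_ij.  Both sums are computed
from the n×n Gram matrix, so p ~ 10⁴ never requires a p×p matrix; the
same identity powers the inverse square root R_λ^{-1/2} through the
economy SVD of the standardized data.

The decomposition is the SVD of K = R_x^{-1/2} R_xy R_y^{-1/2}, with the
cross block of the *joint* shrunken correlation matrix scaled by
√((1−λ_x)(1−λ_y)).  That scaling keeps the implied joint matrix positive
semidefinite, hence every canonical correlation obeys |ρ| ≤ 1; it is
applied to the singular values after the SVD so the canonical
*directions* remain well defined even in the full-shrinkage limit.
Signs are fixed so that each component's loading sum is positive on both
blocks; the association's sign then lives in ρ (signed canonical
correlations), which is how a negative brain–cognition association can
be represented.  Components are ordered by decreasing |ρ|, ties broken
by first occurrence.  Latent scores are standardized to unit variance on
the fitting data, and the stored centres/scales make out-of-sample
application deterministic.

**In-sample overfitting.**  With p ≫ n the whitened features span the
sample space, so the *in-sample* correlation of a score pair approaches
1 for any target — even for independent blocks — whenever shrinkage is
weak.  The model therefore records two quantities: `rho` (the shrunken
canonical correlations) and `score_corr` (the raw in-sample score
correlations).  A high in-sample correlation is not evidence of
generalization, and a mediation analysis run on such an in-sample latent
absorbs part of the direct path into the mediated one (the first
spectra variate partially reproduces the cognitive variate, including
its dose-driven variance).  The test suite demonstrates both effects.
Consequences: (i) the latent extraction is best interpreted as a
descriptive compression, exactly as in the motivating analysis;
(ii) unbiased mediation decompositions in the package's validation use
the generative latent variables, where the estimand is unambiguous.

Open choices made here: columns are standardized before whitening (not
stated in the source analysis), and both visits of a subject enter the
CCA as separate rows with no within-subject decorrelation (matching the
repeated-measures use downstream).

## Mixed models

The only random effect is a subject intercept — appropriate for two
visits per subject and what the design identifies.  For the variance
ratio γ = σ²ᵤ/σ²ₑ the GLS estimate, the profiled (restricted) likelihood
and log|V| have closed forms via the Woodbury identity per subject, so
fitting reduces to a 1-D bounded minimization over log γ (tolerance
1e-10, bounds e^±15-ish, with the γ = 0 boundary checked explicitly).
This is deliberately simple and robust at n ≈ 25 subjects, and it makes
the thousands of refits inside power simulation cheap.  REML is used for
reported fits; power-simulation refits use ML.

P-values are Wald-z by default; a Satterthwaite-style option computes
per-coefficient degrees of freedom from the numeric curvature of the
REML surface in (σ²ᵤ, σ²ₑ).  Wald-z is mildly anti-conservative at small
n — the type-I-error calibration test brackets it at 3–8% for a nominal
5% — and the two modes are both exposed because the original analysis
does not name its method.  Severity enters as a numeric covariate (the
published coefficient tables show a single severity row), and education
as numeric years.

## Mediation and power

For linear models the counterfactual decomposition reduces to products
of coefficients: per parameter draw, ACME = a·b·Δ, ADE = c′·Δ,
total = ACME + ADE (additivity is exact per draw), and the proportion
mediated is the per-draw ratio.  Draws are taken independently from
N(β̂, V̂(β̂)) of the two fitted models — quasi-Bayesian in the sense that
random effects are integrated out and only fixed-effect uncertainty is
propagated.  Point estimates are means over draws; intervals are 2.5/97.5
percentiles; the two-sided Monte-Carlo p-value 2·min(P̂(>0), P̂(<0)) is
floored at 2/n_sims and then reported as "< 2/n_sims".  Draws with a
zero total are excluded from the ratio with their count reported, and
the ratio-of-means ACME/total is kept as a diagnostic; when the total
effect's CI includes zero the ratio is unstable and the package warns.
The ratio's heavy tails at small n are a real feature of the estimand,
not a bug: with 25 subjects the mediator-path estimate has a standard
error of ≈0.29 under the default noise levels, and the proportion
mediated inherits a standard deviation of roughly 0.12–0.15.

Power for a coefficient is estimated unconditionally: responses are
regenerated from the fitted fixed effects with *fresh* subject
intercepts and residuals, the model is refit by ML, and rejections at
level α are counted; refit failures are excluded from the trials and
reported.  The binomial CI is the exact Clopper–Pearson interval
(beta-quantile bounds), which reproduces published all-success intervals
such as 100·0.025^(1/100) = 96.38 for 100/100.

## Baseline comparisons and screening

Categorical baseline rows use the Pearson chi-square without continuity
correction — this choice reproduces all three published categorical
p-values (0.18, 0.26, 0.5) to the printed precision, so it is the
default; Yates' correction is a flag.  Continuous rows use Welch's
t-test; from the printed age summaries it gives p ≈ 0.14, not the
published 0.16, and no standard two-sample test reproduces that value
from the summaries — the discrepancy is documented rather than forced.

The battery screening runs a paired t-test of follow-up minus baseline
per variable and controls the FDR across variables by Benjamini–
Hochberg at q = 0.05.  The published selection rule is ambiguous about
the role of the two groups; the default selects variables passing FDR in
the treated group, with `either` and `treated_not_control` as
alternatives.

## Synthetic generator: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis
assumes: a mediator latent driven by dose and confounders with a subject
intercept, an outcome latent driven by the mediator, dose and
confounders, six cognitive scores loading on the outcome latent
(default loadings 0.26, 0.22, 0.24, 0.22, 0.20, 0.21 — the published
roughly-equal pattern), and a spectra block loading on the mediator
latent.  Defaults: 15 treated / 10 placebo subjects, dose contrast 1,
path coefficients a = 0.496, b = 3.840, c′ = 0.987 (the published fitted
values, giving closed-form proportion mediated 0.659), subject-intercept
SD 0.5, residual SDs 0.5, confounder effects matching the published
coefficient tables, age ~ U[40, 70], education ~ U[6, 20] years,
severity ∈ {1, 2} with 80% stage II (the published demographics),
spectra of 200 sources × 49 bins (a desk-scale stand-in for 3,244
sources), observation-noise SDs 0.2 (scores) and 0.5 (spectra columns),
and a fixed mixed-sign loading pattern over sources × frequencies.  The
within-subject correlation of repeated measures is not reported for the
real data, so `sd_subject` is a free parameter, not an estimate.

Draw order is fixed (confounders, intercepts, latent residuals, score
noise, then spectra noise last), so a seed fully determines the bundle
and the cohort is bit-identical whether or not the spectra block is
generated.

It does **not** emulate realistic Parkinsonian electrophysiology — no
spectral slowing, no 1/f shape, no channel covariance structure, no
artifacts — and the raw-EEG emulator is only a monotone mapping from the
mediator latent to narrow-band sinusoid power on a white-noise floor,
documented so expected spectra are computable analytically.  Passing
tests therefore validate the statistical machinery, not any claim about
real EEG.

## Validation problem sizes

The suite exercises the trial scale the design targets: 25 subjects × 2
visits for recovery at the default seed, 500 subjects for the tight
(±0.02) recovery check, 500 replicates of 100-subject trials for ACME
interval calibration (observed coverage ≈95%), 1000 null fits for Wald
calibration, and 400 simulations for power type-I error.  These sizes
keep the whole suite under a few minutes on one core while leaving the
Monte-Carlo error well inside the asserted brackets.

## Known limitations

* The in-sample CCA latent is not a consistent estimate of the
  generative mediator when p ≫ n (see above); cross-validated or sparse
  variants are out of scope.
* Sequential ignorability — no unmeasured confounding of the
  mediator–outcome relation — is assumed, not tested; no sensitivity
  analysis is provided.
* One mediator, linear Gaussian models, random intercepts only.
* The Satterthwaite option relies on finite-difference curvature and can
  be fragile when the subject variance sits on the boundary.
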