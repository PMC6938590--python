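# Methods

## Outcome model

The outcome is a non-negative integer count (grams of alcohol consumed per
week at follow-up). Counts of this kind are strongly over-dispersed —
the calibration moments (mean 120.8, SD 86.4 g/week) give a variance some
60 times the mean — so the model is the mean–dispersion negative binomial
(NB2) with a log link:

    y_i ~ NB2(mu_i, phi),   log mu_i = x_i' beta,
    Var(y_i) = mu_i + mu_i^2 / phi.

`phi > 0` is the dispersion; NB2 approaches Poisson as `phi → ∞`. The log
pmf is evaluated through log-gamma functions only; no probability is ever
formed by multiplying per-observation terms, so large counts cannot
overflow. `dispersion_from_moments(mean, sd) = mean^2/(sd^2 − mean)`
inverts the variance relation for calibration and fails loudly when the
data are not over-dispersed (`sd^2 ≤ mean`), where no NB2 exists.

The linear predictor contains an intercept, the arm indicator (1 =
intervention, so `IRR = exp(beta_GROUP) < 1` favors intervention), sex, age
in years, university site and the baseline weekly frequency of heavy
episodic drinking (HED). Age and HED enter untransformed as numerics; sex,
university and arm are one-hot encoded with the lexicographically first
level dropped as reference and the intercept kept, which keeps a generic
design at full column rank. One-hot-encoding a continuous covariate such
as age would explode the design for no inferential gain, which is why the
encoder draws the numeric/categorical line where it does; the split is
configurable per call.

## Estimation

**Maximum likelihood.** The likelihood is maximized jointly over
`(beta, log phi)` with L-BFGS-B and analytic gradients
(`dL/d eta = y − (y+phi) mu/(mu+phi)`; the `log phi` gradient uses
digammas). The covariance is the inverse observed information, obtained by
central finite differences of the analytic gradient at the optimum
(step `1e-5·max(1,|theta|)`). A fit is flagged non-converged when the
optimizer fails and the scaled gradient norm stays above `1e-3·n`;
downstream inference refuses flagged fits. Rank-deficient designs (e.g. a
single-arm dataset, whose GROUP column is constant) raise immediately
rather than producing an unstable fit. Wald inference is the default
(`exp(theta ± 1.96·SE)`, two-tailed normal P): a symmetric-on-the-log-scale
interval of exactly this form is what standard negative binomial
regression output reports. Likelihood-ratio inference was considered and
left out of scope; the choice is documented rather than switchable because
the Wald path is the only one the report formats consume.

**Bayesian.** Priors are improper uniform on every coefficient and on
`phi` over the positive reals, so the log posterior equals the log
likelihood on the support and `−inf` off it. Optional finite bounds exist
because improper priors can yield improper posteriors on degenerate
designs; they are off by default and none of the shipped analyses need
them. The sampler is adaptive random-walk Metropolis:

* `phi` is sampled as `log phi` with the `+log phi` Jacobian, so support
  violations cannot occur and every stored draw has `phi > 0`;
* during warmup the global proposal scale adapts toward the 0.234
  random-walk optimum by Robbins–Monro (`gain = t^-0.6`), and — when no
  proposal covariance is supplied — the proposal covariance itself is
  learned from the chain history (Haario-style, `2.38^2/d` scaling, small
  diagonal jitter); after warmup everything is frozen so the retained
  draws form a genuine Markov chain;
* when a proposal covariance **is** supplied (the pipeline passes the
  observed-information covariance of the MLE), its shape is trusted and
  frozen and only the scale adapts. Re-learning the shape from a short
  warmup history was measurably worse: the early history covariance
  collapses and the chain crawls.

Default chain layout is 4 chains × 2,000 iterations with 1,000 warmup
(the "desk scale" used throughout the tests); larger runs, e.g.
4 × 50,000 with 25,000 warmup, are a settings change. Reports always state
the pooled draw count explicitly, since "total draws" is otherwise
ambiguous between per-chain and pooled counts.

Chains initialize at the engine default (coefficients 0, dispersion 1)
jittered per chain, but the pipeline initializes at the MLE with the
observed-information proposal: a 1,000-iteration warmup cannot both absorb
a burn-in from the origin (the intercept alone must travel ~5 units) and
adapt the proposal. Initializing a flat-prior posterior at its own mode
biases nothing and is standard practice.

Convergence is assessed with split-R̂ and effective sample size (via
ArviZ) plus exported trace plots; the verdict is "converged" only when
every R̂ < 1.01. At desk scale on the full 14-parameter model the verdict
is typically "suspect" (R̂ ≈ 1.02–1.15, pooled ESS ≈ 100): random-walk
Metropolis pays a factor-of-dimension penalty in mixing, and the
threshold probabilities it supports are accurate to a few percentage
points, which is the resolution at which they are interpreted. The
verdict and maximum R̂ ride along in every report so a reader can judge.
Single chains and zero-variance chains yield "suspect" with an
explanation instead of a number.

Posterior evidence is summarized as `P(IRR < t)` for strictly decreasing
thresholds, default `(1, 0.96, 0.92)`: direction of effect, then two
magnitude markers. Counting is strict `<`; ties (measure-zero for
continuous draws) count as not-below. Percentages are reported to one
decimal with raw counts carried alongside, so rounding loses nothing.
Histograms use 50 equal-width bins over the central 99.9% of the draws.
Posterior quantiles are exported as supplementary output only; no
credible-interval decision rule is layered on top of the threshold
probabilities.

## Synthetic trials

`simulate_trial` emulates the data-generating process the analysis
assumes: covariates drawn independently per participant, the NB2 outcome
drawn as a gamma–Poisson mixture from the linear predictor, per-arm
Bernoulli follow-up (missing at random by construction — attrition is
independent of the outcome given arm), and contamination that replaces a
completer's outcome with a uniform integer draw from an extreme range,
emulating data-entry errors or malicious entries without changing `n`.
Four RNG streams (covariates, outcomes, attrition, contamination) spawn
from one master seed, so toggling contamination perturbs nothing else;
identical configs give byte-identical datasets.

`default_study_config` encodes the study conditions: 825/780 randomized
(intervention/control), follow-up probabilities 0.490/0.678, true IRR
0.937, dispersion `phi = 120.8^2/(86.4^2 − 120.8) ≈ 1.99`, and
contamination probability 3/933 with range 1044–1524 g/week, yielding ~3
extreme completers per trial. The intercept is solved analytically so the
control-arm *marginal* mean hits 120.8 g/week after integrating the
covariate effects out (each covariate's `E[exp(effect)]` has a closed
form for the default laws).

No covariate summary was ever published for the motivating trial, so the
covariate laws are invented defaults chosen to look like a Swedish
university population: age uniform on 19–35, sexes balanced, nine
university sites uniform, HED on a half-episode grid `{0.5, 1, …, 7}`
with geometric-like decay (ratio 0.65, mean ≈ 1.4 episodes/week).
Covariate effects default to small values (|effect| ≤ 0.05 on the log
scale) so the marginal SD stays near the 86.4 g/week target despite
covariate mixing. Everything is configurable and serializes to JSON.

What passing tests on this generator do *not* show: robustness to
informative dropout (attrition here is MAR by construction, as the
complete-case analysis assumes), to misspecified dispersion (outcomes are
exactly NB2), or to reporting artifacts in real self-report data (heaping
at round numbers, recall bias). The contamination channel is the only
deliberate misspecification.

## Outliers and the paired report

The published analyses identified outliers graphically from Q-Q plots; a
reproducible artifact needs a rule, so the default rule is the verbal
criterion the graphical check supported: consumption strictly above 80
standard drinks per week at 12 g of alcohol per drink (960 g/week).
A value of exactly 960 is not flagged. A manual-id mode reproduces
arbitrary judgments, and a Q-Q plot (against moment-matched NB2 quantiles
by default, normal quantiles on request — the right reference family for
a skewness check on counts is itself a judgment call) preserves the visual
step.

`run_full_analysis` always computes both the primary and the
outlier-excluded analysis and labels the latter "post hoc" in the report;
the exclusion is presented as a fragility probe, never as the headline
result. The sensitivity pass reuses the same settings with a distinct
derived seed (`seed + 1`). Reports serialize to JSON losslessly and
contain the attrition block, both variants (frequentist + posterior),
the flagged ids and values, diagnostics verdicts, the config digest and
the master seed; per-stage timings go to stderr logging so same-seed runs
serialize byte-identically.

## Numerical and testing choices

* Linear predictors above 500 short-circuit the likelihood to `−inf`
  (exp would overflow); interior optima are far from this guard.
* The MLE starts from `beta = 0` with the intercept-like column set to
  `log(mean y)`; the problem is smooth and unimodal in practice and the
  start only affects iteration count.
* Oracles: the log pmf is cross-checked against an independent
  parameterization (`nbinom(phi, phi/(phi+mu))`), the MLE against a
  refined dense grid search and against an independent regression
  implementation, the sampler against closed-form targets (normal, gamma
  via log-transform, correlated bivariate normal) and against 2-D grid
  quadrature of an intercept-only posterior, with agreement required
  within 3 Monte-Carlo standard errors.
* Study-scale simulation tests use 10 seeded replicates at the full trial
  size for parameter recovery, and 200 seeded replicates at 200/arm for
  null calibration of the Wald test (target band [0.01, 0.09], the 99%
  binomial band around 0.05 at 200 replicates). Law-of-large-numbers
  checks use 50,000–60,000 participants per arm. These sizes make the
  whole suite a desk-scale run while keeping Monte-Carlo noise well below
  the tolerances tested.

## Known limitations

* Random-walk Metropolis mixes slowly in ≥10 dimensions; paper-scale
  chain lengths (or fewer covariates) are needed for R̂ < 1.01 on the
  full model. No NUTS-style adaptation, tempering or parallel execution
  is provided.
* No zero-inflation, hurdle or random-effects extensions; no
  likelihood-ratio or robust (sandwich) inference; no small-sample
  corrections.
* Missingness is handled by complete cases under MAR only — no multiple
  imputation or sensitivity to informative dropout.
* The published intervention-arm completer counts disagree between
  sources (402 analyzed vs 404 followed up); the package takes "analyzed"
  to mean rows with a valid outcome and surfaces whatever counts the data
  actually contain rather than reconciling the discrepancy.
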