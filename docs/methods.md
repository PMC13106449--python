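# Methods

## The estimation problem

A two-phase prevalence survey screens a stratified sample of children with a
39-item questionnaire (total score 0–39; screening-positive at a cutoff,
default ≥ 11) and offers gold-standard diagnostic confirmation to
screen-positives only. Three design features make the naive positive
fraction a poor prevalence estimate: diagnostic-phase participation is
voluntary and correlated with symptom severity; the confirmed diagnosis is
itself an error-prone measurement with sensitivity Se and specificity Sp;
and the strata (low-risk mainstream schools LR, elevated-risk special
education ER, high-risk resource classes HR) are sampled at very different
fractions of their populations. The package estimates prevalence under all
three corrections simultaneously.

## Latent-status model

Among screen-positive children, true case status z_i is latent:

- priors: beta_0, beta_1 ~ Normal(0, 2.5^2) on the centred-covariate scale;
- latent risk: z_i ~ Bernoulli(p_i), logit(p_i) = beta_0 + beta_1 x_i, where
  x_i is the screening score centred at the screen-positive sample mean
  (centring improves Metropolis mixing; coefficients are reported on both
  scales via `PosteriorDraws.beta_uncentered`);
- measurement, participants only: y_i | z_i ~ Bernoulli(z_i Se + (1-z_i)(1-Sp)).

Non-participants carry no measurement term; their z_i is the
prior-predictive Bernoulli(p_i). Because the score drives both latent risk
and participation, conditioning on it makes the missing diagnoses ignorable
(missing at random given x): this is the model's participation-bias
adjustment, and the reason no inverse-probability weighting is applied on
the primary path (an IPW-style crude pooled estimate is available as
`pooled_crude_prevalence`, flagged as a cross-check interpretation).

The covariate set is configurable: the default is the score alone; a male
indicator and grade can be added (an intercept-only model gives the
closed-form limit below). Se/Sp enter either as fixed values — primary
analysis 0.85 / 0.75, with Se + Sp > 1 enforced, since an uninformative test
leaves prevalence unidentified — or as uncertain parameters with Beta priors
(probabilistic sensitivity analysis; defaults Beta(85, 15) and Beta(60, 40),
prior means 0.85 and 0.60).

## Sampler

A partially collapsed Gibbs scheme, per sweep:

1. **beta** — adaptive random-walk Metropolis targeting the observed-data
   posterior: participants contribute P(y_i = 1 | beta) = p_i Se +
   (1 - p_i)(1 - Sp) with z marginalised out. Four proposals per sweep; the
   proposal is a scalar step times a Cholesky factor of the chain's own
   burn-in covariance (updated every 200 burn-in sweeps from the
   post-transient half; scalar step tuned toward ~30% acceptance every 50
   sweeps). All adaptation is confined to burn-in, so the kept draws come
   from a fixed kernel.
2. **z** — full conditional: for participants
   P(z=1 | y, beta, Se, Sp) ∝ p_i [y Se + (1-y)(1-Se)]; for non-participants
   Bernoulli(p_i).
3. **Se, Sp** (Beta-prior mode) — conditional on z the measurement likelihood
   factors into Bernoulli counts among z=1 and z=0 participants, so both get
   exact conjugate Beta updates. (A Metropolis step on the logit scale would
   also be valid; conjugacy is available here and mixes better.)

Marginalising z out of step 1 and redrawing it in step 2 preserves the joint
posterior and removes the imputation feedback that makes plain data
augmentation mix very slowly when ~75% of diagnoses are missing; with it,
bulk ESS is typically 30–50% of the kept draws. Chains start overdispersed
(prior mean + 0.25 jitter; Se/Sp from their priors). Every chain's stream
derives from a single seed via `SeedSequence` spawn keys (fixed stage table
in `_rng.py`), so runs are bit-reproducible and across-seed variation of the
overall median is well under 0.5 per 1,000 at the default settings
(3 chains, 5,000 burn-in, 10,000 kept draws — the settings used for real
analyses; tests use shorter chains).

## Prevalence, post-stratification, reporting

Per kept draw, the stratum case count is the sum of the *sampled* latent
indicators z_i over screen-positive children (screen-negatives count zero
cases), divided by all screened children in the stratum; the overall draw is
the population-size-weighted mean, sum_s N_s prev_s / sum_s N_s — an exact
convex-combination identity per draw. Using sampled indicators rather than
their conditional means makes the credible interval track the posterior of
the realised finite-sample case count, which is the quantity the coverage
studies check; Rao–Blackwellised per-child probabilities (conditional means
averaged over draws) are kept for per-child reporting
(`posterior_case_probabilities`, `predict_proba`). Results are summarised as
the posterior median with the equal-tailed 2.5–97.5% interval, per 1,000 by
default.

Screen-negative children contribute zero cases on the primary path, so the
estimand is the *screen-detectable* prevalence. An optional
`screening_sensitivity` argument to `post_stratify` divides stratum case
totals by an assumed screening-phase sensitivity as an explicit
false-negative correction; it is off by default because that sensitivity is
not estimable from a design that never verifies screen-negatives.

Sex/grade breakdowns post-stratify within subgroups using proportional
allocation of stratum population sizes (N_{s,g} = N_s n_{s,g} / n_s), which
makes subgroup estimates combine back to the overall estimate exactly per
draw; the adjusted sex ratio is the posterior median (with interval) of the
per-draw male/female rate ratio.

## Sensitivity analyses

- **Deterministic grid**: one full refit per (Se, Sp) cell; default 4×4 grid
  over Se ∈ {0.80, 0.85, 0.90, 0.95} × Sp ∈ {0.65, 0.70, 0.75, 0.80} (16
  cells, all satisfying Se + Sp > 1). Each cell derives its seed from the
  primary seed plus the cell index, so cells differ only through the Se/Sp
  assumption. In the intercept-only limit, cell medians track the
  Rogan–Gladen correction's direction, which the tests exploit as an
  ordering oracle.
- **Probabilistic**: the Beta-prior mode above; with no participant data the
  Se/Sp posteriors provably equal their priors, and point-mass-like priors
  reproduce the corresponding fixed-value fit — both are tested.
- **HR capping**: per draw, the HR stratum prevalence is replaced by
  min(value, cap) before post-stratification, for caps 1.00/0.95/0.90/0.85;
  capped overall estimates are monotone non-increasing in the cap by
  construction.

## Convergence diagnostics

Rank-normalised split R-hat and bulk ESS (Geyer initial-monotone truncation)
as implemented by arviz, wrapped so that degenerate (zero-variance)
parameters are flagged with NaN and a reason instead of crashing. Report
thresholds: warn above R-hat 1.01, fail above 1.05, warn when ESS < 400 —
modern defaults, stricter than the bare "R-hat near 1" convention. Trace and
density plots are available behind an explicit call (`plot_traces`), never
on the critical path.

## Synthetic generators: what they emulate, what they do not

`simulate_population` (mixture generator) reproduces the statistical
structure the analysis confronts: three strata with configurable true
prevalences (defaults LR 0.015, ER 0.12, HR 0.95 — the HR stratum is by
construction nearly saturated); class-conditional score distributions as
discretised truncated normals on [0, 39] (non-cases mean 5 SD 3, cases mean
17 SD 5), chosen so that both screen-negative true cases and screen-positive
non-cases occur; screening by cutoff; participation logistic in the score
(intercept −3.2, slope 0.15 per point → roughly 25–35% diagnostic-phase
response, rising with severity); diagnosis as the Se/Sp-corrupted truth. Sex
(51.7% male) and grade (uniform 1–3) are independent decoration used by the
descriptive outputs and null checks. Under this generator the pooled
score-only logistic latent model is *deliberately misspecified* (the true
status-given-score relation is a stratum-dependent mixture posterior), so
single-cohort interval coverage is not a guaranteed property on this path —
it exercises robustness, flow accounting and structure.

`simulate_logistic_cohort` (model-consistent generator) draws latent status
from a logistic in the score (defaults beta_0 = −8, beta_1 = 0.45, with
stratum-specific score distributions), matching the analysis model exactly.
Parameter-recovery and interval-coverage studies use this generator, with
truth defined as the cohort's screen-detectable prevalence (true cases among
screen-positives over all screened, post-stratified) — the estimand of the
primary path.

Neither generator models school-level clustering, sibling structure,
item-level responses, screening-phase non-response mechanisms, or
sex-dependent symptom expression; passing tests therefore demonstrate
correctness of the estimation machinery under the stated assumptions, not
robustness to those real-data features.

## Validation studies and problem sizes

`screenprev.validation` packages the self-checks run by the test suite and
the acceptance script:

- **Closed-form oracle**: single stratum, cutoff 0, full participation,
  intercept-only model on 2,000 children — the posterior median must match
  the Rogan–Gladen correction of the observed positive fraction within
  Monte-Carlo error of the median (MC-SE estimated as 1.253 sd/sqrt(ESS)).
- **Interval coverage**: 100 seeded replicates of the model-consistent
  generator (samples 600/150/50 across LR/ER/HR; ~200 screen-positives) at
  reduced MCMC settings (2 chains, 1,000 burn-in, 2,000 kept draws), checking
  that the 95% CrI covers each replicate's screen-detectable truth at least
  90 times. Coefficient CrIs are checked the same way at a larger size
  (~1,500 screen-positives), where posterior normality is adequate.
- **Slope recovery, diagnostic calibration, identities**: participation
  slope within 3 SE at n = 2,000; R-hat within [0.99, 1.01] and ESS within
  10% of n on i.i.d. chains; exact per-draw post-stratification identity;
  cap monotonicity.

The reduced replicate sizes and chain lengths are the package's choice of a
desk-scale experimental design: large enough that Monte-Carlo noise does not
mask a real defect, small enough to re-run routinely.

## Degenerate inputs and numerical choices

Configuration errors (probabilities outside [0, 1], Se + Sp ≤ 1 in fixed
mode, empty strata, sample larger than population, cutoff off-scale) are
rejected before any computation. A participation fit with a constant outcome
raises; quasi-separation is flagged as non-converged and weight computation
refuses such fits. A latent fit with no screen-positives raises; with no
participants it raises in fixed mode but is allowed in Beta-prior mode,
where posterior = prior is well defined. Measurement probabilities are
clipped away from 0/1 only inside log-likelihoods (1e-300 floor); the
Rogan–Gladen estimate clamps to [0, 1] with an explicit flag. Zero-variance
MCMC parameters yield NaN diagnostics with a reason. The Wald interval on
administrative proportions is the registry-table convention; at boundary
counts it degenerates and the exact Clopper–Pearson interval is substituted
with a flag.

## Known limitations

- The false-negative burden among screen-negatives is not estimable from the
  design; the primary estimand is screen-detectable prevalence, and the
  optional screening-sensitivity correction is assumption-driven.
- The latent model is a working model: on data whose status-given-score
  relation is not logistic (e.g. the mixture generator), estimates carry
  approximation bias that the credible interval does not account for.
- Se/Sp are assumed exchangeable across strata, sexes and grades.
- The probabilistic sensitivity analysis treats Se and Sp as independent a
  priori; correlated two-dimensional priors are not implemented.
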