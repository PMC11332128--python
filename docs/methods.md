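# Methods

## The task and the suspicion model

The package analyses a two-player cards game. Both players see the same
seven-card red/blue set; the computer picks one card independently for
each player (so the pick-colour probability equals that colour's card
fraction); each player reports a colour; reporting blue against a red
report wins one point, equal reports tie. Wins and losses follow the
*reports*, not the truth, so misreporting a red pick as blue is the only
profitable lie. After each trial the assessor rates the partner's
honesty on a 6-point scale (1 = completely dishonest … 6 = completely
honest), which is reverse-coded to suspicion `s = (6 − r)/5 ∈ [0, 1]`.

Suspicion is modelled as a linear function of four trial-level cues:

| cue | definition | range |
|---|---|---|
| `own_lie` | assessor lied on this trial | {0, 1} |
| `signed_ev` | `v(1 − p)`, `v` = reported colour's value (red −1, blue +1), `p` = its card fraction | [−6/7, 6/7] |
| `unsigned_ev` | `1 − p`, surprise regardless of benefit | [1/7, 6/7] |
| `lost` | assessor lost the trial | {0, 1} |

For a 3-blue/4-red set with the partner reporting red,
`signed_ev = −1 − (−1·4/7) = −0.429` and `unsigned_ev = 1 − 4/7 = 0.429`.
By construction `unsigned_ev = |signed_ev|`; the two are nevertheless
separate regressors because their *signs* carry different psychology
(benefit-weighted vs. pure surprise).

## BIC-weighted model averaging

All `2⁴ − 1 = 15` nonempty cue subsets are fitted to suspicion.
At group level each subset is a linear mixed-effects model with fixed
and random intercepts and fixed and random slopes by participant;
random slopes are mutually uncorrelated (one variance component per
cue), which maximises convergence when no correlation structure is
known. Fits use maximum likelihood so BICs are comparable across
fixed-effect structures; statsmodels' MixedLM exposes no BIC, so it is
computed as `−2·llf + k·log n` with `k` = fixed effects +
random-intercept variance + slope variance components + residual
variance. Per-participant and detector fits are ordinary least squares
with an intercept.

Outcome and predictors (binary cues included) are z-scored on the
fitted dataset before fitting — pooled standardization at group level —
so all coefficients are standardized betas. A cue that is constant in
the fitted data (a participant who never lied or never lost) is dropped
from the design and reported as β = 0, SE = 0 (degeneracy convention).

BICs become model probabilities `wᵢ ∝ exp(−½ ΔBICᵢ)` normalised over
the converged lattice. Each cue's averaged estimate is
`β̄ = Σᵢ wᵢ βᵢ` with models omitting the cue contributing 0
(shrinkage-style averaging), and its unconditional standard error is

```
SE = Σᵢ wᵢ √(SEᵢ² + (βᵢ − β̄)²)
```

again with absent models entering at β = 0, SE = 0. The 95% CI is
`β̄ ± 1.96·SE`, and a cue is *non-significant* when the CI rounded to
three decimals contains zero. The unconditional-SE formula is the
standard choice for BIC-weight averaging; whether averaged CIs should
instead be weighted sums of per-model CIs is genuinely open, so the
formula is echoed in the run manifest.

Non-convergence handling: a mixed fit that fails (including boundary
fits with non-finite cue SEs) is refitted with a random intercept only;
if that also fails the model is excluded and the weights renormalised,
with a logged warning. In practice only low-weight small subsets are
affected: their random-slope variance for an omitted strong cue sits on
the boundary.

## The accurate lie detector

The oracle applies the identical 15-model averaging to the pooled
trials of all participants with the ground-truth lie indicator
(0/1) as the outcome and single pooled OLS fits. Its prediction maps
the averaged standardized betas back to the outcome scale,
`score = ȳ + sd(y)·Σ β̄_c·z(cue_c)`, read as an (unclipped) lie
probability. For d′ scoring the score is dichotomised at a threshold,
default 0.5; because no binarisation rule is canonical, the pipeline
emits a 0.3–0.7 threshold sensitivity sweep alongside.

## Signal-detection scoring

Discernment is `d′ = z(H) − z(FA)` with H the hit rate over lie trials
and FA the false-alarm rate over honest trials, after dichotomising
ratings at the scale midpoint (1–3 → lie suspected). Extreme rates are
corrected by replacing 0 with `1/(2N)` and 1 with `1 − 1/(2N)`
(only offending rates touched); a log-linear alternative
(`(count+0.5)/(N+1)`) is switchable and is used automatically for trial
sets missing one ground-truth class, where the half-count rule is
undefined. Overall accuracy is reported as the naive alternative — at a
25% lie base rate an always-"honest" judge already scores 0.75, which
is why d′ is primary.

## Mediation

The stakes design asks whether high stakes raise suspicion *because*
they raise the assessor's own lying. The estimator is linear
product-of-coefficients at trial level: `a` from `own_lied ~ stakes`,
`b` and the direct effect from `suspicion ~ own_lied + stakes`, total
from `suspicion ~ stakes`; `indirect = a·b` and
`total = direct + indirect` holds exactly for nested least squares.
Inference is a participant-level cluster bootstrap (default 5000
resamples; percentile CIs; two-sided p as twice the smaller tail
fraction with add-one smoothing), because trials within a participant
are not exchangeable. A participant-aggregated mode (collapsing to
participant × stakes means) is provided; trial-level is the default.

Cross-participant regressions (d′ on cue sensitivities and covariates;
mean suspicion on lying tendency) are OLS on z-scored complete-case
data with two-tailed p-values at 0.05 and no multiplicity correction.
Group comparisons use Mann-Whitney U (independent) and Wilcoxon
signed-rank with zeros dropped (paired), exact when both samples are
≤ 25 without ties, otherwise a continuity-corrected normal
approximation.

## The synthetic generator

The generator emulates the study conditions so that every stage has a
parameter-recovery surface:

* **Card sets** — blue count uniform on 1..6 (the true ratio
  distribution is not public; the weights are configurable).
* **Senders** — lie on a red pick with probability
  `p_lie_when_red = 0.47` (never on blue), giving ~23.5% lies when red
  is picked half the time, the ecological regime. Style 2 instead
  samples each participant's partner responses stratified: exactly half
  lies (red pick reported blue), half honest. Style 3 uses two 30-trial
  blocks with low/high stakes (counterbalanced order), sender policies
  0.40/0.488 by stakes, and *the same partner responses in both
  blocks*, so partner behaviour is constant across stakes by
  construction.
* **Partner pool** — a seed cohort of 50 senders × 84 trials is
  simulated once per experiment and live trials sample from it,
  mimicking a growing-pool design without modelling batch growth
  (immaterial to the statistics).
* **Assessors** — latent suspicion
  `0.45 + 0.05·own_lie + 0.35·signed_ev + 0.20·unsigned_ev + 0.05·lost
  + ε`, `ε ~ N(0, 0.15)`, on the 0–1 scale, thresholded at
  (0.1, 0.3, 0.5, 0.7, 0.9) onto the 6-point scale — equally spaced at
  the Likert step width, so the staircase has average slope ≈ 1 and
  regression coefficients on the observed scale track the latent
  weights. Between-participant heterogeneity is Gaussian on the
  intercept (SD 0.05) and each cue weight (SD 0.03), giving the mixed
  model's random effects something real to estimate and mirroring the
  reported individual differences. Style 3 sets the own-lie weight to
  0.083 and adds a direct stakes effect of 0.022, so the mediation
  paths are known by construction (a = 0.044 via the policy gap,
  b = 0.083).

Because the generating weights live on the raw suspicion scale while
fits report standardized betas, recovery tests compare against the
*implied standardized estimand*: pooled-OLS standardized coefficients
from one 3000-participant Monte-Carlo cohort, solved by `lstsq`
independently of the statsmodels fitting path.

What the generator does **not** emulate: comprehension/attention-check
behaviour beyond a per-participant failure count, learning or drift
across blocks, skewed lie-tendency distributions (lying probability is
homogeneous within stakes level up to slope noise), response times, and
any questionnaire psychometrics (covariates are arbitrary numeric
columns). Passing tests therefore show the *pipeline* recovers known
generative structure — not that real cohorts satisfy the linear-cue
model. Under these defaults the synthetic cohort is also somewhat more
discerning (mean d′ ≈ 1.2) than a typical human cohort in this
paradigm, because a single shared cue model with modest noise is more
homogeneous than real assessors.

## Numerical choices and degenerate inputs

* Exclusions: rating variance below 1e-6 (raw 1..6 scale) or failing at
  least ⌈n_checks/3⌉ attention checks; both configurable, both logged.
* Mixed fits: lbfgs, ML, maxiter 200; BIC ties need no tie-break
  (weights are continuous).
* Detector training requires both ground-truth classes; all-honest or
  all-lie data raise immediately.
* `fixed-50` mode requires an even per-participant trial count.
* d′ requires at least one lie and one honest trial; callers filter or
  receive the flagged log-linear fallback (detector path only).
* Colour values are a single constant mapping (red = −1, blue = +1) to
  prevent drift between modules.
* All randomness flows from one master seed through named child
  streams (pool / trials / assessor / attention), so the same seed
  reproduces a byte-identical trial table.

## Problem sizes used in the test suite

Unit tests run cohorts of 4–40 participants; the end-to-end checks use
50 replicate cohorts of 100 assessors × 90 trials for group-level
recovery, one 200-participant cohort for the detector comparison (the
paired d′ test needs the extra power at the generator's noise level),
and 100 participants × 60 trials with 1000 bootstrap resamples for
mediation recovery.

One caveat the tests surface deliberately: under the default generator
the assessor's own lying and the partner's lying are *not* exactly
independent — both players lie mostly on red picks, and the shared card
set determines the red-pick probability for both, so a small true
partial association (~0.01 standardized) between `own_lie` and the
ground truth exists and becomes visible in very large pooled fits. The
detector-specificity check therefore uses a controlled construction in
which partner lying is drawn directly from the expectation-violation
cues (more likely the more improbable and self-favourable the report),
making the EV cues exactly sufficient; there the null cues' averaged
betas round to 0.000 robustly. On default cohorts at study scale the
BIC penalty suppresses the shared-card-set leakage in most but not all
realisations.

## Known limitations

* The mixed-model BIC uses the ML likelihood of the converged lbfgs
  solution; boundary solutions (zero random-slope variance) are common
  in subsets omitting strong cues and are handled by the fallback
  chain rather than by profiling the boundary properly.
* The unconditional-SE CI ignores weight-estimation uncertainty.
* The detector's d′ depends on the dichotomisation threshold; 0.5 is a
  convention, hence the emitted sensitivity sweep.
* Trial-level mediation treats stakes as exogenous per block and
  ignores within-block serial dependence beyond participant
  clustering.
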