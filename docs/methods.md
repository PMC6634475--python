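# Methods

`veracue` implements an analysis chain for two-person deception-game
data — utterance-level cue annotations plus the guesser's cursor
trajectory — together with a synthetic dyad-game generator that makes
every stage testable against known ground truth. This note records the
models, the defaults and why they are set where they are, and the places
where the design was genuinely open.

## Data model

One row per utterance: the speaker's veracity (truth/lie), the guesser's
response (truth = clicked the referent, the object the speaker named),
seven binary disfluency annotations (filled pause, silent pause,
repetition, restart, substitution, addition, prolongation), eight binary
raw gesture annotations, four function-based gesture categories
(adaptor, illustrator, affect display, eye contact), three continuous
speech measures (utterance duration ms, total silent-pause duration ms,
syllable rate /s), the disambiguation point (ms from trial onset, absent
when not codable), onsets of the focal cues, and bookkeeping flags
(consistent commitment, gesture data present). Cursor logs are
long-format (dyad, trial, t_ms, x_px, y_px) at a nominal 50 Hz.

Disfluencies collapse deterministically into four predictor categories:
pauses = filled OR silent; repetitions; repairs = restart OR
substitution OR addition; prolongations. Collapsing is monotone and
ignores multiplicity. Gesture categories are *not* derived from the raw
gesture types: whether a hand movement is an adaptor or an illustrator
is a judgement about its communicative function, so categories are
carried as annotation inputs (the generator emits them directly).

Exclusion rules are evaluated independently per analysis, so rule order
cannot change the included set: the cue-model analyses drop
inconsistent-commitment trials; the mouse analyses additionally drop
trials with no disambiguation point and trials whose focal cue (pause,
or affect display) begins only after disambiguation; the affect analysis
requires video. Every exclusion is logged (trial, rule, analysis) so the
data funnel is auditable.

## Speech-rate composite

The three continuous measures are summarized by the first principal
component of their correlation matrix (i.e. PCA on standardized
variables). Scores are projections onto the unit-norm leading
eigenvector; the eigenvalues of a 3x3 correlation matrix sum to 3, so
the variance share is lambda_1/3 exactly. Orientation is a free choice;
we fix the syllable-rate loading positive so that a higher score means
faster, more fluent speech, and record the orientation in output
metadata. Downstream the scores enter models standardized to unit SD.

## Mixed-effects models

**Binomial (cue models).** Speaker veracity and guesser response are
modelled by logistic regression with crossed Gaussian random intercepts
for participants (the dyad: speakers and guessers are in one-to-one
correspondence, so one grouping factor serves both outcomes) and items
(the target image). The likelihood integrates the random effects by a
Laplace approximation: for candidate (beta, sigma) the conditional mode
of the spherical effects is found by penalized Newton iteration (PIRLS,
tolerance 1e-8), and

    -2 l = -2 g(v_hat) + ||v_hat||^2 + log det(L' Z' W Z L + I)

is minimized over (beta, sigma) with L-BFGS-B (sigma >= 0, central-
difference gradients). Starting values are fixed — plain-logistic
coefficients and unit SDs — so fits are deterministic. Because the
objective is locally even in sigma, sigma = 0 is always a stationary
point; when a free SD lands below 0.02 the optimizer is restarted once
from 0.25 and the better optimum kept. Against lme4's `glmer` (the
reference Laplace implementation) coefficients, random-effect SDs and
log-likelihood agree to ~1e-3 on a shared fixture. Wald z and p values
come from the beta block of the inverse joint Hessian at the mode, as in
`glmer`. Estimable-parameter count K = fixed effects (incl. intercept) +
free variance components; the intercept-only model with two random
intercepts has K = 3. Binary cues enter as 0/1 dummies, so exp(beta) is
the odds ratio of the cue being present. Complete separation is detected
(|beta| diverging) and reported as an error naming the predictor;
non-convergence is flagged on the result instead of raising.

**Gaussian (trajectory model).** The binned-trajectory DV is modelled as
DV ~ time x cue with by-subject and by-item random intercepts and
independent random slopes for both predictors (six variance
components). Fitting is maximum likelihood — not REML — so
log-likelihoods remain comparable across fixed-effect structures when
criterion-compared. The likelihood is profiled: with variance ratios
gamma_j = sigma_j^2/sigma^2, beta and sigma^2 have closed forms through
the q x q capacitance matrix I + L Z'Z L, so an objective evaluation
costs one Cholesky factorization in q regardless of the number of rows;
L-BFGS-B runs over gamma >= 0. A ratio estimated at zero is reported via
a boundary flag, not an error. The zero-variance limit reproduces OLS
exactly, and on crossed variance-component fixtures the ML
log-likelihood matches statsmodels' MixedLM to ~1e-4. Fixed effects are
reported with t statistics (no degrees-of-freedom-based p values).

## AICc multimodel inference

For each outcome and cue family the candidate set is *every* additive
combination of the predictors — 2^5 = 32 speech models (four disfluency
categories + speech rate), 2^4 = 16 gesture models — including the
intercept-only null, enumerated in deterministic order (size, then
lexicographic). Models are scored by the small-sample criterion

    AICc = -2 log L + 2K + 2K(K+1)/(n - K - 1),

with n the number of utterances in the fitted data (the correction is
undefined for n <= K+1 and raises). The table carries, per model, the
difference to the best model Delta_i, the Akaike weight
w_i = exp(-Delta_i/2)/sum_r exp(-Delta_r/2) and the evidence ratio
ER_i = w_best/w_i = exp(Delta_i/2); per predictor, the cumulative weight
(sum of w_i over models containing it), a variable-importance measure in
[0, 1] that equals 1 for a predictor present in every candidate. Models
with Delta < 2 (configurable) form the competitive set. Ties in the
minimum are broken toward smaller K, then enumeration order; everything
is kept at full precision internally and rounded only for display.
Non-converged candidates are excluded with a warning; candidates fitted
on different n are rejected as non-comparable. No model averaging of
coefficients is performed — inference stops at weights, evidence ratios
and the best model's coefficients.

## Mouse-trajectory analysis

Cursor samples are binned into 20 ms bins time-locked to the
disambiguation point (bin 0 starts at it); each inter-sample
displacement belongs to the bin containing the later sample, so
irregular sampling is tolerated. x-axis pixels toward the referent's
side accumulate in d_ref, toward the other side in d_dist. The
proportion of movement toward an object is its cumulative distance
divided by the total cumulative distance travelled so far; by default
only x displacement enters numerator and denominator (a configurable
mode adds |dy| to the denominator only). The model DV is the empirical-
logit difference

    elogit(p) = ln((pN + c)/((1-p)N + c)),  DV = elogit(p_ref) - elogit(p_dist),

with N the cumulative distance and smoothing constant c = 0.5 (the
count-based e-logit convention; configurable, since no canonical choice
exists for continuous "counts"). Under the x-only denominator the DV
reduces to 2 ln((d_ref+c)/(d_dist+c)) and is antisymmetric under
referent/distractor swap; mirroring the display leaves every output
unchanged. Bins before any movement carry DV = 0 with a zero-movement
flag (a drop-bin mode is available). The model window is 0-800 ms
post-disambiguation; time enters centred on the window midpoint and
scaled to seconds, which sets the scale of the time and interaction
coefficients and is recorded in metadata. Mean +/- SE proportion curves
per condition are produced to 4000 ms for plotting.

## Synthetic dyad-game generator

The generator emulates the study conditions end to end with a known
causal structure (veracity -> cues -> judgement):

* 24 dyads x 48 trials; 96 items, each dyad drawing 48 without
  replacement; target side and treasure type (gold/silver)
  counterbalanced. Treasure type is carried but given zero effect.
* Veracity ~ Bernoulli with a 53.9% truth bias and a per-speaker random
  effect (SD 0.38 logits, chosen to reproduce a realistic per-speaker
  spread of truth rates).
* Each binary cue ~ Bernoulli with base log-odds matched to the
  annotated corpus rates (e.g. filled pauses 288/1149, silent pauses
  588/1149) and a veracity-dependent shift equal to the truth-vs-lie log
  odds ratio: +0.26 for filled and silent pauses, -0.29 for adaptors,
  0 elsewhere. Gesture-category base rates (adaptor 0.35, illustrator
  0.25, affect display 0.29, eye contact 130/1101) are plausible values,
  since the corpus reports counts only for raw gesture types. Cues are
  conditionally independent given veracity; real inter-cue co-occurrence
  is only coarsely emulated.
* The guesser's referent click follows a logistic model on the cue
  categories — intercept 0.40, pauses -0.39, affect displays +0.29 —
  with crossed guesser (SD 0.40) and item (SD 0.20) random intercepts.
  Because log odds ratios are symmetric, these are exactly the
  quantities the analysis models recover, which makes parameter-recovery
  tests well defined.
* Continuous measures come from a latent trivariate Gaussian with
  correlations (duration-pause +0.60, duration-rate -0.55, pause-rate
  -0.60); duration is lognormal matched to mean 3008.92 / SD 1329.35 ms,
  syllable rate Gaussian 3.82 +/- 1.42 floored at 0.3, and silent-pause
  duration is a Beta(2,3) quantile transform of the latent coordinate
  times the utterance duration — zero exactly when the silent-pause flag
  is zero and never exceeding the duration.
* The disambiguation point is uniform in 30-90% of the utterance and
  missing with probability 0.189 (additional-dialogue trials);
  inconsistent commitment occurs with probability 0.003; one dyad's
  video is marked lost. Pause onsets are early-biased (Beta(1,4)
  fraction of the utterance), affect onsets Beta(1,2), which yields
  post-disambiguation exclusion rates of a few percent for pauses and
  ~15% for affect displays.
* The cursor starts at screen centre, jitters with a zero-mean random
  walk (SD 4 px/sample), and from a drift onset — disambiguation + 200
  ms, + 250 ms if the utterance contains a pause, + 250 ms if it lacks
  an affect display — moves at 350 px/s toward the eventually clicked
  object and rests on it (+/-300 px), so the final sample always lies in
  the clicked half. This constant-drift-plus-noise process is the
  simplest mechanism that produces a slower referent bias after pauses
  and absent affect displays.

Identical seeds give bit-identical outputs. The ground-truth record
stores every generating parameter and drawn random effect in the
parameterisation the fitting modules report.

### What the generator does and does not emulate

It reproduces the truth bias, cue prevalences, effect directions, the
exclusion funnel and the qualitative post-disambiguation drift pattern.
It does not reproduce: the tetrachoric co-occurrence structure among
cues; double-bluff strategy; velocity profiles or curvature of real
mouse movements; or the exact continuous-measure correlation pattern —
the zero-inflation of pause durations and the lognormal/truncation
transforms attenuate the latent correlations, so the default-condition
PCA eigenvalue is ~1.9 (63% of variance) rather than the ~2.2 (73%)
reported for the real corpus. Passing tests therefore demonstrate
correctness of the machinery and recoverability of injected structure,
not distributional fidelity to real dyad data.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full pipeline at the default study scale
(24 dyads, 1152 utterances) and a 200-dyad (9600-utterance) recovery
fit. Simulation-based tests use 100 seeds at study scale for response-
coefficient sign recovery, 200 seeds at study scale for the trajectory
interaction sign, and 8-16 dyads for pipeline plumbing tests, sizes
chosen to keep the suite comfortably reproducible on a single CPU.

## Known limitations

* The trajectory model's t statistics are anticonservative. The per-bin
  DV is a cumulative proportion, so residuals are strongly
  autocorrelated within a trial, and the random structure (subject and
  item intercepts and slopes, no per-trial terms) leaves that dependence
  unmodelled: under a full null (no drift lag, no response pathway) the
  empirical SD of the interaction t across simulations is ~4-5 rather
  than 1. This is a general property of binned empirical-logit analyses
  of cumulative measures; sign and magnitude comparisons across
  conditions remain meaningful, but nominal |t| > 2 should not be read
  as a calibrated test. The interaction *estimate* is unbiased under the
  null (sign-balanced, mean ~0).
* Laplace integration is single-mode; with very small cluster counts
  the variance components are estimated with appreciable noise, and SDs
  genuinely at zero are reported at the boundary.
* The e-logit transform for continuous proportions has no canonical
  weighting; c and the denominator convention are configurable and
  recorded in metadata because coefficient scales depend on them.
* Raw gesture *types* in the synthetic data are descriptive set dressing
  drawn at corpus rates; only the gesture categories carry signal.
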