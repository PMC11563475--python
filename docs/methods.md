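# Methods

## Task and generative model

The task presents 8 cues, 40 times each (320 trials). Each cue pairs a
motivational valence (win: outcomes reward/neutral; avoid: neutral/punishment)
with a required action (go-left, go-right, or nogo); the inventory realizes
all four condition cells, with the Go cells split by response side and the
NoGo cells duplicated. Feedback is probabilistic at an 80:20 valid:invalid
ratio: on valid trials the correct action draws the favorable outcome of the
cue's valence, on invalid trials the mapping flips. The synthetic scheduler
balances validity exactly within cue (32 valid / 8 invalid per cue) rather
than sampling it i.i.d., which removes schedule variance from recovery
experiments; the empirical procedure it emulates fixes only the ratio.

Agents learn Q(a, s) by the delta rule `Q += ε (ρ r − Q)` from Q ≡ 0, choose
by softmax over action weights `w(go·) = Q + b + π V(s)`, `w(nogo) = Q`, with
V = +0.5 (win) / −0.5 (avoid). The model space M1–M7 is nested as described
in the README. Two constructions deserve explicit statement:

- **Outcome recoding in M7.** With sensitivities split by outcome valence
  (ρ₊FB, ρ₋FB) a raw ±1/0 coding would leave neutral outcomes carrying no
  sensitivity and confine each parameter to one motivational context. The
  package therefore recodes outcomes by context-relative desirability:
  desired outcomes (reward on win cues, neutral on avoid cues) enter the
  update as +ρ₊FB, undesired ones (neutral on win, punishment on avoid) as
  −ρ₋FB. This is the only coding under which both parameters act in both
  contexts and govern win-stay/lose-shift tendencies, and it makes
  ρ₊FB = ρ₋FB collapse M7 to a single-ρ learner on the recoded outcomes
  (verified numerically in the tests).
- **Instrumental learning bias κ (M4, M5).** κ shifts the learning rate up
  for rewarded Go and down for punished NoGo trials. To keep the modulation
  symmetric on the probability scale, the smaller branch is computed on the
  logit scale — with base rate ε₀ = invlogit(ε̂), if ε₀ ≤ 0.5 then
  ε_punishedNoGo = invlogit(ε̂ − κ) and ε_rewardedGo = ε₀ + (ε₀ −
  ε_punishedNoGo); the mirrored construction applies for ε₀ > 0.5. The
  reflected branch can leave (0, 1) and is clamped to [1e−9, 1 − 1e−9]. The
  boundary ε₀ = 0.5 (measure zero) is deterministically assigned to the
  first branch.

Parameter transforms between the unconstrained fitting scale and the native
scale: sensitivities by exponential (positivity), learning rate by inverse
logit (unit interval), b/π/κ identity (unbounded). Round trips are exact to
machine precision.

## Likelihood and numerics

The per-subject likelihood runs the generative recursion over the observed
trials, accumulating −log p(action). Softmax weights are max-subtracted and
probabilities floored at 1e−12 inside the log. The inner loop is
JIT-compiled (numba); the test suite checks it against a deliberately naive
O(n²) pure-Python recomputation that rebuilds the Q table from scratch at
every trial.

## Hierarchical fitting

Subjects are fit by MAP on the unconstrained scale under a Gaussian group
prior, with the model evidence approximated by Laplace's method at the mode:
log Z ≈ −penalized-NLL(θ*) + (d/2) log 2π − ½ log|H|. Defaults: initial
prior mean 0, variance 6.25 per parameter (weakly informative on the
transformed scales); L-BFGS-B with finite-difference gradients; 3–5 jittered
restarts on the first sweep, warm starts afterwards; Hessians by central
finite differences (step 1e−4), ridge-repaired with a logged warning if not
positive definite.

The group prior is learned by EM: the M-step sets the group mean to the mean
of subject MAPs and the group variance to the mean squared deviation plus
the local posterior variances (floored at 1e−4 to keep the prior proper when
between-subject variability vanishes). Iteration stops when the prior moves
less than `tol` (default 1e−3) or after `max_iter` sweeps; the summed
Laplace evidence is tracked and the EM is monotone-accepting — a decrease
restores the previous prior and stops, which doubles as the divergence
guard. One deliberate simplification relative to full hierarchical Bayesian
inference with the model as a random effect: models are fit independently
and only then compared by random-effects selection on their evidences,
rather than weighting subjects by model responsibility during fitting. At
the data scales used here the comparison outputs are indistinguishable and
the two stages are far easier to verify in isolation.

## Model comparison

Random-effects Bayesian model selection places a Dirichlet(1, …, 1) prior on
population model frequencies and fits it by variational Bayes on the
subjects × models log-evidence matrix. Exceedance probabilities come from
the exact Beta form for two models and from 10⁶ (configurable, seeded)
Dirichlet Monte-Carlo samples otherwise. The Bayes omnibus risk compares the
frequency model's free energy against the null of equal frequencies,
BOR = 1/(1 + exp(F₁ − F₀)), and the protected exceedance probability is
PXP = (1 − BOR)·EP + BOR/K. Comparisons are invariant to per-subject
constant shifts of the evidences.

## Validation

Posterior-predictive checks simulate each subject at the fitted parameters
on that subject's own cue order and validity flags (100 sessions by
default), aggregating P(Go) by condition and within-cue presentation index
1–40 — the natural x-axis for per-condition learning curves — and P(repeat)
by previous action × outcome valence × salience, where "repeat" means
choosing the identical action (including Go side) on the next presentation
of the same cue. Parameter recovery simulates a cohort, refits it
hierarchically, and reports Spearman correlations between generating and
recovered values per parameter; parameters with zero between-subject
variance are flagged degenerate instead of given a correlation.

## Synthetic cohorts and the cross-task table

Cohort generators default to the group-mean estimates of the fitted model
space with between-subject sd 0.5 on the unconstrained scale — a spread
wide enough to make recovery non-trivial while keeping agents in a
behaviorally plausible regime. Ages are uniform on [12, 42] (the study
range; the empirical distribution's right skew is available as an option but
not the default). Age gradients are linear shifts of a parameter's mean per
sd of age.

The cross-task table is linear-Gaussian: mediator m = a·age_z + e₁, outcomes
y = ±b·m + c′·age_z + e₂ (negative sign for switching after negative
feedback), remaining columns correlated with the mediator at configured
levels (defaults qualitatively mirror the cross-task pattern: noise
parameters cohere across tasks, learning rates do not). Defaults a = 0.5,
b = 0.5, c′ = 0.25 give a true proportion mediated of 0.5. Mediation as
implemented is linear, so this minimal structure exercises every code path;
it does not emulate the reversal-learning or two-step generative processes
themselves, and passing tests certify the statistical machinery, not any
claim about real behavioral data.

## Mediation and correlations

Mediation uses the product-of-coefficients decomposition from three
least-squares fits (m ~ x; y ~ x + m; y ~ x), with the predictor
z-standardized, and nonparametric case-resampling percentile bootstrap CIs
(default 10,000 replicates; the recovery/calibration studies use 1,000).
Two-sided p-values are doubled tail proportions of replicates crossing zero.
The proportion mediated is stored uncapped and flagged unstable whenever the
total effect's CI covers zero. Cross-task Spearman correlations carry
family-wise Bonferroni thresholds of 0.05/4 for Go/NoGo × reversal pairs and
0.05/2 for Go/NoGo × two-step pairs.

## Performance filter

The pipeline's rudimentary performance check excludes subjects whose overall
accuracy is not significantly above chance (one-sided binomial test against
1/3, α = 0.05); a fixed accuracy threshold can be supplied instead. This
operationalization is a package choice — the empirical exclusion rule it
stands in for is not specified beyond "rudimentary".

## Problem sizes and determinism

The validation studies run at 93 subjects (recovery, mediation), 30
(model identification), and 50 (posterior-predictive self-consistency),
with 320 trials per subject, 100 predictive simulations, and 100–500
mediation replications at 1,000 bootstrap draws — sizes at which every
quantity is stable across seeds. All randomness flows from explicit integer
seeds; reruns with the same configuration are bit-identical.

## Known limitations

- Laplace evidence assumes a locally Gaussian posterior; strongly skewed
  subject posteriors (e.g., near-boundary learning rates) are summarized
  optimistically.
- The EM hierarchy estimates a diagonal group covariance; parameter
  correlations at the group level are not modelled.
- ρ₋FB recovers less sharply than the other parameters at the default
  cohort spread (rank correlation ≈ 0.5 at n = 93): with ρ₋FB near 1 its
  influence on choice is weak relative to ρ₊FB, an identifiability property
  of the design rather than an implementation defect.
- The cross-task generator is linear-Gaussian by construction; nonlinear or
  heteroscedastic mediation structures are out of scope.
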