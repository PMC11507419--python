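# Methods

## Model and assumptions

State occupancy S(t) ∈ {1, 2, 3} (no / mild / severe ADL disability) follows
a time-homogeneous continuous-time Markov chain. The generator `Q` has six
free off-diagonal intensities — all transitions are allowed, including the
rare direct moves 1↔3 — and diagonal `q_rr = −Σ_{s≠r} q_rs`. Transition
probabilities over an interval are `P(t) = exp(Qt)`, evaluated with
scipy's scaling-and-squaring Padé implementation (`scipy.linalg.expm`);
the test suite checks it against an independent truncated power-series
oracle to 1e-10 and verifies the Chapman–Kolmogorov semigroup property to
1e-8 on random generators.

Time-homogeneity is assumed within the follow-up; covariates are evaluated
at the start of each observation interval and held constant across it (the
conventional piecewise-constant treatment of time-varying covariates in
panel multi-state models). Age is time-updated at interval starts by
default; all other covariates are baseline characteristics. There is no
absorbing death state: the modelled cohort excludes deceased subjects at
ingestion (a `death_flag` column, if mapped, removes them).

## Likelihood and estimation

Panel data are interval-censored, so each consecutive within-subject pair
(state r at t, state s at t + Δt) contributes `log P_rs(Δt; z)`. Pairs are
grouped by (Δt, covariate pattern) so each group shares one matrix
exponential; the grouped sum is exactly the naive per-pair sum (tested).
A probability that is numerically zero, or a linear predictor beyond ±30,
makes the likelihood −∞ rather than raising, so optimizers can backtrack.

Parameters are the six baseline log-intensities θ_rs = log q_rs0 (the log
scale enforces positivity without constraints and makes Wald intervals for
hazard ratios natural) followed by one coefficient block per covariate. A
model specification controls which covariates enter which transitions; the
default gives every covariate a transition-specific coefficient.

Optimization is BFGS on the *mean per-pair* negative log-likelihood, which
makes the gradient stopping rule (max-norm < 1e-4, iteration cap 500)
scale-free in the number of pairs. Initial values are moment-style crude
rates `counts_rs / (row_total_r × mean interval)`, floored at 1e-4 per year
so logarithms stay finite; covariate coefficients start at zero. The fit
reports convergence diagnostics and never ends below its starting
log-likelihood.

The covariance matrix is the inverse observed information, computed by
central finite differences (relative step 1e-5) of the total negative
log-likelihood at the optimum. When the information matrix is singular —
typically because a log-intensity or coefficient sits at a flat boundary
(e.g. a transition with essentially no events) — the inverse is taken with
near-zero eigenvalues floored at 1e-10, which assigns enormous (not zero)
variance to non-identified directions; this is the conservative Wald limit
for a flat likelihood, and such fits are flagged with a warning. Hazard
ratios are `exp(β)` with 95% intervals `exp(β ± 1.96·SE)`; no
multiple-testing adjustment is applied across the HR cells. Wald (not
profile) intervals are used throughout.

Covariate coding: age continuous in years, uncentered; education an ordered
1–5 score entered numerically; sex, residence, economic source and
co-morbidity binary with reference levels male, home-based, with-pensions
and non-co-morbidity coded 0.

## Synthetic cohort generator

The generator emulates the structure of the restricted 2014–2017 Shanghai
needs-assessment cohort: 9091 subjects by default, annual waves at 0–3
years, baseline state mix (0.512, 0.268, 0.220), age truncated-normal
(mean 77.87, SD 9.22, minimum 60, drawn exactly by inverse-CDF), and the
published binary/ordinal covariate marginals. Baseline states are drawn
independently of covariates by default (the joint structure of the source
tables is only partially recoverable from printed margins); covariate
effects are injected explicitly per experiment as log hazard ratios on
chosen transitions, and default to zero so that the marginal process
follows the configured generator exactly. Latent trajectories are simulated
by exact event simulation (exponential sojourns, embedded-chain jumps;
piecewise-constant generators handled by clock restarts, exact by
memorylessness) and observed at the wave times, producing genuine interval
censoring.

Follow-up waves are dropped independently with probability 0.42 by default
(baseline always observed; patterns leaving fewer than two observations are
redrawn). That rate was chosen once so the expected number of consecutive
observation pairs at n = 9091 matches the reference cohort's ≈17,200 pairs
(≈1.9 per subject). Real missingness is unlikely to be independent across
waves or of health status; the generator makes no attempt to model informative
dropout, so passing tests demonstrate correctness under (covariate-modulated)
Markov dynamics with ignorable missingness, not robustness to informative
observation schemes. Each subject has a private random substream keyed by
(seed, subject index), so enlarging the cohort never reshuffles existing
subjects and identical configurations are byte-identical.

## Recovery experiments and problem sizes

The simulation experiments in the acceptance tests run at 5000 subjects ×
4 annual waves with no missingness. Intensity recovery uses 20 seeds; the
four well-populated intensities (q12, q21, q23, q32) are recovered with
median relative error well under 10%, while the tiny rates (q13 = 0.0003,
q31 = 0.0068 per year) contribute at most a handful of expected events at
this scale and are recoverable only in order of magnitude — their
estimates often sit at the small-rate floor with appropriately enormous
intervals. Hazard-ratio recovery injects a balanced (prevalence 0.5)
binary covariate with true HR 4.65 on the 1→3 transition and fits the
coefficient on that transition; prevalence 0.5 maximizes design information
for a generic exposure, and even so the effect is weakly identified because
observed 1→3 moves are dominated by the indirect 1→2→3 pathway — the Wald
intervals are honest about this by being very wide, and cover the truth in
well over 90% of replicates.

## Numerical choices and edge cases

- Classification cutpoints are exact: total 20 → state 1, total 8 → state 2
  (8 is excluded from the severe band), so boundary scores are never
  ambiguous.
- Generator rows sum to zero by construction to 1e-12; probability rows sum
  to one to 1e-9, with round-off clipped into [0, 1].
- Sample paths are right-continuous: a state entered exactly at an
  observation time is the state recorded at that time.
- An empty dataset has log-likelihood 0; a subject ordering permutation
  changes estimates by < 1e-8 (the likelihood is a sum).
- Prevalence-based goodness of fit propagates each subject's baseline state
  through P(t) (covariate-aware when the fit has covariates, with a marginal
  option), with the risk set at time t defined as subjects whose last
  assessment is at or after t; requested times beyond the whole follow-up
  are computed by propagating the full cohort and flagged as extrapolation.
  Formal hypothesis-test diagnostics are out of scope.

## Known limitations

- No hidden-Markov misclassification layer: observed states are taken as
  true states.
- Time-homogeneous baseline intensities; calendar-time or age-inhomogeneous
  baselines are not modelled (age enters only through the proportional
  term).
- No mortality/absorbing state, matching the modelled cohort's design; in
  populations with non-trivial mortality this will bias transition
  estimates.
- Wald intervals can be poor for boundary-adjacent parameters; the wide
  flagged intervals above are the symptom, and profile likelihood would be
  the next step if those transitions mattered substantively.
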