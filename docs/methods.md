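# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Detection data model

The sampling unit is the *sampling event*: one visit to one vernal
pool, yielding J replicate water samples (typically three) and a
dip-net survey. Repeat visits to the same pool are treated as
independent events; the pool identifier is retained only for
reporting. Each water replicate is assayed by species-specific TaqMan
qPCR in quadruplicate, and the sample-level call follows the rule: ≥2
of 4 wells amplified → positive; 0 → negative; exactly 1 → re-run,
then positive if any re-run well amplifies, else negative. (The
all-negative re-run branch is stated nowhere explicitly in monitoring
protocols of this kind; negative is the only reading consistent with
the other three branches.) A well counts as "amplified" whenever the
instrument reports a Cq within the 50-cycle protocol; a stricter Cq
ceiling is exposed as the `edna_cq_max_cycle` config knob. The
tissue-identification cycle cutoffs (20 cycles, or 30 for the BRLY
assay, against off-target floors of 30 and 42) apply only to specimen
classification, which uses the median of the quadruplicate so a single
aberrant well cannot flip a call.

Events whose paired field/equipment negative amplified are discarded:
their replicates are coded missing, and an event with no usable
replicate is dropped from the detection history.

## Occupancy model

Site i (an event) has latent occupancy z_i ~ Bernoulli(ψ_i), and
replicate j yields y_ij | z_i=1 ~ Bernoulli(p_ij), with
ψ_i = expit(w_i·α) and p_ij = expit(x_ij·β). The site likelihood
marginalizes z_i; for events where the dip-net caught the species
("known occupied"), the unoccupied branch is dropped while the ψ_i
factor is kept, so ψ remains estimable from the full likelihood rather
than being pinned to 1 at those sites.

Numerics: covariates are z-standardized internally (coefficients
reported on both scales); the optimizer is L-BFGS-B on the logit scale
with box bounds ±15, run from 5 jittered starts (seeded; best
log-likelihood wins, ties to first found). Estimates with |logit| > 10
are flagged as boundary estimates and no covariance is reported for
them. The covariance matrix is the pseudo-inverse of a numerical
Hessian. Candidate detection covariates are the four the field data
carry: volume filtered per replicate, site-average volume, pool area,
and filtration protocol (field = 0, lab = 1). Model selection fits all
2⁴ = 16 subsets and ranks by AIC; within 2 AIC units of the best, the
fewest-parameter model is selected (standard parsimony convention).
Occupancy covariates are supported but default to none.

Detection predictions use the delta method on the linear predictor:
x·β̂ ± 1.96·se, back-transformed, which keeps the interval inside
[0, 1]. Profile-likelihood intervals would differ slightly near
boundaries; the delta-on-link choice is the conventional one and is
validated against a Monte-Carlo normal-sampling oracle in the tests.

### Goodness of fit

The MacKenzie–Bailey statistic is T = Σ (O − E)²/E over
observed-history cells. Because covariates can make every site's cell
probabilities distinct, each site is its own cohort: E is the site's
fitted probability of each of its 2^J possible histories (conditioned
on occupancy at known-occupied sites, so each site's cells sum to 1),
O the indicator of the observed history; cells with E < 10⁻¹⁰ are
skipped. The null distribution comes from a parametric bootstrap that
preserves covariates, the missing-replicate pattern and the
known-occupied conditioning, refits each simulated dataset
(warm-started at the fitted parameters), and reports
p = (1 + #{T* ≥ T_obs})/(B + 1) and ĉ = T_obs / mean(T*). Because both
T_obs and T* are evaluated at data-specific MLEs, ĉ centres slightly
below 1 on well-specified data (≈0.95 in the calibration tests), well
inside the conventional adequacy band.

## False-positive (certain/uncertain) model

Observations take codes 0/1/2 (none / uncertain / certain detection).
Certainty comes from the event-level dip-net result: every eDNA
positive at a dip-net-positive event is certain. At occupied sites a
replicate is detected with probability p₁₁ and a detection is certain
with probability b; at unoccupied sites detections arise with constant
probability p₁₀ and can never be certain — that structural zero is
what separates p₁₀ from p₁₁. p₁₀ carries no covariates (a contaminant
has no reason to track pool area or filtration method); p₁₁ may. b is
estimated by default but can be fixed.

A caution established by simulation in this package's test suite: the
likelihood treats replicate outcomes as independent given z_i, but
event-level certainty assignment ties together the certainty codes of
all replicates at an event (sites are all-certain or all-uncertain).
On data generated that way, the replicate-independent MLE can
degenerate (b → 1 with p₁₀ absorbing uncertain-only sites). Estimator
checks therefore use histories drawn from the model's own observation
process (per-replicate certainty, `simulate_fp_history`); applied to
real event-certainty data, p₁₀ estimates should be read alongside the
concordance table, and fixing b is the conservative option. Setting
p₁₀ = 0, b = 1 recovers the binary likelihood exactly on data whose
positives are all certain.

## Standard curves, LOD and LOQ

The calibration line is an OLS fit of Cq on log₁₀(copies/reaction)
over amplifying wells only; non-amplifying wells are excluded from the
regression but counted in detection fractions. Efficiency is
10^(−1/m) − 1. Low95 is the lowest *tested* concentration with ≥95% of
replicates amplifying (a sentinel, `ABOVE_MAX_TESTED`, is returned
when no level qualifies — never 0). The LOD is that same discrete rule
or, in `curvefit` mode, the 95% crossing of a two-parameter logistic
dose-response fitted to the detection fractions by binomial maximum
likelihood, clamped to the smallest tested concentration and falling
back to the discrete rule when the pattern is not increasing. The LOQ
back-calculates copies for each amplifying well through the fitted
line and takes the lowest concentration whose coefficient of variation
is ≤ 0.35 (the conventional threshold of qPCR LOD/LOQ calculators;
configurable); `curvefit` mode interpolates the crossing of a
log-linear CV decay. All three are single-replicate figures; r
replicates improve effective detection as 1 − (1 − d)^r.

## Survey-design calculus

Assuming independent water replicates, P(≥k of n positive) is the
binomial upper tail, evaluated at p̂ for detection and at p̂₁₀ for the
false-positive rate of a k-of-n site-calling rule. Requiring 2 of 3
positives at p₁₀ = 0.091 gives an exact rule-level false-positive
probability of 0.0233 (3p²(1−p) + p³); note that the square alone,
p₁₀² ≈ 0.0083, understates the rule's false-positive rate because it
ignores the three ways two positives can land among three replicates
and the all-three term. Confidence intervals push the per-replicate CI
endpoints through the tail, exact because the tail is monotone in p.
Independence across replicates is a modelling assumption; spatial
clumping of eDNA within a pool would make cumulative detection
optimistic.

## Synthetic-data generator

`simulate_study` emulates the study design end to end: 89 events by
default, three replicates each, ψ = 0.5, per-replicate detection
expit(intercept + covariate effects) with a default intercept of
logit(0.7564) and zero covariate effects (the base-model situation),
p₁₀ = 0, and dip-net sensitivity 0.8 — a free parameter, since no
dip-net detection rate has been established for these taxa; 0.8
represents a good surveyor in season. Pool areas are log-normal
(median ≈ 500 m²); a site-level turbidity latent depresses replicate
volumes through a clogging model (volumes in (0, 1000] mL), which is
what makes site-average volume a meaningful covariate; filtration
protocol is Bernoulli(0.5). Detected replicates expand to
quadruplicate wells with 2–4 amplifications and Cq values drawn from a
log-linear curve (defaults m = −3.609, c = 38.664, σ = 0.35);
non-detected replicates occasionally (5%) show a single amplifying
well followed by an all-negative re-run, exercising the re-run rule.
`simulate_standard_panel` mirrors the calibration geometry: five
concentrations spanning 1–100 copies/reaction, eight replicates each,
eight NTCs, with logistic concentration-dependent dropout.

What the generator does *not* emulate: spatial or temporal
autocorrelation between events, eDNA concentration dynamics within a
season, inhibition, cross-contamination structure beyond a constant
per-event rate, and dip-net false positives (visual misidentification).
Passing recovery tests therefore demonstrate estimator correctness
under the stated model, not robustness to those field realities.

## Problem sizes used in the checks

Recovery checks run at 500 sites (binary model) and 1000 sites
(false-positive model) with three replicates; interval coverage uses
200 repeats of 200-site studies; goodness-of-fit calibration uses 50
repeats at B = 200 bootstrap replicates on 100-site studies; LOD
recovery averages 10 panels of 24 replicate wells per level. These
sizes put Monte-Carlo error comfortably below the tolerances asserted
while keeping the default test run fast.
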