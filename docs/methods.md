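# Methods

This note documents the models, conventions and design choices behind
`gldtraj`, in the order the pipeline runs them.

## Synthetic dispensing database

`gldtraj.synthetic` emulates a community-pharmacy prescription database:
a patient table (birth year, sex, registration interval) and a
dispensing table (patient, 7-character ATC code, date). It is the
package's substitute study population; the real database it is modelled
on is access-restricted.

**Covariates.** Age at mid-index-window is normal (default mean 66.19,
SD 11.11 years, stored as birth year); sex is Bernoulli (48.2% female).
Each patient draws a baseline glucose-lowering regimen from a 14-category
taxonomy (metformin monotherapy 41.2%, SU + non-insulin combination
26.4%, insulin + other 15.5%, …), realised as concrete ATC products
(e.g. metformin A10BA02, gliclazide A10BB09, basal insulin A10AE04,
premixed A10AD05 for 15% of insulin users). Non-diabetes "filler" drugs
(Poisson, mean 3 distinct subgroups) and antidepressants (20%) are
dispensed around the index date so the drug-count and antidepressant
predictors of the risk score are exercised.

**Refills.** Each active drug emits dispensings as a renewal process
with truncated-normal intervals (default mean 60 d, SD 15 d, floor
14 d — a typical 2–3-month dispensing cycle). Under these defaults the
probability that an active drug has *no* dispensing inside a ±45-day
assessment window is E[(L−90)⁺]/E[L] ≈ 0.2% per drug per assessment
(stationary-renewal argument), so snapshot misclassification is rare but
not zero; statistical tests that need exact recovery of the latent path
shorten the refill interval to mean 30 d, SD 5 d, where the miss
probability is numerically zero.

**Latent annual path.** Each follow-up year a patient draws an intended
state (NC/IN/DI) from row-conditional rates given the previous year's
state; the five per-interval default rows reproduce the annual
transition structure of the emulated cohort (e.g. Year-1 marginals
7.7% IN / 4.7% DI; later NC-row, IN-row and DI-row conditional
frequencies taken from its printed transition matrices). An intended
change is realised as one concrete regimen edit at a uniformly drawn
date 60–300 days into the interval — add SU, add insulin, discontinue,
or switch, with action weights conditioned on the current regimen
(insulin is mostly added on top of SU-containing combinations; SU is the
dominant add-on to monotherapy), chosen to mimic the observed subtype
mix. The 60–300-day bound keeps every change ≥45 days away from both
anniversaries, so a sustained change is visible to the snapshot method.
If the regimen cannot express the intended state (intensification with
insulin+SU already present; de-intensification without any hypo drug)
the year falls back to NC; `latent_truth` returns the realised states
and is the oracle for classifier-recovery tests.

**Covariate effects and calibration.** Odds multipliers modify the
intended-state probability per patient-year: insulin-active ×0.18 on
intensification (calibrated so the net 5-year intensification OR for
high risk lands near the reported ≈0.15), female ×0.94 (IN) and ×1.12
(DI), and per-decade age factors 0.80 (IN) and 0.97 (DI). No explicit
insulin multiplier is placed on de-intensification: its strong positive
association with insulin use (net OR ≈ 3) emerges mechanically because
only patients on a hypoglycemia-associated drug can de-intensify.
Because eligibility and modifiers shrink realised rates below intended
ones, the NC-row draw probabilities are calibrated analytically: the
realised frequency is the expectation of the modified probability over
the baseline regimen × sex × (truncated ≥35) age law, and a
one-dimensional root-find inverts it per destination. This makes the
realised Year-1 marginals match the configured targets to Monte-Carlo
error; later intervals reuse the baseline mix as an approximation, so
their marginals track the targets to within a few percent. Rates,
modifiers and targets are all configurable.

**Edge cases** are injected at configured fractions and exist to be
excluded: spot users (a single A10 dispensing, 2%), insulin-only
pre-index patients (2%), and short-registration patients (49%,
mirroring the roughly half of database patients that fail a ten-year
continuous-registration requirement). Regular patients whose baseline
is insulin-only carry a discontinued oral episode 2–4 years pre-index,
as real type-2 insulin users do, so they survive the insulin-only
exclusion.

**Determinism.** One master seed; per-patient substreams are spawned
from a `SeedSequence`, so outputs are byte-identical for a given
configuration and independent of iteration order.

What the generator does *not* model: dose changes and DDDs, prescriber
effects, hospital carve-outs, mid-follow-up pharmacy switching,
mortality beyond `registration_end`, intra-year churn beyond one change
per year, and within-person rate heterogeneity. Consequences: the
synthetic cohort's *net* 5-year de-intensification share runs a few
points above the emulated population's (transient real-world changes
revert more often than the one-edit-per-year latent path allows), and
passing tests demonstrate the pipeline's correctness on data with this
structure, not the clinical fidelity of any particular rate.

## Cohort selection

Rules are applied in a fixed order (index date exists → age ≥35 → not a
spot user → full registration → not insulin-only pre-index → optional
dummy-id screen) and tallied into a flow report whose counts add up to
the input size. Conventions: the index window is closed on both ends;
age is completed years from birth year with a July-1 convention (the
database stores birth year only); the ≥2-dispensing rule counts A10
dispensings in the closed interval [index, index+365 d], the index
dispensing included; registration must cover [index−5 y, index+5 y]
continuously; patients with *no* pre-index A10 dispensings are retained
(incident-like users), while those whose pre-index A10 dispensings are
exclusively insulin are excluded.

## Snapshots, taxonomy and change classification

A drug subgroup (5-character ATC) is active at an assessment date iff it
has ≥1 dispensing in the closed ±45-day window. Fixed-dose combination
products (`A10BD…`) decompose into constituent subgroups via a shipped,
editable lookup. Anniversaries are calendar dates (Feb 29 → Feb 28 in
non-leap years), not index+365k. The regimen taxonomy gives insulin
labels precedence over SU labels over others; "Insulin combination"
means ≥2 insulin subgroups and no oral agent, "SU combination" ≥2
distinct SU products only.

Interval classification compares consecutive snapshots (net annual
change — only changes sustained to the anniversary are seen):

* no SU/insulin class delta → **NC**, including changes confined to
  "other" glucose-lowering drugs;
* hypo additions only → **IN**; the subtype is a switch when a non-SU
  agent disappears at the same time, otherwise an addition;
* hypo drops only → **DI**; a switch when a new non-SU agent appears,
  otherwise a discontinuation (a full stop of all glucose-lowering
  drugs counts as discontinuation of the dropped hypo drug; stopping
  non-hypo drugs only is NC);
* mixed deltas resolve by insulin dominance: SU→insulin is IN,
  insulin→SU is DI.

Subtypes are named systematically `{Mono|Comb}—{action}` with the
prefix from the start-of-interval therapy type. The published subtype
table is a "most common" list; the systematic vocabulary additionally
contains the rare `Mono—Switching from SU to insulin`, which the
enumeration oracle exercises. All reported percentages round half away
from zero to one decimal, matching the printed tables.

## Multi-state Markov model

States NC/IN/DI observed annually are panel data: the five observed
states give four inter-observation intervals, each with its own
generator Q_k (piecewise-constant intensities; each gap treated as
exactly one year). The log likelihood of an interval is
Σ n_ij log [exp(Q_k)]_ij over its transition counts. Off-diagonal
intensities are optimised on the log scale (positivity by construction,
box bounds log q ∈ [−12, 3]) with analytic gradients from the Fréchet
derivative of the matrix exponential, L-BFGS-B, gradient tolerance
1e-6, initialised from continuity-corrected crude rates
(n_ij+0.5)/(n_i+0.5). With fully interval-specific intensities the MLE
saturates the empirical transition frequencies whenever they are
embeddable (expressible as exp(Q) for a valid Q); on non-embeddable
empirical matrices — which annual-resolution panels routinely produce —
the fit returns the nearest embeddable law, and some intensities land
on a bound.

Confidence intervals (95%) come from a seeded parametric bootstrap
(default 500 draws) over the asymptotic normal of the log-intensities,
pushed through the matrix exponential elementwise; a delta-method
alternative is provided. Bound-active (unidentified or boundary)
parameters are held fixed during uncertainty propagation, the standard
treatment for boundary MLEs; intervals are widened if needed to contain
the point estimate. Goodness of fit compares observed with expected
counts (row marginal × fitted P) via Pearson residuals.

## Risk score

The score is an inverse-logit of a linear predictor over: age per
decade, female sex, distinct ATC-5 subgroups in the index window (total
and glucose-lowering), SU and insulin subgroup counts, premixed-insulin
and antidepressant use, and years since the first insulin dispensing in
the five pre-index years (capped at 5). Counts are distinct subgroups,
not dispensing events, making the score robust to refill frequency.
The published coefficient vector is not public, so coefficients are a
required configuration input; the shipped synthetic default was
calibrated once, against the analytic covariate law of the generator,
so that the expected high-risk share is ≈26% — essentially the
insulin-treated patients, the group the published score is designed to
flag. The cutoff comparison is `score ≥ 0.6` (boundary high).

## Outcome regression

Multinomial logit of the net 5-year state (index snapshot vs Year-5
snapshot; NC reference) via statsmodels MNLogit (Newton). Model 1: high
risk + female + age/10; Model 2: high risk only. Wald 95% CIs;
two-sided p<0.05 flags significance; no multiple-testing correction.
Constant or collinear predictors and perfect separation raise a
dedicated error naming the offending predictor.

## Problem sizes and numerical checks

The acceptance script simulates a 53,400-patient database (≈25,000
retained, matching the emulated cohort) and runs in about a minute.
The test suite's statistical checks use: a 27,500-patient generation
(≈25,200 retained) for rate-calibration, classifier-recovery (≥99%
agreement with the latent truth) and risk-share checks; 200 replicates
of 5,000-patient panels for Markov recovery (mean elementwise bias
< 0.02, pooled bootstrap CI coverage 95%±3) with true generators taken
as matrix logs of realistic 1-year transition matrices; and 100
replicates of 25,000 simulated outcomes for regression CI coverage at a
true de-intensification OR of 2.9. Exact tolerances: matrix-exponential
identities to 1e-8, saturation to 1e-4, closed-form odds ratios to
1e-6, hand-computed linear predictors to 1e-12.

## Known limitations

* The Markov model assumes first-order dependence between annual
  states; the generator's latent path is itself first-order, so model
  misspecification on synthetic data is limited to the
  discrete-vs-continuous-time mismatch (visible as non-embeddable
  empirical matrices and nonzero Pearson residuals).
* The calibration of later-interval NC rows uses the baseline regimen
  mix, so Years 2–5 marginals track their targets only approximately.
* Exposure is class-level presence in a window: dose changes and
  duration-weighted exposure are out of scope by design.
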