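# Methods

This note documents the models, default parameters, numerical choices
and limitations of the `nutricea` pipeline. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic trial generator

The generator (`nutricea.synthetic_trial`) emulates a two-arm randomized
trial of ONS + nutritional counseling vs counseling alone in head and
neck cancer radiotherapy patients. Its defaults are the study
conditions; everything is overridable through `TrialConfig`.

**Design.** 78 treatment / 81 control patients; utility visits at 0, 2,
3 and 5 months (end of radiotherapy at month 2); staggered uniform
accrual 2012-07-01 to 2016-04-30 with administrative censoring at
2020-01-02 (potential follow-up 1343–2742 days).

**Utilities.** Visit value = arm-visit mean + patient random intercept
(SD 0.10) + residual (SD 0.05), clipped to [0, 1]. A quarter of the
intercept variance loads on baseline handgrip and phase angle so the
imputation predictors carry real signal. The visit means

- treatment: 0.7973, 0.7081, 0.7344, 0.7973
- control: 0.8070, 0.7008, 0.7274, 0.7964

are calibrated so the *expected* per-arm QALYs equal the observed trial
means (0.2911 and 0.2883; Δ = 0.0028) after accounting for dropout; the
dip-and-recovery shape around the end of radiotherapy is a design
choice, since only QALY summaries, not the per-visit curve, are
reported. Sporadic single missing points occur completely at random at
1.3% of non-baseline visits.

**Dropout.** Hospitalization / artificial-nutrition / loss-to-follow-up
compete as constant monthly hazards over the 5-month window (treatment
0.008/0.010/0.005, control 0.010/0.013/0.005 — the control excess
mirrors its higher hospitalization and parenteral-nutrition costs).
On-trial death is not a separate dial: it is the long-term survival
process restricted to the first 5 months, which keeps the trial and the
6-year analysis mutually consistent and yields ≈ 7–8 expected deaths
per arm.

**Costs.** Per-category resource quantities are zero-inflated Gamma
(point mass at zero + Gamma positive part), in fractional
unit-equivalents (bottle-, day-, visit-, episode-equivalents), so
expected euro amounts are analytic. Parameters are calibrated to the
published per-category arm means (totals ≈ €988 vs €996) with the
control arm's heavy right tail (SD in the low thousands) coming from
sparse large hospitalization and parenteral-nutrition episodes.

**Survival.** Piecewise exponential with a changepoint at 730 days:
equal early hazards (ln 2 / 1085 per day) and a lower treatment late
hazard (1.86 × 10⁻⁴ per day), reproducing medians of ≈ 1949 vs 1085
days through purely late separation. Early-emphasis tests therefore
have little power while late-emphasis tests do; at these medians the
plain log-rank also gains power, which is a property of any generator
matching both medians with proportional-or-later separation.

**Ground truth.** `true_values` returns the implied estimands in closed
form: expected QALY per arm as the trapezoid of the expected utility
curve (expectation and trapezoid commute because the area is linear in
the visit values; the clipped-normal mean is evaluated exactly, and
rule-based dropout contributes its 0.35/0.30/0 values with
competing-risk probabilities), expected cost per arm as Σ (1−p₀) ×
mean quantity × unit cost, and RMST at 1–6 years by piecewise-exponential
integration. Loss-to-follow-up visits are treated as missing at random
and assumed recovered at the active-patient mean by imputation — exact
in expectation under the generator's independence of loss and utility.

**What the generator does not emulate.** Item-level EORTC scores (the
synthesis happens on the utility scale); correlation between a
patient's costs and utilities; non-uniform accrual; informative
censoring; center effects. Passing recovery tests therefore shows the
estimators are correct under these assumptions, not that the original
trial data satisfy them.

## QALY construction

Interpolation is linear (trapezoid); decedents contribute utility 0
from the death time onward, the standard QALY convention (the curve
still interpolates linearly from the last observed value down to 0, so
a small sliver accrues between the last pre-death visit and the death
visit). Dropout utilities 0.35/0.30 are configuration values, not
constants. Chained imputation defaults: m = 20 imputations, 10
iterations, predictive-mean-matching donor pool of 5, Bayesian linear
regression draws per visit on baseline covariates plus the other
visits. PMM only ever copies observed donor values, so imputations
respect [0, 1] by construction. Downstream bootstrap operates on each
patient's QALY averaged across imputations — a deliberate
simplification that understates between-imputation variance in the
bootstrap cloud; Rubin's rules (`pool_rubin`) are provided for scalar
estimates. The supported test for the arm-by-time interaction is the
ML likelihood-ratio test; Satterthwaite degrees of freedom are not
implemented.

## Costing

Amounts are held in integer cents per category (rounded once at
costing), so category amounts sum to the total exactly. The inflation
index is user-supplied; the default is the identity with a logged
notice, because no specific national price index is bundled. Costing is
arm-agnostic: control-arm ONS prescriptions are priced at the control
unit cost (€1.43/bottle). Per-category comparisons use Welch t-tests
(the unequal-variance choice is deliberate given the variance ratios
involved); the total uses the stratified bootstrap percentile p-value
2·min(P(Δ\* ≤ 0), P(Δ\* ≥ 0)).

## Decision analysis

The bootstrap is stratified by arm (preserving arm sizes); B = 1000 by
default. The ICER point estimate comes from original-sample means, not
bootstrap means. EVPI uses the two-strategy form
E[max(0, INB)] − max(0, E[INB]), equivalent to the per-arm
net-benefit-maximum form for two strategies. Population EVPI discounts
every year 1..T at 3.5% (no undiscounted year 0); defaults are 5,580
eligible patients/year (60% of 9,300 annual incident cases) over 10
years. The WTP grid runs 0–50,000 in steps of 100 — fine enough that
CEAC interpolation error is negligible, coarse enough that the full
sweep is instantaneous.

## Parametric PSA

Candidate families: normal, gamma, Weibull, lognormal, all fitted by
maximum likelihood with location pinned at zero for the positive
families, so every candidate has two free parameters and AICs are
comparable; ties break toward fewer parameters, then lexicographic
name. Cost vectors containing exact zeros are fitted as a zero point
mass plus a positive-family fit (gamma/Weibull/lognormal exclude 0 from
their support). QALYs are fitted through their complement to the
0.417 ceiling; exact-zero complements are shifted by half the smallest
positive complement to avoid −∞ log-likelihoods, and samples are
back-transformed with clamping to [0, 0.417]. Costs and effects are
sampled independently within arm; no cost-effect dependence is
propagated (documented limitation). Note the PSA pair cloud carries
*patient-level* variability, whereas the bootstrap cloud carries
uncertainty in *arm means*; the two quantify different things and the
PSA's CEAC/EVPI are correspondingly more dispersed.

## Survival analysis

Kaplan–Meier processes tied events before censorings; Greenwood
variance accumulates d/(n(n−d)). The reverse-KM median CI uses log-log
transformed bands. RMST variance is the integrated-Greenwood form
Σ [∫_{t_j}^τ S]² d_j/(n_j(n_j−d_j)); the difference test is a normal
z-test. Weighted log-rank weights use the pooled left-continuous KM
(standard Fleming–Harrington). The max-combo reference distribution is
a permutation of arm labels (default 10,000 permutations; p-value
(1 + exceedances)/(1 + n_perm), Monte-Carlo SE reported); a Gaussian
approximation is not used because the permutation test is
assumption-free and directly testable for type-I calibration. Days
convert to years at 365.25. Life-years-gained discounting applies the
annual factor (1+r)^−(t−1) to the incremental area accrued in year t —
year 1 undiscounted, consistent with a year-1 €/LYG ratio that equals
ΔC divided by the raw year-1 RMST difference. The 6-year incremental
cost is carried over unchanged from the 5-month analysis under the
assumption that post-trial costs are independent of arm.

## Reproducibility and problem sizes

One master seed drives every stochastic stage through labeled
substreams (CRC-32 of the stage name mixed into the seed sequence), so
stage results do not depend on execution order and reruns are
bit-identical; the provenance manifest records the configuration hash
and seed but not wall-clock timings (which would break bitwise
comparison) or the output directory. Simulation-based tests use desk
scales chosen for tight-but-fast inference: 5,000 patients/arm for
moment recovery, n = 2,000 for the RMST closed form, 200 random
datasets for the log-rank oracle equivalence, 500 null replicates at
2,000 permutations for max-combo calibration, 30 replicates at
n = 5,000 for AIC model-selection recovery, and 120 simulated trials
for LRT/bootstrap type-I checks.

## Known limitations

- The EORTC-to-utility mapping is a hook (`MappingSpec`) for
  user-supplied coefficients; no published coefficient set is bundled.
- Bootstrap on imputation-averaged QALYs understates imputation
  uncertainty (see above).
- No covariate-adjusted survival models, no EVPPI/EVSI, no more than
  two strategies, no societal costs.
- Permutation p-values are exact only up to Monte-Carlo error; very
  small p-values are bounded below by 1/(1 + n_perm).
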