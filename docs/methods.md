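# Methods

`t2dmace` implements, end to end, a registry-style cohort analysis of
first-time major adverse cardiovascular events (MACE) after a new type 2
diabetes diagnosis, together with a synthetic-registry generator whose
analytic ground truth makes every stage testable.  This note records the
models, the conventions the source registers leave open, the numerical
choices, and what the synthetic data do and do not establish.

## Study design being emulated

Individuals enter at their first HbA1c measurement of 48–57 mmol/mol
(6.5–7.4%), aged 40–80, with no prior glucose-lowering drug treatment
(GLDT, ATC A10), no prior diabetes diagnosis, no condition invalidating
HbA1c (eGFR < 30 ml/min per 1.73 m², haemoglobin < 6.83 mmol/l, and a
configurable code list), and no statin (C10AA) or RASi (C09) redemption in
the 180 days before the first measurement.  Follow-up starts at the
**index date**, 180 days after the first measurement (365 in a sensitivity
configuration), where participants are classified into four exposure
groups by GLDT initiation and the most recent qualifying HbA1c
(post-GLDT measurements only, once GLDT has begun):

| group | GLDT | latest HbA1c |
|---|---|---|
| `WC_GLDT` (reference) | yes | < 48 |
| `PC_GLDT` | yes | ≥ 48 |
| `REMISSION` | no | < 48 |
| `PERSISTENT` | no | ≥ 48 |

The outcome is the first of myocardial infarction, stroke or all-cause
death; follow-up ends at MACE, emigration or the administrative end of
study.  The **mediators** are binary statin and RASi initiation in the
exposure window (first measurement, index date].

## Estimands and estimators

For exposure level $a$ and horizon $t = 5$ years, the standardized
absolute risk under a mediator regime $\pi$ is the g-computation average

$$\Psi_a^{\pi} = \frac1n \sum_{i=1}^n \sum_{m_1,m_2\in\{0,1\}}
  \pi_1(m_1\mid L_i)\,\pi_2(m_2\mid L_i)\,
  \bigl\{1 - e^{-\Lambda_0(t)\exp(x_i'(a,m_1,m_2)\beta)}\bigr\},$$

always averaging over **all** included individuals.  The nuisance models
are: (i) eight logistic propensity models, $p_g(m=1\mid L)$, one per
(exposure group, mediator); and (ii) a single Cox model for MACE with
exposure contrasts, both mediators, full exposure × mediator interactions
(each group keeps its own mediator effects) and the adjustment covariates
$L$: age (5-year bands), sex, cohabitation, income quartile, ethnicity,
requester of the first HbA1c, first-HbA1c band, eGFR band (with an
explicit `unknown` level), and heart failure / atrial fibrillation /
COPD-asthma / cancer flags.  $\Lambda_0$ is the Breslow baseline.

Reported quantities:

* $\Psi_a^{\text{obs}}$ — within-group regime ($\pi = p_a$);
* total-effect differences $\Psi_a^{\text{obs}} - \Psi_{\text{ref}}^{\text{obs}}$;
* interventional indirect effects
  $\Delta_a = \Psi_a^{\text{obs}} - \Psi_a^{\text{ref}}$, where the
  reference regime draws the selected mediator(s) (both, statins only, or
  RASi only) from the reference group's propensities.

Two compute paths give the same estimand.  The default enumerates the
four mediator combinations exactly.  The Monte Carlo path redraws
mediators $R = 200$ times and averages; draws are shared (common random
numbers) across regimes and exposure levels by default, which leaves each
$\Psi$ unchanged but shrinks the Monte Carlo variance of contrasts; a
fresh-draws mode exists.  95% CIs are percentile intervals from $B =
1{,}000$ bootstrap resamples of individuals, refitting the entire model
pipeline per resample.

## Synthetic registry

The generator emits four raw tables (persons, labs, prescriptions,
diagnoses) on a day grid anchored at a fixed synthetic origin
(2014-01-01), with entry dates uniform over a 7-year inclusion window and
administrative censoring at a fixed end-of-study day, mirroring a
2014–2020 inclusion period followed through early 2022.  Covariates are
drawn from independent marginals; GLDT initiation and HbA1c normalisation
are logistic in the covariates and define the group structure; mediators
are Bernoulli with group-specific logistic propensities (independent given
covariates, matching the two separate propensity models; a Gaussian-copula
correlation knob exists, default 0); event times are inverse-transform
draws from a constant or Weibull baseline hazard under the configured
log-hazard ratios; emigration is exponential and independent.

Default parameters were chosen once to resemble the published setting:
four-group shares near 22/15/38/25%, statin uptake ≈ 42–45% on GLDT vs
11–14% off GLDT (RASi ≈ 26–28% vs 13–14%), a constant baseline hazard of
0.013/year giving an overall 5-year MACE risk around 10–15% with rising
age effects, and protective mediator effects (statin HR ≈ 0.74, RASi ≈
0.84) with zero interactions.  These are plausibility choices, not
calibrated estimates — the source data cannot be shared, so no real-data
fit is possible.

Because the covariates are discrete and the mediators binary,
`true_standardized_risks` computes the population $\Psi$ and $\Delta$
**exactly** by enumerating the covariate product grid (weights are
products of the marginals) and the four mediator combinations, for
constant or Weibull baselines.  This oracle is what recovery and coverage
tests compare against.

What the synthetic data do *not* emulate: real coding dialects, duplicate
or erroneous records, correlated covariates, time-varying hazards or
mediator processes, informative censoring, and misclassification.
Passing tests therefore demonstrate the *estimator machinery* is correct
under the stated assumptions, not that those assumptions hold in any real
register.

## Conventions and numerical choices

* Windows: exposure/mediator window is half-open left, closed right —
  (first measurement, index]; a redemption on the index date counts, one
  on the first-measurement date counts as prior use.  Lab lookback for
  eGFR/haemoglobin is the 180 days up to and including the first
  measurement; comorbidity lookback is 10 years before the index date.
* Ties: same-date HbA1c values resolve to the last record in stable input
  order; MACE components on one day take precedence MI > stroke > death
  (death never masks a same-day cardiovascular code); an event on the same
  day as a censoring counts as an event; in the nonparametric estimators
  events precede censorings at tied times.
* Time: 365.25 days/year; five years = 1826.25 days; the index offset is
  exact days (180/365).
* Cox fitting uses Efron's tie correction (day-granular registry times are
  heavily tied) maximized by Newton iterations with step-halving on a
  centered design; the Breslow baseline is computed on the raw design.
  Zero-variance columns are dropped (coefficient 0); with an empty design
  the baseline reduces to the Nelson–Aalen estimator.  Monotone likelihood
  (a level with no events) raises an error on a primary fit.  Inside the
  bootstrap a stabilization ladder retries with small ridge penalties
  (1e-2, then 1e-1), because at n ≈ 1,000 rare interaction cells lose all
  their events in a large fraction of resamples; resamples that still fail
  are dropped and counted, and more than 10% failing is an error.
* Propensity fits walk maximum likelihood → ridge-stabilized →
  empirical-proportion fallback; a group with zero or full uptake uses the
  empirical proportion with a logged warning.  Quasi-complete separation
  (a dummy level with constant outcome) is detected by a cross-tab
  pre-check and routed directly to the ridge rung.  Predicted
  probabilities are clipped to [1e-12, 1 − 1e-12].
* The 2×2 mediator mixture is evaluated in interaction form,
  $r_{00} + p_1(r_{10}-r_{00}) + p_2(r_{01}-r_{00}) + p_1p_2(\cdots)$, so
  that null mediator effects yield exactly zero indirect effects in
  floating point.
* Solvers are in-package vectorized Newton implementations; tests verify
  them against statsmodels (logistic), lifelines (Cox coefficients,
  standard errors and Breslow baseline, to 1e-6) and a brute-force
  partial-likelihood maximization on tie-free data.  The nonparametric
  estimators are computed directly from the event table and checked
  against lifelines (on tie-free samples for the Aalen–Johansen
  comparison, whose lifelines implementation jitters ties).
* Seed policy: one master seed spawns independent substreams (below
  2³¹) for simulation, Monte Carlo draws and the bootstrap; all seeds are
  echoed in the outputs, and a full run is byte-reproducible.
* Treatment-uptake curves (Aalen–Johansen with MACE competing) start the
  clock at the first elevated HbA1c and report the proportion at
  index-offset + 1 year; the generator includes post-index initiation
  processes so these curves carry information past the index date.
* Missing values become explicit levels (`unknown` eGFR band and income)
  rather than dropping rows; baseline-table percentages are computed among
  complete data, with `unknown` rows reported as counts.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to keep the full run on
one CPU comfortably inside a coffee break while retaining statistical
power: oracle-equivalence on a fixed n = 500 cohort (50 × R = 200 Monte
Carlo replicates, plus R = 10,000), Cox recovery at n = 5,000 and
propensity recovery at n = 20,000 per group over 20 seeds, indirect-effect
recovery at n = 10,000, and bootstrap coverage over 200 datasets of
n = 1,000 with B = 200.  The acceptance script runs the full pipeline at
n = 14,000 with B = 1,000.

## Known limitations

* Statin and RASi draws are independent given covariates; no joint
  mediator model.
* The interventional estimand is for *initial* treatment only; no
  time-varying mediator or exposure processes.
* No natural direct/indirect effects (they need cross-world assumptions);
  no proportional-hazards diagnostics, frailty or time-varying
  coefficients.
* Exclusion code lists are editable approximations in configuration, not
  validated register lists.
* Percentile (not BCa) bootstrap; near-null effects therefore overcover,
  which is visible for the `PC_GLDT` group in the default configuration.
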