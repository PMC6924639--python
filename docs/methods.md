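# Methods

This note records the model as implemented: its assumptions, parameter
conventions, numerical choices, and the places where a design decision was
genuinely open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Polygenic risk distribution

Relative risk of prostate cancer is log-normal, `log r ~ N(μ, σ²)` with
`σ² = 0.68` (the variance implied by the known susceptibility loci under
log-additive interaction). The location is not a free parameter: we fix
`μ = −σ²/2` so the population mean relative risk is exactly 1. This makes
total incidence conservation across risk strata an identity rather than a
calibration, and it reproduces the published eligibility fractions (11.4%
of 55-year-olds and 50.5% of 69-year-olds at a 5% threshold) from the
published background risks with no further tuning.

Everything downstream is closed-form normal arithmetic:

* percentile relative risk: `exp(μ + z_p σ)`;
* case (size-biased) distribution: `log r ~ N(μ + σ², σ²)`, so the case
  mass above the population `q`-quantile is `Φ(σ − z_q)`;
* eligibility at threshold `t` with baseline `b`: individual absolute risk
  is modelled as `b·r`, so the eligible fraction is
  `1 − Φ((log(t/b) − μ)/σ)`. Absolute risk scales linearly in `r`;
  competing-risk nonlinearity at the individual level is ignored (the
  life table handles competing risks at the stratum level);
* stratum relative risks: case mass over population mass above/below the
  cut; the conservation identity `f·RR_s + (1−f)·RR_u = 1` then holds to
  rounding.

The oracle tests validate these closed forms against adaptive quadrature
(absolute tolerance 1e-10) and a 10⁷-draw Monte-Carlo ratio estimator.

Known limitation: published first/99th-percentile relative risks (0.09,
5.52) and the "7% of cases in the lowest quintile" figure derive from an
empirical SNP distribution, not from the pure log-normal model, whose
closed forms give 0.105, 4.85 and 4.8%. We do not force agreement; the
log-normal model is used consistently throughout.

## Life table

An annual-cycle cohort model follows each single-age cohort from entry to
age 90; the mixed cohort is fifteen single-age sub-cohorts (entry ages
55–69) weighted by population counts and summed. Cycle length is one year
with no half-cycle correction; within a cycle transitions apply in the
order incidence → prostate-cancer death → other-cause death. Life-years
count the population alive at the start of each cycle.

Rates are per person-year population rates in the registry/DevCan
convention. In particular, prostate-cancer mortality applies to the whole
alive (non-overdiagnosed) population, not only to the diagnosed — the
rate already embeds the population's diagnosis history. Overdiagnosed
cases are routed to other-cause death only: by definition they never die
of prostate cancer, but they do accrue diagnosis and treatment costs and
the post-diagnosis utility decrement.

The cohort is partitioned into three strata: attenders (screened),
eligible non-attenders (precision arms with uptake < 1: genotyped,
carrying the eligible stratum's relative risk, but receiving no screening
effects) and the ineligible remainder. Eligibility is absorbing; newly
eligible men move out of the ineligible healthy pool at their crossing
age.

**Hazard renormalisation.** Registry rates are averages over the
population risk mixture. Stratum hazards are therefore renormalised each
cycle so that the risk-weighted mean hazard over the surviving pool
equals the registry rate, separately for the healthy and the diagnosed
pools (their risk compositions diverge as cases accrue). Without this, a
heterogeneous-population run would drift below the homogeneous registry
projection through depletion of susceptibles, and the three scenarios
would disagree even with all screening effects switched off. With it,
setting `rr_incidence = rr_mortality = 1` and zero overdiagnosis makes
all scenarios' case and death counts identical to machine precision — a
property the test suite asserts.

**Screening effects.** The screened stratum's incidence is multiplied by
1.23 while organised screening is ongoing; its prostate-cancer mortality
is scaled by 0.79 from first screen onward, persisting after screening
stops at 69 with no onset lag (an ERSPC-style effect carried forward; the
evidence is silent on lags). Stage shift multiplies the advanced-stage
share of screen-detected cases by 0.85 and feeds only the treatment-mix
costing. Overdiagnoses are screen-detected cases (incident cases in the
actively screened stratum during screening ages — the broadest internally
consistent reading) times `clamp(−0.62 + 0.014·age, 0, 1)`.

**Opportunistic testing.** Registry incidence is deflated by 10% in all
scenarios to strip cases attributable to pre-existing opportunistic PSA
testing; screening effects multiply the adjusted baseline. The sign of
this adjustment is ambiguous in the source evidence; deflation of the
registry rate is the direction consistent with "the registry already
contains opportunistically detected cases", and the fraction is a single
configurable field. Background 10-year absolute risk, by contrast, is
computed from the rate table as given, so the synthetic calibration
anchors refer to the unadjusted table.

**10-year absolute risk** is the discrete competing-risk cumulative
incidence `Σ_t p_inc(a+t)·S(t)` with `S` the probability of reaching year
`t` alive and undiagnosed (all-cause mortality competes). The annual
convention carries a small upward discretisation bias relative to a
continuous-time daily-step cohort: about 1e-4 absolute at age 55 on the
synthetic table, growing to ~1e-3 at 69 where mortality is higher (always
< 1.5% relative). The tests assert those measured bounds.

## Strategies

Age-based screening: PSA tests at start age and every `interval` years
(default 4) to the stop age, for every attender. Precision screening: at
each age the cumulative eligible fraction is the risk-model tail above
the threshold at that age's background risk, monotonised by running
maximum (once eligible, always eligible); each man starts quadrennial
screening at his crossing age, in whole years. Uptake scales attendance
uniformly. The whole cohort is genotyped once, when risk assessment
begins. Threshold limits degenerate correctly: a threshold everyone
clears reproduces age-based screening, an unreachable threshold
reproduces no screening (both asserted on the synthetic table).

## Economics

Utility is `max(0, 0.8639 − 0.0048·(age − 55))` — the anchor age of 55 is
a package choice; the source gives a value and a slope but no anchor —
multiplied by 0.93 during the ten years from diagnosis (diagnosis year
inclusive). Costs and QALYs discount at 3.5%/year with
`t = attained age − entry age`, so each sub-cohort's entry year is
undiscounted.

Treatment and follow-up costs are charged as a lump sum in the diagnosis
year (the published unit costs already bundle 5–10 years of follow-up):
staging plus the stage-mix expectation, with the screen-detected (and
overdiagnosed) stage distribution shifted by the 0.85 advanced-stage RR.
Palliation (£6,837) is charged in the year of prostate-cancer death. The
biopsy cascade charges every screen positive a biopsy at baseline
(per-screen positivity is a required input; the synthetic default is a
flat 0.12 across ages, which is *not* a published value); the
declined-biopsy path (£105) activates only when biopsy compliance is set
below 1 in adherence sensitivity analyses. Clinically detected cases are
costed from staging onward.

## Probabilistic sensitivity analysis

One draw is one coherent parameter set reused across all strategies
(common random numbers), so incremental quantities are within-draw
differences. Distributions:

* Relative risks: log-normal with the mean preserved at the point
  estimate and log-SD recovered from the published 95% interval,
  `σ = log(hi/lo)/(2·1.96)`. The published per-parameter "SE" values
  (0.06, 0.18, 0.07) are inconsistent with the published intervals for
  the incidence RR (SE 0.18 would give a 0.86–1.75 interval against the
  published 1.03–1.48), so the intervals are treated as authoritative.
  The recovered intervals match the published ones to within ~1% (tested
  at 200,000 draws).
* Unit costs: Gamma with the published (shape, scale) pairs taken
  verbatim, even where shape·scale differs from the printed mean by a few
  per cent (e.g. PSA test: 33.9 × 0.3 = 10.17 against a printed £11);
  documented rather than re-fitted.
* Utilities: `0.83 + Gamma(4, 0.06)·0.167` (general population) and
  `0.88 + Gamma(5, 0.05)·0.2` (post-diagnosis multiplier), both clamped
  to [0, 1].
* Overdiagnosis proportion: a Beta perturbation of each age's clamped
  point value, moment-matched to mean = point and SD = 0.001, driven by a
  single common uniform quantile per draw so all ages move coherently.

Summaries are percentile-based 95% intervals; ICERs are ratios of mean
increments. Two acceptability curves are exposed and deliberately named
apart: `ceac()` is pairwise versus no screening (probabilities need not
sum to 1 across strategies) and `ceaf()` is the frontier probability of
having the highest NMB (sums to 1). Defaults: 10,000 draws, seed 42.

All scalar parameters broadcast as draw-length arrays through the life
table and economics, so a full PSA is a single vectorised pass per
strategy; 2,000 draws across the 19-strategy grid complete in well under
a minute on one CPU (asserted, generously, in the test suite).

## Synthetic data

The generator emulates the structure of the unavailable national inputs:
Gompertz other-cause mortality (level 0.002 at 45, log-slope 0.0866/year
≈ doubling every 8 years), logistic prostate-cancer incidence (midpoint
66.5, scale 6 years) rising to a plateau, prostate-cancer mortality a
0.35 fraction of the incidence hazard lagged 5 years, and entry weights
declining 1%/year across ages 55–69, summing to 4.48 million. The
incidence plateau is the single calibrated parameter: 1-D root finding
(Brent) against the published 2.6% background 10-year risk at 55; the
7.1% anchor at 69 is then checked against the band [0.066, 0.076], not
fitted, and generation fails loudly if the shape violates it.

What passing tests on synthetic rates do **not** show: agreement of
absolute counts (cases, deaths, costs) with analyses run on the real
registry tables. The synthetic incidence plateaus rather than declining
after the late 70s, which pushes diagnoses later and changes every
absolute total; the structural properties (conservation, limit
equivalences, monotonicities, oracle agreement) are what the suite
establishes. Supply a real rate CSV
(`age,pc_incidence,pc_mortality,other_mortality,population_weight`) to
reproduce registry-based results.

## Numerical conventions and degenerate inputs

* Probabilities are clipped to [0, 1] after every multiplication of a
  rate by relative risks.
* Population conservation (alive + cumulative deaths = cohort) is checked
  every cycle inside the engine at 1e-6 of the cohort and raises on
  violation.
* Degenerate strata (eligible fraction numerically 0 or 1) raise an
  explicit error from `stratum_relative_risks`; the schedule builder
  substitutes relative risk 1 for empty strata, which never enter the
  life table with positive mass.
* Beta perturbation of an overdiagnosis proportion of exactly 0 or 1 (or
  an infeasible variance) passes the point value through unchanged.
* All randomness flows through `numpy.random.default_rng(seed)`; fixed
  seeds give bit-identical PSA summaries (asserted).

## Known limitations

* Cohort-level strata, not individual natural history: no PSA growth, no
  sojourn-time model, no stage-specific survival; screening intervals do
  not vary with risk.
* The mortality benefit is applied without an onset lag and persists
  after screening stops; both choices favour screening arms slightly.
* Overdiagnosis is assumed independent of polygenic risk in the base
  case.
* The utility decrement is a single multiplier for ten years regardless
  of stage or treatment.
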