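# Methods

## Outcome definitions

Classification uses the internationally standard definitions, all
strict inequalities and all configurable (`ClassificationConfig`),
because facility practice varies in charts and cut-offs:

| outcome | rule | default |
|---|---|---|
| low birthweight | livebirth, birthweight < threshold | 2,500 g |
| preterm birth | livebirth, gestational age < threshold | 259 d (37 completed weeks) |
| small for gestational age | livebirth, birthweight < sex/GA weight percentile | 10th percentile |
| congenital microcephaly | livebirth, head circumference < sex/GA cut-off | 3rd percentile (−2 SD / −3 SD selectable) |
| stillbirth | fetal death, GA ≥ viability floor | 196 d (28 weeks); GA-missing counts as stillbirth by default |
| neonatal death | death day 0–27 after livebirth | fixed 28-day period |
| neonatal infection | recorded diagnosis of bloodstream / meningitis / respiratory infection | — |

Gestational age is stored in days; reference lookups interpolate
linearly between whole-week rows and, by default, clamp ages outside
the 24–42-week span to the nearest endpoint.  A record missing an input
for a rule gets no label for that outcome and is tallied as
unassessable, but stays in the denominator — surveillance denominators
are all livebirths (all births for stillbirth), not the assessable
subset.

## The growth reference

The packaged reference grid
(`data/growth_reference_synthetic.csv`) is synthetic: a smooth
median/SD grid for birthweight and head circumference by sex and
completed week (24–42), with the weight 10th percentile at
median − 1.2816 SD and the head-circumference 3rd percentile at
median − 1.8808 SD.  It has the shape and ordering properties of
published intrauterine charts but represents no specific chart;
analyses of real data should load the locally applicable reference with
`GrowthReference.from_csv`.

## The synthetic cohort generator

`simulate_site` draws, per birth, independently given the profile:

- **Cohort size**: `round(annual_births × duration_weeks / 52)`;
  optionally Poisson with that mean (fixed is the default so counts are
  reproducible).
- **Gestational age**: a term/preterm mixture with weight
  `preterm_prob`.  Term: truncated normal, mean 276 d, SD 8 d on
  [259, 294].  Preterm: 259 − d with d exponential (mean 16 d)
  truncated so GA stays at or above the site's registration floor
  (default 154 d).  Registered stillbirths draw their preterm component
  above the 28-week stillbirth floor, so the delivery outcome and the
  classification rule agree by construction.
- **Anthropometry**: birthweight and head circumference are normal
  around the reference median at (sex, GA) with the reference SD.  This
  makes the true SGA prevalence ≈10% and the true microcephaly-by-p3
  prevalence ≈3% of livebirths by construction — a consequence of
  percentile-based definitions, not a tunable rate.  An excess fraction
  (`microcephaly_excess_prob`) of heads is redrawn from below the 1st
  percentile to emulate pathological microcephaly.
- **Events**: stillbirth (per total birth), neonatal death and
  infection (per livebirth) are Bernoulli at the configured
  probabilities; death day follows a truncated geometric favouring the
  first days of life; one infection subtype per case, drawn from the
  profile's 3-way mix.
- **Missingness**: each measurement is independently blanked at its
  per-measure probability.

`apply_site_ascertainment` then derives the true labels with the
classification rules and flags each true case with the per-outcome
sensitivity (non-cases with the false-flag probability), independently
across outcomes.  Everything is driven by one `numpy` generator per
call, so identical (profile, seed) gives byte-identical line lists.

What the generator does **not** emulate: referral networks and
case-mix differences between facility levels, seasonality, epidemic
disruption, twinning, correlated under-reporting across outcomes, and
correlated missingness.  Passing tests therefore demonstrate that the
analysis machinery is correct under the stated sampling model, not that
it is robust to those real-world features.

The packaged 21-site fixture (`data/site_profiles.yaml`, generated from
`data/site_counts.csv` and `data/ascertainment_counts.csv`) transcribes
a published multi-country network: annual loads 862–10,554 births,
per-outcome event rates in the published ranges, and per-outcome
ascertainment sensitivities from its post-amendment sensitivity
analysis.

## Exact intervals

Clopper–Pearson bounds come from beta quantiles (`scipy.stats.beta`);
the equivalent binomial tail-sum inversion (root-finding on
`binom.sf` / `binom.cdf`) lives in `perisurv.verification` as an
independent oracle and agrees to better than 1e-9 for all n ≤ 200.
Rates are computed on unrounded proportions, scaled by 1,000 last, and
displayed at one decimal, rounding half away from zero.  Whether a
published table rounded half up or half to even at an exact .05
boundary is generally unknowable; knife-edge cells could disagree in
the last digit.

## Minimum detectable risk

The power function is the classical two-proportion normal
approximation — pooled variance under the null, unpooled under the
alternative, no continuity correction.  This choice reproduces the
published large-site planning values to two decimals.  Group sizes are
kept fractional (a planning approximation, not an enrolment plan).

The inversion brackets the smallest ratio with power ≥ target on
(1, cap] and solves by bisection to 1e-6; the cap is 100 (and
additionally RR < 1/p0 for the cohort design, since RR·p0 must stay
below 1).  When even the cap does not reach the target power the result
is an explicit not-reached sentinel (`point = inf`, `reached = False`)
rather than an arbitrary large number.  Zero observed events have no
finite detectable effect and raise.

Confidence bounds substitute the exact rate bounds for the point rate
and re-invert: the upper rate bound (more information) gives the lower
bound of the detectable effect.  Published intervals for these planning
quantities are not described operationally anywhere we know of; the
rate-bound substitution is the natural reading of "exact interval" and
is labelled as such.

Two caveats for users comparing against published planning tables:
aggregated-only sites (monthly summary submission, no line list) can
carry rate inputs that are not reconstructible from per-site counts —
for the two such sites in the packaged network the published cohort
MDRR values (2.58, 4.56) are not reproducible from their printed counts
under the stated assumptions, while their case-control values are; the
package computes from counts and documents rather than guesses.  And
small-site values can differ by ±0.01–0.02 depending on the exact power
formula, which published tables typically do not state.

## Problem sizes in tests

The test suite runs the full oracle sweep (all n ≤ 200), 2,000-draw
coverage simulations at three event rates, 100,000-rep Monte-Carlo
power checks at three design points, 50 randomized bisection-vs-grid
comparisons, and a 100-seed simulate→classify→estimate recovery study
at 5,500 annual births — sizes chosen so the whole suite completes in a
few minutes on one core while keeping Monte-Carlo error well below the
tolerances being asserted.

## Known limitations

- The generator's independence assumptions (outcomes, flags,
  missingness) are simplifications; capture-recapture or correlated
  missed-case models are out of scope.
- No pooled or meta-analytic rates across sites: facility-based rates
  are site-specific by design and are not population-representative.
- No exact (unconditional/conditional) power methods, matched designs,
  survival endpoints, or multiplicity adjustment.
- GAIA diagnostic-certainty adjudication of individual cases is out of
  scope; classification here is purely measurement-rule based.
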