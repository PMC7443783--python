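# Methods

## The burden model

The package computes incidence-based DALYs for a chronic, incurable
condition observed through claims records. Each incident patient
contributes

    YLD = B(a_onset, e(a_onset), D)
    YLL = B(a_death, e(a_death), 1)        (only if the disease caused death)
    DALY = YLL + YLD

with the general burden integral

    B(a, L, D) = D ∫ₐ^(a+L) [K·C·x·e^(−βx) + (1−K)] e^(−r(x−a)) dx.

Two presets parameterise it:

| parameter | harvard1994 | gbd2015 | meaning |
|---|---|---|---|
| K | 1 | 0 | age-weighting toggle (any value in [0,1] is allowed) |
| C | 0.16458 | — | age-weight level, dimensionless |
| β | 0.04 /yr | — | age-weight decay rate |
| r | 0.03 /yr | 0 | continuous discount rate |
| life table | sex-specific, e(0)=80.0 M / 82.5 F | sex-invariant, e(0)=91.9 | source of e(a) |

The closed form uses integration by parts with μ = β + r:

    ∫ₐ^(a+L) x e^(−μx) dx = [e^(−μa)(μa+1) − e^(−μ(a+L))(μ(a+L)+1)] / μ²

multiplied by `K·C·e^(ra)` (folded into the exponentials as `e^(−βa)` to
avoid overflow at large `r·a`), plus `(1−K)(1−e^(−rL))/r` for the
unweighted term. The `r = 0` and `μ = 0` limits are taken analytically
rather than by epsilon substitution, so the gbd2015 preset returns exactly
`D·L` and the undiscounted weighted case is exact. An adaptive-quadrature
evaluation of the same integrand (`burden_integral_quad`, via
`scipy.integrate.quad`) is kept as a numerical cross-check; the test suite
verifies agreement to 1e-8 relative across randomized `(a, L, K, r, β)`
including both limits.

### Modelling choices where the convention is genuinely open

* **Continuous discounting** `e^(−r(x−a))`, not annual compounding: the
  standard reading of "3% per year" in the 1994 framework.
* **Age weighting applies to YLD as well as YLL** by default; the
  alternative (weights on mortality only) is exposed as
  `MethodSpec.age_weight_on_yld` / the `age_weight_on_yld` run flag, since
  analyses differ on this point. Discounting always applies to both.
* **Recorded integer ages are used as exact onset/death ages** — no
  mid-year +0.5 shift. Configurable only by editing the input ages; the
  pipeline does not second-guess the records.
* **YLD is not truncated at death.** A patient who dies in-year still
  accrues YLD over the full remaining life expectancy at diagnosis, and the
  death adds YLL on top. With ~3 deaths per 196,003 cases this double
  counting is negligible, but it is a property of the definition, not a bug.
* **Death-cause rule**: only deaths with an osteoarthritis code as the
  *primary* cause trigger YLL by default; contributory causes are included
  with `contributory_deaths=True`.

## Life tables

The authentic West level-26 and GBD-2050 tabulations are not redistributed;
the bundled tables are Gompertz-survivorship stand-ins
`S(x) = exp(−(B/θ)(e^(θx) − 1))` with slope θ = 0.1/yr (typical of modern
low-mortality schedules) and level `B` solved by Brent's method so that
`e(0)` matches the anchor (80.0 / 82.5 / 91.9) to within 0.05 years.
`e(a) = ∫ₐ S(x)dx / S(a)` is evaluated on a 0.05-year grid (trapezoid) and
tabulated at integer ages 0–110; where survivorship numerically vanishes
(low-`e(0)` configurations) the tabulation is truncated at the last age
with `S > 1e-12` so the terminal entry stays positive. These tables satisfy
the structural invariants enforced on every `LifeTable` — strictly
increasing ages, `e(a) ≥ 0`, non-decreasing expected age at death
`a + e(a)`, positive terminal entry — and users can substitute authentic
tables via `age,sex,ex` CSV files; the choice of table changes absolute
DALY totals but not the package's rate arithmetic or the weight-ratio
identities.

Between tabulated ages, `e(a)` is linearly interpolated; outside the table
it clamps to the nearest entry. These are the simplest defensible choices;
published analyses rarely state theirs.

## Cohort pipeline

Selection keeps attention records with an M15–M19 code, age ≥ 15
("older than 15" is implemented inclusively because the first reporting
band is 15–44; `min_age` is a parameter), outpatient or emergency setting
(hospitalisation excluded), no prior treatment, and a visit date inside the
analysis year, then deduplicates to each patient's earliest eligible visit
(same-day ties: outpatient before emergency, then lexicographically first
code, which orders hip M16 < knee M17 < first-CMC M18 < unspecified M19 —
an arbitrary but deterministic tie-break). Every excluded row is counted
against the first rule it failed, and the counts reconcile exactly with
`input rows − selected patients`.

Osteoarthritis type comes from the single deduplicated code: M16 hip, M17
knee, M18 first carpometacarpal, M15/M19 pooled as poly/unspecified — the
pooling the source system's reports use. Rates are per 1000 insured,
rounded half-up to one decimal (`Decimal`-based, so 0.05 → 0.1); DALY
totals are reported as integers while all internal arithmetic is
unrounded. Stratified DALY sums over any complete partition (sex, age
band, type, network) conserve the total to 1e-6 before rounding; printed
tables may disagree with their own totals by ±1 after rounding.
Osteoarthritis-type strata share the whole-population denominator (a
patient of any type can arise from any insured person); care-setting
strata have no population denominator and carry no rates.

## Synthetic cohorts

The generator emulates the 2016 EsSalud osteoarthritis cohort's published
marginal structure, and its defaults are those study conditions: 65.5%
female; age bands 15–44 / 45–59 / ≥60 at 15.4% / 30.0% / 54.6%, with ages
drawn truncated-normal(60.9, 15.1) *within* the sampled band (so band
shares are matched exactly in expectation while the mean/SD are honoured
approximately — band shares are what the stratified tables consume); type
mix 62.6 / 31.0 / 5.9 / 0.5% with the poly/unspecified mass split evenly
between M15 and M19 (the source never separates them); network mix
45.3 / 27.0 / 23.5 / 4.2%; 5% emergency; death probability 3/196,003 with
primary-cause certificates dated after the visit. Denominators scale the
2016 insured counts (total 10,937,079) proportionally to the requested
population, preserving the sex and network sums exactly; age-band
denominators cover insured aged 15+ only and deliberately do not sum to the
total, as in the real population table. Everything is drawn from a single
seeded `numpy.random.Generator`, so equal seeds give byte-identical files.

What the generator does **not** model: the joint distribution of sex × age
× type × network (independence is assumed and stated in the manifest),
within-year revisit patterns, comorbidity, non-osteoarthritis mortality,
and any secular trend. Passing tests on synthetic cohorts therefore
demonstrate the pipeline's arithmetic, bookkeeping and invariances under
the published marginals — not that the package reproduces the original
record-level totals, which would require the deposited workbook and the
authentic life tables.

A corruption variant injects ineligible rows (inpatient, prior-treatment,
under-15, non-osteoarthritis codes) at configured rates with a manifest of
exact counts, so selection tests can assert per-rule exclusion tallies.

## Problem sizes and numerics

The default test run uses cohorts of 1.5k–10k records and a 50k-record
cohort for the conservation property; the acceptance script measures the
weight-sensitivity ratio on a 20k-record zero-death cohort. The ratio is
scale-free (it is algebraically 0.28/0.165 whenever YLL = 0), so cohort
size affects only runtime. Quadrature cross-checks run with
`epsabs = epsrel = 1e-12` against a 1e-8 relative assertion; Gompertz
calibration uses `xtol = 1e-10` on `log₁₀ B`.

## Known limitations

* Absolute DALY totals depend on the life table; with the stand-in tables
  they approximate, but do not equal, totals computed from any specific
  published digitisation of West level 26 or the GBD 2050 standard.
* The incidence-based YLD convention is used for *both* methods (as the
  analysis this package operationalises did); true GBD-2015 practice is
  prevalence-based YLD, which is out of scope.
* No uncertainty propagation: inputs are counts and deterministic
  parameters, and the source analysis reported no intervals.
* "Previous treatment" is taken as a flag on the input record; the package
  does not reconstruct it from prior-year history.
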