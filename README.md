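# oaburden

Incidence-based burden-of-disease estimation for osteoarthritis cohorts,
implementing and contrasting two DALY methodologies on claims-record data.

## The problem

Disability-adjusted life years (DALYs) quantify the healthy life a
population loses to a disease: `DALY = YLL + YLD`, years of life lost to
premature death plus years lived with disability. How many DALYs a cohort
"produces" depends strongly on methodological conventions that have changed
over time. The original 1994 framework used sex-specific model life tables
(West level 26, life expectancy at birth 80.0 years for men, 82.5 for
women), weighted ages by `C·x·e^(−βx)` with `C = 0.16458`, `β = 0.04`
(valuing mid-life years above infancy and old age), and discounted future
years continuously at `r = 3%/yr`. The 2015 GBD revision dropped age
weighting and discounting and adopted a single sex-invariant aspirational
life table with `e(0) = 91.9` years. The same cohort can therefore yield
DALY totals differing by a factor of 2–3 depending purely on the method.

This package makes that comparison reproducible for chronic-disease claims
cohorts — specifically osteoarthritis (ICD-10 M15–M19) attention records of
the Peruvian social health insurance system (EsSalud), where both methods
were applied to 196,003 incident patients of 2016 under two disability
weights: 0.165 (GBD, severe lower-limb musculoskeletal) and 0.28 (Peruvian
Ministry of Health, MINSA). It is a library for epidemiologists and health
economists who want per-person burdens, stratified per-1000 rates, and
method-sensitivity ratios from record-level inputs, plus a seeded synthetic
cohort generator so every stage is testable without access to the original
records.

## The model

For a person with onset (or death) at age `a`, duration `L`, and disability
weight `D` (`D = 1` for death), the burden is

    B(a, L, D) = D ∫ₐ^(a+L) [ K·C·x·e^(−βx) + (1−K) ] · e^(−r(x−a)) dx

evaluated in closed form (integration by parts for the weighted term, with
analytic `r = 0` and `β + r = 0` limits, so the GBD preset returns exactly
`D·L`). YLL uses `L = e(a)` at death and `D = 1`; YLD for a chronic,
incurable condition uses `L = e(a)` at first diagnosis, scaled by `D`.
Remaining life expectancy `e(a)` is linearly interpolated from a life
table — bundled Gompertz-survivorship stand-ins calibrated to the anchors
above, or any user-supplied `age,sex,ex` CSV.

## Worked example

```python
from oaburden import (DW_WHO, DW_MINSA, GBD2015, HARVARD1994, RunConfig,
                      SyntheticConfig, compare_methods, generate, run)
from pathlib import Path

paths = generate(SyntheticConfig(n_cases=5000, seed=7)).write("scratch/in")
bundle = run(RunConfig(records=paths["records"], deaths=paths["deaths"],
                       denominators=paths["denominators"], out_dir="scratch/out"))
for cell, total in bundle.summary["total_dalys"].items():
    print(cell, round(total))
```

prints

```
harvard1994_who 10257
harvard1994_minsa 17406
gbd2015_who 27075
gbd2015_minsa 45945
```

i.e. 36.8, 62.4, 97.0 and 164.7 DALYs per 1000 insured on the synthetic
cohort's scaled denominator (279,003 insured) — the same rate structure as
the real 2016 cohort (36.6 / 62.0 / 94.9 / 161.0). `compare_methods(bundle)`
reduces this to the headline ratios: the GBD-2015 method yields ~2.6× the
Harvard-1994 totals on this age mix, and the MINSA weight raises totals by
exactly 0.28/0.165 − 1 ≈ 70% when (as here, with ~3 osteoarthritis deaths
per 196,003 cases) virtually all burden is YLD.

The `examples/` directory holds one narrative script per capability
(burden integral, life tables, full pipeline, method comparison), and the
same pipeline is scriptable from a shell:

```
oaburden generate --out in/ --n-cases 10000 --seed 1
oaburden run --records in/records.csv --deaths in/deaths.csv \
             --denominators in/denominators.csv --out out/
oaburden compare --summary out/summary.json
```

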