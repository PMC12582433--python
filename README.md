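# prevpde

Estimation of the age-, sex- and calendar-year-specific **lifetime
prevalence of a chronic condition** — and the absolute number of people
living with it — from the aggregated tables that registries and statistical
offices actually publish: incidence rates, mortality rates and population
counts on 5-year age groups, plus an initial prevalence profile.

The motivating application is cancer survivorship ("survivor" = anyone
alive with a prior diagnosis, no minimum elapsed time), where prevalence
at the oldest ages, its change over a decade, and the implied headcounts
drive health-care planning.  The package is for epidemiologists and
biostatisticians who have such aggregated inputs and want a validated,
reproducible pipeline rather than a one-off script.

## The model

The theoretical basis is the three-state illness-death model (healthy →
ill, healthy → dead, ill → dead; no remission).  With incidence rate
i(t, a), mortality of the diseased m1(t, a) and general-population
mortality m(t, a) = p·m1 + (1−p)·m0, the lifetime prevalence p(t, a)
satisfies the partial differential equation

```
(∂t + ∂a) p = (1 − p) · i − p · (m1 − m)
```

Along a characteristic line (one birth cohort, constant a − t) the PDE is
an ODE, which the solver integrates with classical Runge-Kutta (default
step 0.1 years).  Cohorts alive at the start year t0 are seeded from an
initial prevalence profile; cohorts born later start healthy (p = 0 at
birth).

Because m1 is rarely observed directly, the default mode derives it from
population **cause-specific** mortality μc (what cause-of-death statistics
report) under two assumptions — all cause-specific deaths occur among the
diseased, and the diseased die of other causes at the non-diseased rate —
giving m1 = μc/p + m − μc, under which the right-hand side reduces to
(1 − p)(i − μc).  A direct-m1 mode is also available.

Every run is validated against two independent references built into the
package: a high-resolution integration of the same cohort ODEs (exact
truth for synthetic scenarios) and a stochastic microsimulation of
individual three-state life histories.

## Worked example

The real inputs of the motivating study are not redistributable, so the
bundled synthetic scenario plays their role: exponential-in-age incidence
with a rising calendar trend, Gompertz background mortality, constant
excess mortality of the diseased, and a population with a baby-boom bump.

```
python analysis/01_generate_inputs.py      # tables + exact truth -> results/inputs/
python analysis/02_estimate_prevalence.py  # PDE pipeline         -> results/estimate/
python analysis/03_survivor_counts.py      # headcounts and totals
python analysis/04_validate_oracle.py      # microsimulation check
```

Step 02 prints (numbers from an actual run):

```
max |estimate - truth|               : 0.0837
max |estimate - truth| where p <= 0.5: 0.0077
estimated prevalence at 85, final year, female: 86.1% (truth 86.7%)
```

i.e. the pipeline recovers the known truth to well under one percentage
point wherever prevalence is moderate; at the oldest ages the 5-year
grouping of the inputs costs a few points (see `docs/methods.md`).  Step
03 prints the survivor totals implied by the synthetic population,

```
both-sex total: 1831527 (2010) -> 2157532 (2019), x1.18
```

and step 04 reports the agreement with 200,000 simulated individuals per
sex:

```
1718/1720 cells (99.88%) within 3*SE + 0.002; max |diff| = 0.03244
verdict: PASS
```

The same pipeline is available as a CLI (`prevpde estimate --config
run.yaml --out results/`, plus `simulate`, `validate`, `report`
subcommands) for use with your own CSV tables; the input schemas are
documented in `prevpde/tables.py`.

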