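# Methods

## Model and governing equation

The package models one chronic, non-remitting condition with the
three-state illness-death model: individuals are healthy, ill (ever
diagnosed), or dead.  Transition rates are the incidence i(t, a), the
all-cause mortality of the non-diseased m0(t, a) and of the diseased
m1(t, a), all per person-year, depending on calendar time t and age a.
The lifetime prevalence p(t, a) — the fraction of those alive at (t, a)
who are or ever were ill — then satisfies

    (∂t + ∂a) p = (1 − p) · i − p · (m1 − m),      m = p·m1 + (1 − p)·m0.

The excess-mortality term is sometimes typeset with an extra (1 − p)
divisor in the literature; expanding m shows p·(m1 − m) = p·(1 − p)·(m1 −
m0), which is the only form consistent with the mixing relation, and that
form is used throughout.

Assumptions worth making explicit:

* **Healthy at birth.**  p(t, 0) = 0 for every cohort born after the start
  year.  For conditions diagnosed at birth this is wrong; for cancer
  registries (which cannot contain undiagnosed newborns) it is essentially
  exact.
* **No remission.**  Once ill, always counted — the definition of lifetime
  prevalence.
* **Closed population.**  No migration; the rates are assumed to apply to
  everyone alive at (t, a).
* **Age truncation at 85.**  Published tables pool everything above 85
  into one open group, so no interpolation node exists beyond the oldest
  closed-group midpoint and results are reported for ages 0–85 only.

## From published tables to continuous rates

Registries publish rates on 5-year age groups.  Each closed group [L, H]
contributes one node at its continuous-age midpoint (L + H + 1)/2; values
are interpolated bilinearly in (year, age) and extended by nearest-value
(constant) extrapolation outside the node hull.  The open 85+ group
contributes no node.  Evaluation at a node returns the stored value
exactly.

Initial prevalence from claims data typically starts at age 15; with
`anchor_zero_at_birth` an extra node (age 0, value 0) encodes the
healthy-at-birth assumption and closes the gap linearly.  The same flag is
available for any table but is only the default for the initial profile.

Two routes provide the diseased mortality:

* **direct** — a table of m1 is interpolated as-is;
* **cause_specific** (default) — cause-of-death statistics give μc, the
  cause-specific deaths per person-year in the whole population.  Assuming
  (i) all cause-specific deaths occur among the diseased and (ii) diseased
  non-cause mortality equals the non-diseased rate m0 = m − μc, the mixing
  relation pins down m1 = μc/p + m − μc pointwise at the current
  prevalence.  Substituted into the PDE this reduces algebraically to
  (∂t + ∂a) p = (1 − p)(i − μc); the solver implements the derived-m1 route
  (form `via_m1`) and the reduced form (`reduced`) separately and the test
  suite asserts they agree to better than 1e−12 rather than hard-coding the
  identity.  At p = 0 exactly, the `via_m1` route uses the analytic limit
  p·(m1 − m) → μc (the 0/0 cancellation of μc/p · p).  μc > m is flagged as
  a data inconsistency but still computed; negative excess m1 < m is
  counted, never clamped, because silent clamping would bias prevalence
  upward.

## Numerical integration

Characteristics are lines of constant a − t; on each one the PDE is an ODE
integrated with classical RK4 (default) or forward Euler at a fixed step
that must divide one year, so samples land exactly on the integer-age
output grid.  The default step is 0.1 years: on smooth rate fields the
measured error against a step-1e−4 reference is ~1e−10, and the empirical
convergence orders (error ratios per step halving ≈ 2.0 for Euler, ≈ 16
for RK4, measured by `scripts/acceptance.py`) confirm the implementation.
Step-refinement studies use `integrate_fixed_span`, which drops the
integer-age sampling requirement so steps like 0.4 are admissible, and an
independent `reference_solution` integrator (rates tabulated up front,
pure-float loop) that shares no code with the production path.

Output values are clamped into [0, 1 − 1e−9] only at the end, and every
clamp is counted and logged; on all bundled scenarios the count is zero.
Cells with a − (t − t0) ≥ 0 are seeded from the initial profile at t0,
younger cells from p = 0 at birth.  Characteristics are mutually
independent, so the surface solve equals solving each one alone (tested).

## Synthetic scenarios and their truth

Real claims/registry inputs are not redistributable, so validation runs on
parametric scenarios:

* incidence i(t, a) = α·exp(β·a)·max(1 + γ·(t − t0), 0) — exponential in
  age, linear calendar trend, clipped at zero so the rate stays
  non-negative for cohorts whose lifetime predates t0 by more than 1/γ
  years;
* m0(a) = g_a·exp(g_b·a) (Gompertz), time-constant;
* m1 = m0 + δ0·exp(δ_trend·(t − t0)), a non-negative excess hazard.

Defaults (per sex): α = 1e−4, β = 0.09, γ = 0.02, g_a = 2e−5, g_b = 0.095,
δ0 = 0.02, δ_trend = 0.  Under these the truth prevalence reaches ≈ 0.81
(2010) to 0.87 (2019) at age 85 — a deliberately demanding regime with
old-age incidence around 0.2/year.  The `trend` scenario adds a faster
incidence rise (γ = 0.03), declining excess (δ_trend = −0.05) and 1.5×
male incidence to exercise the qualitative decade shape; `null` is all
zeros.

The truth bundle integrates, per birth cohort (spaced 0.5 years so every
grid cell is covered), the pair dp/ds (the PDE along the characteristic,
in (m0, m1) form) and dS/ds = −(p·m1 + (1 − p)·m0)·S with RK4 at step
1e−3.  It is therefore deterministic; the stochastic check lives in the
microsimulation.  From p* and S the bundle derives consistent m and μc
surfaces (the mixing relation holds at every node by construction) — so
the aggregated tables handed to the pipeline are exactly self-consistent,
and any recovery error is attributable to the aggregation/interpolation
scheme, not to the data.

Aggregation back to registry-style tables computes person-time-weighted
group averages: composite-trapezoid quadrature of ∫ S·x da / ∫ S da over
each group's span [L, H+1] on the 0.5-year truth grid; the open 85+ group
carries the value at 85.  The initial-prevalence table covers only t0 and
ages ≥ 15, emulating claims data.  The synthetic population is
base_cohort·S with an optional Gaussian baby-boom bump on the birth-cohort
size.

What the generator does **not** emulate: claims-data ascertainment
artifacts (confirmation criteria, under-documentation), multiple
concurrent conditions, migration, cohort effects beyond the smooth
calendar trends, and non-Gompertz old-age mortality.  Passing tests
therefore demonstrate the correctness of the mathematics and numerics on
smooth self-consistent inputs, not robustness to real-data artifacts.

## Microsimulation oracle

`simulate_cohort` walks n individuals of one birth cohort through the
three states in steps of dt (default 0.05 years) with per-transition
probabilities 1 − exp(−rate·dt) evaluated at the current (t, a); a healthy
individual's single uniform draw is compared against the illness and death
probabilities sequentially (the O(dt²) competing-risk bias is far below
the comparison allowance).  `simulate_grid` covers the analysis window
with one cohort per characteristic (births t0 − 85 … t1), splitting the
per-sex sample evenly, with one spawned child seed per cohort — results
are bit-identical under a fixed seed, and healthy + ill + dead = n exactly
at every recorded age.

The comparison bound per cell is 3·SE + 0.002, with SE the plug-in
binomial standard error and 0.002 an allowance for the simulator's
discrete-time bias.  It is calibrated for the designed sample size of
200,000 per sex (≈ 2,100 per cohort): at that size ≥ 99% of cells agree
(measured 99.88%).  At much smaller n the check degrades for reasons that
are diagnostic, not numerical: cells with zero observed cases get SE = 0,
and all cells along one characteristic share individuals, so a single
unlucky cohort fails several cells at once.

## Known limitations, with numbers

* **Interpolation error of 5-year grouping.**  On the default scenario the
  full pipeline (aggregate → interpolate → solve, cause-specific mode)
  recovers the truth with a maximum absolute error of ≈ 0.008 over cells
  with true p ≤ 0.5 (and ≈ 0.08 at the oldest ages where p ≈ 0.85), as
  computed by `scripts/acceptance.py`.  Two mechanisms, both inherent to
  midpoint-anchored linear interpolation of convex curves, dominate: the
  initial profile alone contributes up to ≈ 0.005 (chord sag ≈ p″w²/8 with
  w = 5), and the ≈ (βw)²/12 ≈ 1.7% mean upward bias on interpolated
  exponential incidence accumulates over the decade.  Finer age groups, or
  shape-aware (e.g. log-linear) interpolation, would shrink this; with
  published 5-year tables it is the method's irreducible cost.
* **Open 85+ group.**  Constant extrapolation above the oldest midpoint
  (82.5) understates rising rates, so estimates at 83–85 inherit extra
  bias; no data point exists beyond 85 to do better.
* **Initial profile below the claims age floor** (15) relies entirely on
  the healthy-at-birth anchor; fine for cancer, wrong for congenital
  conditions.
* **No uncertainty propagation.**  The pipeline is deterministic; sampling
  variability of the input tables is not translated into intervals.
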