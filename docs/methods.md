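# Methods

## Model and assumptions

The population is closed (no births, deaths, or migration) and split into
sedentary (S), moderately active (E1), and extremely active (E2)
compartments. Social transitions are mass-action: the rate at which contact
between compartments X and Y moves individuals is proportional to `X·Y/N`.
Spontaneous transitions (physician's advice, injury) are linear in the source
compartment. The exchange between the two active compartments is modeled with
*linear* terms `alpha1·E2` and `alpha2·E1`, not mass-action products, even
though the mechanism is social contact; the threshold analysis below is built
on that linear form, and the package implements it as such.

Compartment sizes are real-valued (continuum approximation); no integer
rounding is applied. All rates are week⁻¹ and no unit conversion layer is
provided. The total `N = S + E1 + E2` is recomputed at every right-hand-side
evaluation rather than frozen at its initial value — the two coincide because
the system conserves the total, and recomputing makes conservation a testable
property instead of an assumption. In the implementation each flow term is
computed once and reused with both signs, so the three derivatives sum to
zero up to rounding (tested at 1e−12 relative; exact bitwise cancellation of
three independently rounded sums is not guaranteed in floating point).

Because every nonlinear term carries a `1/N` factor, the dynamics depend only
on the compartment *fractions*; initial conditions are therefore specified as
fractions with a default population of 1,000 persons.

## Basic reproduction number

Treating physical activity as the transmitted state, R0 is the larger root of
`A·x² − B·x + C = 0` with

```
A = N²(α₁δ₁ + δ₂(α₂+δ₁)) + N·S₀(β₁(α₁+δ₂) + β₂(α₂+δ₁)) + S₀²β₁β₂
B = S₀[N(α₁k₁ + δ₁k₂) + N(α₂(k₂+r₂) + r₁(α₁+δ₂)) + S₀(β₁k₂ + β₂r₁)]
C = (r₁k₂ − r₂k₁)S₀²
```

The spontaneous uptake rates `gamma1, gamma2` do not appear: the
next-generation accounting counts only socially transmitted activity. In
Case 1 (no social transmission) R0 = 0 even though positive `gamma` rates
would in fact sustain active populations indefinitely; R0 = 0 there reflects
the transmission-only bookkeeping, not literal extinction. For this reason
every simulation-based threshold property in the package is restricted to
`gamma1 = gamma2 = 0`.

### Next-generation-matrix cross-check

`r0_ngm` rebuilds R0 independently. With the active compartments as the
"infected" block and `s = S0/N`:

```
F = [[r1·s, r2·s],      V = [[β1·s + α2 + δ1,  −α1],
     [k1·s, k2·s]]           [−α2,  α1 + β2·s + δ2]]
```

F holds creation of active individuals out of the sedentary pool (new
"infections"); V holds recidivism and the inter-exerciser exchange
(transitions). This is the split under which `det V = A/N²`,
`tr(F·V⁻¹) = B/A` and `det(F·V⁻¹) = C/A`, so the spectral radius of `F·V⁻¹`
is exactly the closed-form root; the package verifies the agreement
numerically to 1e−8 relative over a thousand random draws rather than taking
the printed coefficients on faith.

The construction requires `gamma1 = gamma2 = 0` (otherwise the all-sedentary
state is not an equilibrium to linearize at). The linearization is taken at
sedentary fraction `S0/N` for any `0 ≤ S0 ≤ N`, matching how S0 enters the
closed form; `S0 = N` is the genuine activity-free equilibrium, and that is
the value used whenever a persistence classification is compared against a
simulated long-run outcome, since the fate of a small active population is
governed by stability of the all-sedentary state.

### Numerical choices

- `A = 0` (no recidivism/exchange product at all) raises an error directing
  the user to a special-case formula; the general expression is undefined
  there and no limit evaluation is attempted.
- The discriminant `B² − 4AC` is clamped to 0 when within `1e−12·max(1, B²)`
  of zero (pure rounding noise, since the NGM equivalence guarantees real
  roots for valid parameters); a larger negative value raises.
- Classification uses a three-way split with `ε = 1e−9`: extinction below
  `1 − ε`, persistence above `1 + ε`, `threshold` in between, so the
  boundary case is reported rather than silently folded into either side.
- The special-case formulas enforce their zeroing patterns exactly (no
  tolerance): they are algebraic identities, not approximations, and a
  nonzero excluded parameter means the caller is using the wrong formula.

## Simulation

`scipy.integrate.solve_ivp` with LSODA (adaptive step, automatic stiff
switching) at `rtol = 1e−8`, `atol = 1e−10`, sampled on an even grid of 1,001
points. Post-conditions enforced on every trajectory: conservation of the
total within `1e−6·N(0)`, and nonnegativity after clamping excursions within
the solver's absolute tolerance to zero (a larger negative value is treated
as an integration failure, not roundoff). Halving the relative tolerance
changes final fractions by less than 1e−5 on the reference scenarios.

**Plateau and extinction are operationalized** as follows: a trajectory has
*settled* when the largest derivative magnitude over the trailing 20% of the
horizon is below `1e−8·N` per week, and a compartment is *extinct* when its
final fraction is below `1e−3`. These thresholds separate the exponential
tails of the reference dynamics from genuine plateaus at double precision.
Preset runs start at 500 weeks and double the horizon (to at most 8,000
weeks) until settled, so reported plateaus are steady levels, not snapshots
of a slow transient; the reference scenarios settle at 4,000–8,000 weeks.
Exact extinction *times* are not computed — the reproducible surface is which
compartments vanish, not when.

## Reference scenarios

- `fig3a` — persistence: `k1 = 0.002, r1 = 0.015, beta1 = 0.0022,
  alpha1 = alpha2 = 0.005`, all other rates 0, initial fractions 50/30/20%.
  R0 = 0.017/0.0022 ≈ 7.73 > 1; the sedentary compartment goes extinct and
  the active compartments plateau (at 0.5/0.5 because the exchange rates are
  equal).
- `fig3b` — extinction: same but `beta1 = 0.035`. R0 ≈ 0.486 < 1; the active
  compartments go extinct.
- `sensitivity_baseline` — every rate 0.001 week⁻¹, equal initial thirds.

## Sensitivity protocol

One-at-a-time: from the uniform baseline, one parameter (or a named group in
lockstep) is set to each value of a grid, the modified scenario is run to
plateau, and the sedentary final fraction is recorded. The default grid is
{1, 2, 5, 10}× the baseline value — a package choice made to give unambiguous
response directions; the protocol itself fixes only the baseline, so the
plateau-change *percentages* depend on the chosen grid and are not treated
as reproducible quantities. Directions are classified from the first and
last settled grid points with a flatness band of 1e−6 (absolute sedentary
fraction). An unsettled sweep point is recorded as missing with a warning,
not a failure.

At the fully symmetric baseline the sedentary equation depends on `E1 + E2`
only, never on the split between the active compartments, so the response to
`alpha1`/`alpha2` is *exactly* flat (the observed residuals are solver noise
at the 1e−8 level); the uptake rates (`r1, r2, k1, k2, gamma1, gamma2`) lower
the sedentary plateau and the recidivism rates (`beta1, beta2, delta1,
delta2`) raise it. A relabeling symmetry (swap E1↔E2 together with the
parameter pairs r↔k, beta1↔beta2, delta1↔delta2, gamma1↔gamma2,
alpha1↔alpha2) leaves the sedentary trajectory invariant and is checked as a
property test.

## What the tests do and do not show

All inputs are parameter sets; there is no data-fitting layer. Passing tests
show that the implementation reproduces the model's analytic structure
(closed form ≡ NGM ≡ case reductions), its qualitative threshold behavior,
and the sensitivity directions — they say nothing about how well the model
describes any real population, which would require longitudinal activity
data the model is not fitted to. The continuum approximation further means
"extinction" is a fraction falling below 1e−3, not a stochastic fade-out of
discrete individuals; stochastic variants are out of scope.

## Problem sizes

Property and equivalence tests use 300–1,000 random parameter draws; the
threshold-consistency check simulates 200 random scenarios to plateau; sweeps
use 4 grid points per parameter. These sizes make the whole suite run in
seconds while leaving the stochastic checks well-powered (the equivalence
tolerances are 8–10 orders of magnitude below typical parameter effects).
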