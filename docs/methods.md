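# Methods

## The model

A defined-benefit scheme pays a retiree an annual pension `b` from
retirement age `r` until death or a terminal age `w`. The member's survival
is governed by an annual cohort mortality schedule `q_x` (probability of
death within the year for a life aged exactly `x`). If the member is
certified severely or highly dependent at age `x ≥ r`, the scheme may
replace the pension by an LTC-support benefit `b · λ_x` payable for the
member's remaining (dependent) lifetime, with

    λ_x = e_x / e_x^d,

the ratio of residual life expectancies as an independent and as a
dependent person. Because dependent mortality dominates general mortality
at every age (`q_x^d ≥ q_x`), `λ_x ≥ 1` and the dependent expectancy is
shorter: the benefit rises by exactly the factor by which the expected
number of payments falls. In expectation the scheme's outgo is unchanged —
the conversion is cost-free, requiring no extra contributions.

### Assumptions

- **Discrete annual grid.** All quantities live on integer attained ages.
  The continuous force of mortality is linked to the grid through a
  piecewise-constant intensity on each year of age, `μ_x = −ln(1 − q_x)`.
  The underlying theory is usually written with continuous integrals; the
  published per-age results are annual, and the discrete-annual form is
  standard actuarial practice, so the toolkit is discrete throughout with
  `force_of_mortality` as the continuous bridge.
- **One transition per year, no return.** The multistate model
  (active → retired/disabled/dead; retired → dependent/dead;
  dependent → dead) allows a single transition per annual step and no
  recovery. Disability before retirement is absorbing and carries no
  benefit logic here.
- **Exogenous conversion decision.** Whether a dependent retiree converts
  is a 0/1 indicator per age supplied by the user (irreversible once 1);
  no behavioural model is fitted.
- **Cohort tables are static.** `cohort_year` is metadata; no mortality
  improvement or projection model (e.g. Lee–Carter) is applied. Users who
  need generational effects must supply per-cohort schedules.

## Dependent-lives mortality

Three corrections map a general schedule to a dependent one:

- multiplicative `q^d = min(θ·q, 1)`, constant `θ ≥ 1`;
- additive `q^d = clip(q + ε(x))` with any age-indexed excess `ε`;
- mixed (the canonical instance):

      q^d(x) = q(x)            + δ / (1 + γ^(x_i − x))    x <  switch_age
      q^d(x) = q(x)·(1 + β)    + δ / (1 + γ^(x_i − x))    x ≥  switch_age

  The logistic term is monotone increasing in age for `γ > 1`, equals
  `δ/2` at the inflection age `x_i`, and tends to the asymptotic excess
  `δ` in old age. The multiplicative loading `β` from the switch age
  reproduces the observed narrowing of the *absolute* mortality
  differentials at the oldest ages.

Shipped presets (severe/high dependency, Spain):

| parameter | men | women | meaning | units |
|---|---|---|---|---|
| δ | 0.245 | 0.165 | asymptotic additive excess | probability |
| γ | 1.135 | 1.09 | logistic slope | – |
| x_i | 62.50 | 58.61 | inflection age | years |
| β | 0.1142 | 0.0962 | old-age multiplicative loading | – |
| switch_age | 95 | 95 | loading activation age | years |

Design notes:

- The piecewise condition is parameterised on **attained age** versus a
  `switch_age` constant (default 95). A literal reading that conditions on
  the constant `x_i` itself would make the branch vacuous; conditioning on
  attained age is the only reading consistent with differentials that
  narrow from the mid-90s. Whether the loading should start at exactly 95
  or 96 is ambiguous in the source material; 95 is the default and the
  parameter is exposed.
- The logistic exponent is `γ^(x_i − x)` by default. A `mirrored`
  convention `γ^(x − x_i)` is available for experimentation; it makes the
  excess *decrease* with age and is not the shipped behaviour.
- The piecewise form is **not continuous** at the switch age: the corrected
  rate jumps by `β · q(switch_age)`. `branch_jump` reports the magnitude
  rather than smoothing it away.
- Corrected probabilities are clipped to [0, 1], and the derived table must
  dominate its base at every age; a correction that produces
  `q^d < q` anywhere raises `MortalityOrderingError`.

### Fitting

`ExcessMortalityModel` fits `(δ, γ, x_i, β)` to observed
`(age, q_general, q_dependent)` triples by minimising the residual sum of
squares of the predicted dependent rates — ordinary least squares in the
rates, solved with SciPy's bounded trust-region-reflective nonlinear
least-squares. The logistic surface has local minima in `(γ, x_i)`, so the
solver is multistarted over a coarse grid (γ ∈ {1.05, 1.1, 1.2, 1.5} ×
x_i at the age quartiles); the best solution is kept. Bounds:
δ ∈ (0, 1), γ ∈ (10⁻³, 10), x_i within the observed age range ± 30 years,
β ∈ [0, 5]. Non-convergence never raises — the best-so-far parameters are
returned with `converged=False`. Standard errors are the Gauss–Newton
approximation from the solution Jacobian; on noiseless data they are
reported but meaningless (the fit interpolates). On noiseless data
generated by the mixed correction itself the fit recovers all four
parameters to better than 1e-3 with RSS below 1e-10; with uniform noise of
amplitude 1e-4 at 40 ages, δ is recovered well within 5 % relative error.

## Life tables and expectancy conventions

- Tables are **closed**: the terminal age ω carries `q(ω) = 1`. A schedule
  that stops short (the shipped fixture stops at 100 with q ≈ 0.025) is
  extended to ω = 120 by log-linear extrapolation of `q` (slope taken from
  the last two ages, never negative), capped at 1. Expectancies computed
  from such extended tables therefore embed an explicit, documented closure
  choice.
- **Abridged grids**: runs of up to four missing interior ages (a 5-year
  grid) are filled by linear interpolation of `log q`, which is exact for
  Gompertz-type schedules and recovers single-age rates of smooth
  schedules to within 5 % relative error. Supplied node values are kept
  exactly.
- **Curtate vs complete.** Curtate expectancy is `Σ_{t≥1} tPx` (whole
  years); complete adds 0.5 for the part-year lived in the year of death.
  The default is complete, switchable per call, because published
  expectancy tables rarely state their convention. A third convention,
  `truncated_curtate`, is the expected annuity-due payment count
  `1 + Σ_{t=1}^{w−x−1} tPx`; it is the convention under which the
  cost-free identity below is an algebraic identity.
- The radix (default 100 000) is conventional; every derived quantity is
  radix-invariant and tested as such.

## Present values and the cost-free identity

The benefit stream is discretised as an **annuity-due** (payment at the
start of each survived year), consistent with annual `q` grids and pension
practice; annuity-immediate timing is available per call. With a
piecewise-constant discount intensity `δ_t`,

    PVFB_x = Σ_{t=0}^{w−x−1} b(x+t) · tPx · v(t),   v(t) = exp(−∫₀ᵗ δ_s ds).

`check_equivalence` returns the signed relative residual
`(λ · PVFB_dep − PVFB_ind) / PVFB_ind`:

- at **zero interest**, with λ computed as the truncated-curtate expectancy
  ratio over the same window `[x, w)`, the residual is identically zero
  (floating-point rounding only) — the toolkit's central theorem-like
  property, verified for every synthetic dominated pair;
- at **positive interest** the expectancy-ratio λ over-compensates
  (dependent payments arrive earlier on average, so discounting hurts them
  less) and the residual is positive; it is reported, not hidden. Users
  who want exactness at positive interest can use `annuity_lambda`, the
  PVFB-ratio factor, at the cost of departing from the published
  expectancy-ratio definition.

No interest assumption is attached to the cost-free claim itself; the
toolkit interprets it as exact at zero interest and quantified otherwise.

## Comparison statistics

The published per-age comparison columns are **ratio-minus-one**
statistics: relative excess mortality `q^d/q − 1` and the female/male
dependent differential `q^d_f / q^d_m − 1`. Only this reading reproduces
the printed per-age values (e.g. 22.78 for men at 80); the literal
subtractions are exposed separately as `abs_excess`. The expectancy gap
`e − e^d` equals the expected payment-years forgone under annual payments.

## The synthetic generator and the fixture

- `GompertzMakehamParams` generates smooth adult schedules from the hazard
  `μ(x) = A + B·c^x`, so `q_x = 1 − exp(−A − B·c^x(c−1)/ln c)`. Defaults
  `A = 2e-4`, `B = 3e-5`, `c = 1.1` over ages 20–120 give an expected age
  at death near 78 for a life aged 20 — a deliberately generic insured-lives
  shape. It is a synthetic stand-in for proprietary insured-lives
  graduations: it emulates the smoothness and log-linear old-age slope the
  method needs, but no period/cohort structure, no accident hump, and no
  selection effects. Tests passing on it demonstrate the machinery, not
  calibration to any real portfolio.
- `make_dependent_pair` returns a pair whose dependent table is exactly
  the mixed-correction image of the base — the round-trip oracle for the
  fitter.
- The 1970-cohort Spanish fixture ships the printed values verbatim
  (6-decimal rates, 1-decimal expectancies, 5-year grid, ages 20–100) with
  a SHA-256 integrity check. Its expectancy columns embed undisclosed
  closure and graduation choices, so they are treated as **data**: the
  published per-age factors are reproduced by the printed-expectancy ratio
  path (`schedule_from_fixture`), not by rebuilding tables from the
  rate columns. Applying the shipped mixed-correction presets to the
  fixture's general rates does **not** reproduce its dependent-rate column
  (the source's generational-table adjustments are not public); the fixture
  is a fixture, not a derivation target. For the same reason a handful of
  published λ cells (e.g. men at 70) disagree with the rounded-expectancy
  ratio at the second decimal — they were evidently computed from unrounded
  internal expectancies — and are excluded from exact-reproduction checks.

- All random generation takes an explicit seed; the documentation default
  is 20210225.

## Problem sizes and numerical choices

Default experiment sizes: synthetic tables span ages 20–120 (101 ages);
fits use ~48 noiseless or 40 noisy observations; projections run a
100 000-life cohort over 55 annual steps. Tolerances: row closure and mass
conservation at 1e-9; the survival semigroup and the zero-interest
equivalence at 1e-12; noiseless fit RSS at 1e-10. Ties and degenerate
inputs: a table consisting of a single closing age is legal (expectancy 0
curtate); `q = 1` mid-schedule truncates the table there; zero general
mortality at an age makes the relative-excess statistic NaN (flagged, not
fatal); a zero dependent expectancy makes λ undefined and raises.

## Known limitations

- No mortality projection: factors for cohorts other than the fixture's
  require user-supplied generational schedules.
- Dependency incidence (the retired → dependent transition rate) is a user
  input; the toolkit validates and projects it but ships no incidence
  model.
- The conversion decision is exogenous; adverse selection between the
  retirement and LTC annuity pools is not modelled.
- Moderate (non-severe) dependency carries no excess mortality and no
  conversion in this model.
- Sub-annual decrements and semi-Markov durations are out of scope.
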