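# ltcfactor

Actuarial toolkit for converting a retirement pension into long-term-care
(LTC) support **at no extra cost to the pension scheme**, exploiting the
excess mortality of severely or highly dependent lives.

## Who this is for

Pension actuaries, social-insurance researchers and biostatisticians who
want to price, analyse or stress-test the "conversion factor" mechanism in
defined-benefit schemes: when a retiree is certified severely dependent,
their annual pension `b` is rescaled to `b · λ_x`, where

```
λ_x = e_x / e_x^d
```

is the ratio of residual life expectancy as an independent person (`e_x`)
to residual life expectancy as a dependent person (`e_x^d`) at the
conversion age `x`. Dependent lives die faster, so `λ_x ≥ 1`: the pension
rises exactly in proportion to the fall in the expected number of payments,
and the expected payout of the scheme is unchanged — the mechanism is
cost-free.

## What is inside

- `lifetable` — cohort life tables by sex / cohort / health state on a
  single-age grid: survival probabilities, force of mortality, curtate and
  complete life expectancy; readers for 1-year and abridged (5-year) CSV
  schedules.
- `dependent` — multiplicative (`θ·q`), additive (`q + ε(x)`) and mixed
  corrections mapping general mortality to dependent-lives mortality. The
  mixed form adds a logistic-in-age excess `δ / (1 + γ^{x_i − x})` and,
  from a switch age (default 95), a multiplicative loading `(1 + β)`.
  Spanish severe/high-dependency parameter presets are shipped;
  `ExcessMortalityModel.fit()` refits them to observed rates by bounded
  nonlinear least squares and returns a results object with estimates,
  standard errors and a `summary()` table.
- `conversion` — the per-age factor λ and its comparison statistics:
  relative excess mortality `q^d/q − 1`, the female/male dependent-mortality
  differential, and the expectancy gap (payment-years forgone).
- `multistate` — the discrete annual active / retired / dependent /
  disabled / dead model: row-closure validation, expected-count cohort
  projection with an exogenous 0/1 conversion decision, and a seeded
  Monte-Carlo sampler.
- `actuarial` — piecewise-constant discount curves, annuity-due present
  values of benefit streams (PVFB), and `check_equivalence`, which verifies
  the cost-free identity `λ · PVFB(dependent) = PVFB(independent)` (exact
  at zero interest; the signed residual is reported at positive interest).
- `synthetic` — Gompertz–Makeham schedule generators and the shipped
  1970-cohort Spanish fixture (printed rates and expectancies, both sexes,
  ages 20–100 on a 5-year grid).

## Worked example

```python
import ltcfactor as lf

# published-fixture path: per-age factors from printed expectancies
fx = lf.fixture_table3()
sched = lf.schedule_from_fixture(fx, "male")
row = sched.at_age(65)
print(f"lambda(65) = {row['lambda']:.2f}")
print(f"e_ind = {row['e_ind']:.1f} y   e_dep = {row['e_dep']:.1f} y   gap = {row['gap']:.1f} y")
print(f"pension 12000 -> LTC benefit {lf.converted_benefit(12000, row['lambda']):.0f}")

# full-table path: synthetic pair, factor, and the cost-free check
base, dep = lf.make_dependent_pair(excess=lf.SPAIN_SEVERE_MEN)
lam = lf.conversion_factor(base, dep, 75, convention="truncated_curtate", w=110)
spec = lf.PensionSpec(b=1.0, retirement_age=65, terminal_age=110)
r0 = lf.check_equivalence(base, dep, spec, lf.DiscountCurve.flat(0.0), 75, lam)
print(f"lambda(75) synthetic = {lam:.4f}   residual at 0% interest = {r0:.2e}")
```

prints

```
lambda(65) = 2.98
e_ind = 43.5 y   e_dep = 14.6 y   gap = 28.9 y
pension 12000 -> LTC benefit 35753
lambda(75) synthetic = 3.0276   residual at 0% interest = -4.64e-16
```

A man of the 1970 cohort certified severely dependent at 65 has his life
expectancy cut from 43.5 to 14.6 years, so his pension is multiplied by
2.98; a €12 000 pension becomes €35 753 of annual LTC support paid over a
much shorter expected horizon. On the synthetic pair the equivalence
residual at zero interest is at floating-point rounding: the conversion
moves no value into or out of the scheme.

The same operations are available from the shell, e.g.:

```sh
ltcfactor synth --out base.csv
ltcfactor depend derive --base base.csv --preset spain_severe_men --out dep.csv
ltcfactor factor --ind base.csv --dep dep.csv --ages 65:100 --out schedule.csv
ltcfactor equivalence --ind base.csv --dep dep.csv --age 75 --rate 0.0
```

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter defaults,
numerical conventions and known limitations.
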