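"""The pension-to-LTC conversion factor and its comparison statistics.

When a retiree in a defined-benefit scheme is certified severely or highly
dependent, their annual pension ``b`` is rescaled to ``b * lambda_x``, where

    lambda_x = e_x (independent) / e_x^d (dependent)

is the ratio of residual life expectancies at the conversion age.  Because
dependent lives die faster, ``lambda_x >= 1``: the pension rises exactly in
proportion to the fall in the expected number of payments, so the expected
payout — and hence the scheme cost — is unchanged.

:func:`build_schedule` assembles the per-age factor together with the
derived comparison statistics: relative excess mortality of dependent over
general lives, the female/male dependent-mortality differential, and the
expectancy gap (the expected payment-years forgone).  The "excess" and
"differential" statistics are ratio-minus-one quantities, e.g.
``q_dep / q_gen - 1``; the literal subtraction is exposed separately as
``abs_excess``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .lifetable import Convention, LifeTable

__all__ = [
    "ConversionSchedule",
    "conversion_factor",
    "build_schedule",
    "schedule_from_fixture",
    "sex_differential",
    "converted_benefit",
]


@dataclass(frozen=True, eq=False)
class ConversionSchedule:
    """Per-age conversion factors and comparison statistics.

    ``frame`` columns: ``age``, ``lambda`` (= e_ind / e_dep), ``e_ind``,
    ``e_dep`` (years), ``rel_excess`` (q_dep/q_ind - 1), ``abs_excess``
    (q_dep - q_ind), ``sex_diff`` (q_dep_female/q_dep_male - 1, NaN when the
    other sex's table was not supplied), ``gap`` (e_ind - e_dep, years) and
    ``payment_reduction`` (expected annual payments forgone; equals the gap
    under one payment per survived year).
    """

    frame: pd.DataFrame
    sex: str
    cohort_year: int
    convention: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))

    def at_age(self, age: int) -> pd.Series:
        row = self.frame.loc[self.frame["age"] == age]
        if row.empty:
            raise KeyError(f"age {age} not in schedule")
        return row.iloc[0]

    def lambda_at(self, age: int) -> float:
        return float(self.at_age(age)["lambda"])

    def to_csv(self, path) -> None:
        cols = ["age", "lambda", "e_ind", "e_dep", "rel_excess", "sex_diff", "gap"]
        self.frame[cols].to_csv(path, index=False)


def _expectancy(table: LifeTable, x: int, convention: str, w: int | None) -> float:
    if convention == "truncated_curtate":
        # annuity-due payment count: 1 + curtate expectancy truncated at w.
        return table.annuity_due_count(x, w)
    return table.life_expectancy(x, convention)  # type: ignore[arg-type]


def conversion_factor(
    ind: LifeTable,
    dep: LifeTable,
    x: int,
    convention: Convention | str = "complete",
    w: int | None = None,
) -> float:
    """Conversion factor at age ``x``: independent over dependent expectancy.

    ``convention`` is ``"complete"`` (default), ``"curtate"``, or
    ``"truncated_curtate"`` — the last computes the ratio of expected
    annuity-due payment counts truncated at age ``w``, the convention under
    which the conversion is exactly cost-free at zero interest.
    """
    e_ind = _expectancy(ind, x, convention, w)
    e_dep = _expectancy(dep, x, convention, w)
    if e_dep == 0.0:
        raise ZeroDivisionError(f"dependent expectancy is zero at age {x}")
    return e_ind / e_dep


def sex_differential(dep_f: LifeTable, dep_m: LifeTable, x: int) -> float:
    """Female-over-male dependent-mortality differential at age ``x``,
    ``q_dep_female / q_dep_male - 1``."""
    qm = dep_m.qx(x)
    if qm == 0.0:
        raise ZeroDivisionError(f"male dependent rate is zero at age {x}")
    return dep_f.qx(x) / qm - 1.0


def converted_benefit(b: float, lam: float) -> float:
    """Annual LTC-support benefit after conversion: ``b * lambda``."""
    if b < 0 or lam < 0:
        raise ValueError("benefit and factor must be non-negative")
    return b * lam


def build_schedule(
    ind: LifeTable,
    dep: LifeTable,
    ages: Iterable[int] | None = None,
    convention: Convention | str = "complete",
    dep_other_sex: LifeTable | None = None,
    w: int | None = None,
) -> ConversionSchedule:
    """Assemble the full per-age schedule from aligned life tables.

    ``dep_other_sex`` (the opposite sex's dependent table) enables the
    ``sex_diff`` column; the female/male orientation follows the tables'
    ``sex`` metadata.  Ages where q_ind = 0 get NaN relative excess
    (flagged, not fatal).
    """
    if ages is None:
        lo = max(ind.age_start, dep.age_start)
        hi = min(ind.omega, dep.omega)
        ages = range(lo, hi)  # omega itself excluded: e_dep can be 0 there
    ages = np.array(sorted(ages), dtype=int)
    records = []
    for a in ages:
        e_i = _expectancy(ind, a, convention, w)
        e_d = _expectancy(dep, a, convention, w)
        q_i, q_d = ind.qx(a), dep.qx(a)
        rel = (q_d / q_i - 1.0) if q_i > 0 else np.nan
        if dep_other_sex is not None:
            if dep.sex == "male":
                sd = sex_differential(dep_other_sex, dep, a)
            else:
                sd = sex_differential(dep, dep_other_sex, a)
        else:
            sd = np.nan
        records.append({
            "age": a,
            "lambda": e_i / e_d if e_d > 0 else np.nan,
            "e_ind": e_i,
            "e_dep": e_d,
            "rel_excess": rel,
            "abs_excess": q_d - q_i,
            "sex_diff": sd,
            "gap": e_i - e_d,
            "payment_reduction": e_i - e_d,
        })
    return ConversionSchedule(
        frame=pd.DataFrame.from_records(records),
        sex=ind.sex, cohort_year=ind.cohort_year, convention=str(convention),
    )


def schedule_from_fixture(fixture, sex: str = "male") -> ConversionSchedule:
    """Schedule computed directly from a printed 5-year-grid bundle.

    Uses the printed expectancies and rates as-is (no table rebuilding or
    interpolation), so the factor matches the printed-value ratio exactly;
    this is the path that reproduces the published per-age results.
    """
    e_i = fixture.column(sex, "independent", "e")
    e_d = fixture.column(sex, "dependent", "e")
    q_i = fixture.column(sex, "independent", "q")
    q_d = fixture.column(sex, "dependent", "q")
    other = {"male": "female", "female": "male"}[sex]
    qd_o = fixture.column(other, "dependent", "q")
    if sex == "male":
        sd = qd_o / q_d - 1.0
    else:
        sd = q_d / qd_o - 1.0
    frame = pd.DataFrame({
        "age": e_i.index.to_numpy(),
        "lambda": (e_i / e_d).to_numpy(),
        "e_ind": e_i.to_numpy(),
        "e_dep": e_d.to_numpy(),
        "rel_excess": (q_d / q_i - 1.0).to_numpy(),
        "abs_excess": (q_d - q_i).to_numpy(),
        "sex_diff": sd.to_numpy(),
        "gap": (e_i - e_d).to_numpy(),
        "payment_reduction": (e_i - e_d).to_numpy(),
    })
    return ConversionSchedule(frame=frame, sex=sex,
                              cohort_year=fixture.cohort_year,
                              convention="printed")
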