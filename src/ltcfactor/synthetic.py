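"""Synthetic mortality schedules and the shipped 1970-cohort fixture.

Two sources of test data:

* Gompertz-Makeham generators: a smooth adult law ``mu(x) = A + B c^x``
  whose annual rates under a piecewise-constant intensity are
  ``q_x = 1 - exp(-A - B c^x (c - 1) / ln c)``.  This is a synthetic
  stand-in for proprietary insured-lives graduations — it has the smooth,
  log-linear-at-old-age shape the conversion method assumes, nothing more.

* The 1970-cohort Spanish fixture: printed mortality rates and life
  expectancies for independent and severely/highly dependent lives of both
  sexes, ages 20-100 on a 5-year grid, shipped verbatim (6-decimal rates,
  1-decimal expectancies).  It exercises every downstream module without
  any external data.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dependent import ExcessParams, derive_dependent_table
from .lifetable import DEFAULT_OMEGA, LifeTable, build_life_table

__all__ = [
    "GompertzMakehamParams",
    "make_base_table",
    "make_dependent_pair",
    "fixture_table3",
    "Table3Fixture",
    "DEFAULT_SEED",
]

#: Default seed for reproducible documentation examples.
DEFAULT_SEED = 20210225


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz-Makeham hazard ``mu(x) = A + B c^x``.

    ``A`` is the age-independent (accident) hazard, ``B`` the baseline
    senescent hazard and ``c > 1`` the rate of ageing.  Defaults give a
    schedule of adult-mortality shape with an expected age at death in the
    high 70s for a life aged 20.
    """

    A: float = 0.0002
    B: float = 3e-5
    c: float = 1.1
    age_start: int = 20
    age_end: int = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be non-negative")
        if self.B > 0 and self.c <= 1.0:
            raise ValueError("c must exceed 1 when B > 0")
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")

    def integrated_hazard(self, x) -> np.ndarray:
        """One-year integrated hazard over [x, x+1)."""
        x = np.asarray(x, dtype=float)
        if self.B == 0.0:
            return np.full_like(x, self.A)
        return self.A + self.B * np.power(self.c, x) * (self.c - 1.0) / math.log(self.c)

    def qx(self, x) -> np.ndarray:
        """Annual death probability implied by the hazard."""
        return -np.expm1(-self.integrated_hazard(x))


def make_base_table(
    params: GompertzMakehamParams = GompertzMakehamParams(),
    sex: str = "male",
    cohort_year: int = 1970,
) -> LifeTable:
    """Smooth synthetic general-mortality table, closed at ``age_end``.

    Rejects parameter sets so heavy that q reaches 1 before age 60: such
    schedules are not plausible adult mortality and break the abridged-grid
    interpolation assumptions downstream.
    """
    ages = np.arange(params.age_start, params.age_end + 1)
    q = params.qx(ages)
    early = ages < 60
    if np.any(q[early] >= 1.0):
        raise ValueError("parameters give q >= 1 before age 60; implausible")
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(sex=sex, cohort_year=cohort_year, state="independent",
                     age_start=params.age_start, q=q)


def make_dependent_pair(
    params: GompertzMakehamParams = GompertzMakehamParams(),
    excess: ExcessParams | None = None,
    sex: str = "male",
    cohort_year: int = 1970,
) -> tuple[LifeTable, LifeTable]:
    """(independent, dependent) pair where the dependent table is exactly
    the mixed-correction image of the independent one — the round-trip
    oracle for parameter recovery."""
    from .dependent import SPAIN_SEVERE_MEN

    if excess is None:
        excess = SPAIN_SEVERE_MEN
    base = make_base_table(params, sex=sex, cohort_year=cohort_year)
    dep = derive_dependent_table(base, excess)
    return base, dep


def noisy_observations(
    params: GompertzMakehamParams,
    excess: ExcessParams,
    noise_amplitude: float = 1e-4,
    n_ages: int = 40,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """(age, q_general, q_dependent) triples with uniform noise of the given
    amplitude added to the dependent rates; for fit-robustness tests."""
    rng = np.random.default_rng(seed)
    base, dep = make_dependent_pair(params, excess)
    ages = np.linspace(base.age_start, base.omega - 1, n_ages).round().astype(int)
    ages = np.unique(ages)
    q_g = np.array([base.qx(a) for a in ages])
    q_d = np.array([dep.qx(a) for a in ages])
    q_d = np.clip(q_d + rng.uniform(-noise_amplitude, noise_amplitude, q_d.size), 0, 1)
    return np.column_stack([ages, q_g, q_d])


# -- 1970-cohort Spanish fixture --------------------------------------------

# Printed 5-year-grid values, ages 20-100, both sexes: general rates (q_m,
# q_f), general expectancies (e_m, e_f), dependent rates (qd_m, qd_f) and
# dependent expectancies (ed_m, ed_f).  Stored verbatim; no smoothing.
_TABLE3_CSV = """\
age,q_m,q_f,e_m,e_f,qd_m,qd_f,ed_m,ed_f
20,0.009005,0.010674,85.4,92.5,0.009095,0.011724,54.3,48.6
25,0.000317,0.000285,81.4,88.7,0.000486,0.001895,49.9,44.5
30,0.000221,0.000162,76.5,83.8,0.000539,0.002627,45.0,39.9
35,0.000453,0.000202,71.6,78.9,0.001050,0.003963,40.2,35.5
40,0.001134,0.000280,66.8,74.0,0.002256,0.005997,35.4,31.3
45,0.001261,0.000275,62.2,69.1,0.003365,0.008909,30.9,27.3
50,0.001265,0.000325,57.6,64.2,0.005198,0.013246,26.4,23.5
55,0.001134,0.000340,52.9,59.3,0.008439,0.019416,22.2,20.2
60,0.001270,0.000395,48.2,54.4,0.014677,0.028025,18.2,17.2
65,0.001650,0.000518,43.5,49.5,0.025737,0.039513,14.6,14.6
70,0.002431,0.000740,38.9,44.6,0.054135,0.060454,11.6,12.5
75,0.003742,0.001048,34.4,39.8,0.085696,0.077951,9.1,10.8
80,0.005241,0.001447,30.1,35.0,0.124647,0.096128,7.3,9.4
85,0.007708,0.002037,25.9,30.2,0.165352,0.113471,6.1,8.4
90,0.010964,0.003079,21.9,25.6,0.201444,0.129209,5.3,7.6
95,0.017031,0.005315,18.2,21.0,0.231195,0.143675,4.7,7.0
100,0.025290,0.009638,14.7,16.6,0.255807,0.158651,4.4,6.3
"""

#: SHA-256 of the shipped fixture text, for integrity checks.
TABLE3_SHA256 = hashlib.sha256(_TABLE3_CSV.encode()).hexdigest()


@dataclass(frozen=True, eq=False)
class Table3Fixture:
    """The 1970 Spanish cohort fixture as a tidy DataFrame plus helpers.

    ``frame`` has one row per 5-year age (20-100) and columns
    ``q_m, q_f, e_m, e_f, qd_m, qd_f, ed_m, ed_f`` (m = men, f = women,
    ``d`` = severely/highly dependent).  Expectancies are printed values;
    their convention (curtate vs complete) and old-age closure are not
    disclosed by the source, so they are treated as data, not re-derived.
    """

    frame: pd.DataFrame

    cohort_year: int = 1970

    def column(self, sex: str, state: str, kind: str) -> pd.Series:
        """Select a column by sex ('male'/'female'), state
        ('independent'/'dependent') and kind ('q'/'e')."""
        s = {"male": "m", "female": "f"}[sex]
        prefix = {"independent": "", "dependent": "d"}[state]
        name = f"{kind}{prefix}_{s}"
        return self.frame.set_index("age")[name]

    def to_life_table(self, sex: str, state: str,
                      omega: int = DEFAULT_OMEGA) -> LifeTable:
        """Build a full single-age LifeTable from the 5-year q grid
        (log-q interpolation inside the grid, log-linear extension to
        omega).  Expectancies of the result will differ from the printed
        e columns, which embed undisclosed closure assumptions."""
        q = self.column(sex, state, "q")
        return build_life_table(q, sex=sex, cohort_year=self.cohort_year,
                                state=state, omega=omega)

    def checksum(self) -> str:
        return TABLE3_SHA256


def fixture_table3() -> Table3Fixture:
    """The shipped 1970-cohort fixture bundle (printed values, verbatim)."""
    frame = pd.read_csv(io.StringIO(_TABLE3_CSV))
    return Table3Fixture(frame=frame)
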