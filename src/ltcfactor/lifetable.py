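"""Cohort life tables indexed by single attained age.

A :class:`LifeTable` holds one sex / birth-cohort / health-state mortality
schedule ``q_x`` (the probability that a life aged exactly ``x`` dies before
``x + 1``) on a contiguous integer age grid, closed at a terminal age
``omega`` with ``q(omega) = 1``.  All derived quantities — survivors ``l_x``,
the survival function ``s(x)``, multi-year survival probabilities, the force
of mortality and life expectancies — are computed from that grid.

The toolkit is discrete-annual throughout: the continuous force of mortality
is linked to the annual grid through a piecewise-constant intensity over each
year of age, ``mu_x = -ln(1 - q_x)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "build_life_table",
    "survival_prob",
    "force_of_mortality",
    "life_expectancy",
    "read_qx_csv",
    "write_qx_csv",
]

Sex = Literal["male", "female"]
State = Literal["independent", "dependent"]
Convention = Literal["curtate", "complete"]

#: Default terminal age when a schedule does not reach q = 1.
DEFAULT_OMEGA = 120

#: Largest run of missing interior ages that interpolation will bridge.
MAX_GAP = 4


class LifeTableError(ValueError):
    """Raised for invalid schedules: gaps beyond the interpolation limit,
    probabilities outside [0, 1], empty input, or out-of-range queries."""


@dataclass(frozen=True, eq=False)
class LifeTable:
    """Closed cohort mortality table for one sex, cohort and health state.

    Parameters
    ----------
    sex : {"male", "female"}
    cohort_year : int
        Birth year of the cohort; metadata only, no projection is applied.
    state : {"independent", "dependent"}
        Health state the schedule describes.
    age_start : int
        First age of the grid.
    q : numpy.ndarray
        Annual death probabilities for ages ``age_start .. omega``
        (inclusive); the last entry is always 1.
    radix : float
        Survivors at ``age_start`` (conventional, default 100 000).  Every
        derived quantity is radix-invariant.
    """

    sex: Sex
    cohort_year: int
    state: State
    age_start: int
    q: np.ndarray
    radix: float = 100_000.0
    _lx: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise LifeTableError("q schedule must be a non-empty 1-d array")
        if np.any((q < 0.0) | (q > 1.0)) or np.any(~np.isfinite(q)):
            raise LifeTableError("all q must lie in [0, 1]")
        if q[-1] != 1.0:
            raise LifeTableError("table must close with q(omega) = 1")
        if self.radix <= 0:
            raise LifeTableError("radix must be positive")
        object.__setattr__(self, "q", q)
        # survivors l_x for x = age_start .. omega + 1 (last entry is 0)
        lx = self.radix * np.concatenate(([1.0], np.cumprod(1.0 - q)))
        object.__setattr__(self, "_lx", lx)

    # -- basic structure ---------------------------------------------------

    @property
    def omega(self) -> int:
        """Terminal age: the last age of the grid, where q = 1."""
        return self.age_start + self.q.size - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_start, self.omega + 1)

    def __contains__(self, age: int) -> bool:
        return self.age_start <= age <= self.omega

    def _index(self, x: int) -> int:
        if x not in self:
            raise LifeTableError(
                f"age {x} outside table range [{self.age_start}, {self.omega}]"
            )
        return int(x) - self.age_start

    def qx(self, x: int) -> float:
        """Annual death probability at age ``x``."""
        return float(self.q[self._index(x)])

    def lx(self, x: int) -> float:
        """Survivors to age ``x`` out of ``radix`` at ``age_start``.

        Defined for ``age_start <= x <= omega + 1``; the final value is 0.
        """
        if not self.age_start <= x <= self.omega + 1:
            raise LifeTableError(f"age {x} outside [{self.age_start}, {self.omega + 1}]")
        return float(self._lx[int(x) - self.age_start])

    def survival_function(self, x: int) -> float:
        """s(x) = l_x / l(age_start), the probability a life at the first
        table age is still alive at ``x``."""
        return self.lx(x) / self.radix

    def death_distribution(self, x: int) -> float:
        """F(x) = 1 - s(x)."""
        return 1.0 - self.survival_function(x)

    # -- survival and intensity --------------------------------------------

    def survival_prob(self, x: int, t: int) -> float:
        """``t``-year survival probability for a life aged ``x``.

        Returns the product of one-year survivals, identically
        ``l_{x+t} / l_x``; ``t = 0`` gives 1 and spanning past ``omega``
        gives 0 by closure.
        """
        if t < 0:
            raise LifeTableError("t must be non-negative")
        i = self._index(x)
        if x + t > self.omega + 1:
            raise LifeTableError(
                f"age {x}+{t} beyond omega+1 = {self.omega + 1}"
            )
        return float(np.prod(1.0 - self.q[i : i + t]))

    def force_of_mortality(self, x: int) -> float:
        """Constant intensity over [x, x+1) consistent with q_x.

        Under a piecewise-constant hazard, ``exp(-mu) = 1 - q_x`` so
        ``mu = -ln(1 - q_x)``.  A closing age with q = 1 has no finite
        intensity and raises.
        """
        qx = self.qx(x)
        if qx >= 1.0:
            raise LifeTableError(f"q({x}) = 1: force of mortality is infinite")
        return -math.log1p(-qx)

    # -- expectancy ---------------------------------------------------------

    def life_expectancy(self, x: int, convention: Convention = "complete") -> float:
        """Residual life expectancy at age ``x``.

        ``curtate`` is the expected number of whole future years survived,
        ``sum_{t>=1} tPx``; ``complete`` adds the conventional half year for
        the part-year lived in the year of death.
        """
        i = self._index(x)
        tpx = np.cumprod(1.0 - self.q[i:])
        curtate = float(tpx.sum())
        if convention == "curtate":
            return curtate
        if convention == "complete":
            return curtate + 0.5
        raise ValueError(f"unknown convention {convention!r}")

    def annuity_due_count(self, x: int, w: int | None = None) -> float:
        """Expected number of annual payments made at the start of each
        survived year from ``x`` up to (not including) age ``w``.

        Equals ``1 + curtate expectancy truncated at w``; this is the
        zero-interest annuity-due value and the expectancy convention under
        which the conversion factor makes the benefit swap exactly cost-free.
        """
        if w is None:
            w = self.omega + 1
        if w <= x:
            raise LifeTableError(f"truncation age {w} must exceed {x}")
        i = self._index(x)
        n = min(w - x, self.omega + 1 - x)
        tpx = np.concatenate(([1.0], np.cumprod(1.0 - self.q[i : i + n - 1])))
        return float(tpx.sum())

    # -- export -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Table as a DataFrame with columns age, qx, lx."""
        return pd.DataFrame(
            {"age": self.ages, "qx": self.q, "lx": self._lx[:-1]}
        )

    def metadata(self) -> dict:
        return {
            "sex": self.sex,
            "cohort_year": self.cohort_year,
            "state": self.state,
            "age_start": self.age_start,
            "omega": self.omega,
            "radix": self.radix,
        }


# -- construction -----------------------------------------------------------


def _interpolate_gaps(ages: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing interior ages (runs of at most MAX_GAP) by linear
    interpolation of log q.  Zero rates interpolate through a floor."""
    steps = np.diff(ages)
    if np.any(steps <= 0):
        raise LifeTableError("ages must be strictly increasing")
    if np.any(steps > MAX_GAP + 1):
        bad = ages[np.argmax(steps > MAX_GAP + 1)]
        raise LifeTableError(
            f"gap after age {bad} exceeds {MAX_GAP} missing years; "
            "supply a finer grid"
        )
    full = np.arange(ages[0], ages[-1] + 1)
    if full.size == ages.size:
        return full, q.astype(float)
    tiny = 1e-12
    logq = np.log(np.maximum(q, tiny))
    qi = np.exp(np.interp(full, ages, logq))
    qi[np.isin(full, ages)] = q  # keep supplied values exact
    qi[qi <= tiny * 10] = 0.0
    return full, qi


def _extend_to_omega(ages: np.ndarray, q: np.ndarray, omega: int) -> tuple[np.ndarray, np.ndarray]:
    """Extend a schedule whose last q < 1 up to ``omega`` by log-linear
    extrapolation of q (slope from the last two ages), capped at 1."""
    if q[-1] == 1.0:
        return ages, q
    last = ages[-1]
    if last >= omega:
        out_q = q.copy()
        out_q[-1] = 1.0
        return ages, out_q
    tiny = 1e-12
    if ages.size >= 2 and q[-2] > 0 and q[-1] > 0:
        slope = math.log(q[-1]) - math.log(q[-2])
        slope = max(slope, 0.0)  # never let mortality fall with age here
    else:
        slope = math.log(1.1)
    ext_ages = np.arange(last + 1, omega + 1)
    ext_q = np.minimum(np.exp(math.log(max(q[-1], tiny)) + slope * (ext_ages - last)), 1.0)
    out_ages = np.concatenate((ages, ext_ages))
    out_q = np.concatenate((q, ext_q))
    out_q[-1] = 1.0
    return out_ages, out_q


def build_life_table(
    q_schedule: Mapping[int, float] | pd.Series,
    sex: Sex = "male",
    cohort_year: int = 1970,
    state: State = "independent",
    radix: float = 100_000.0,
    omega: int = DEFAULT_OMEGA,
) -> LifeTable:
    """Build a validated, closed :class:`LifeTable` from an age -> q mapping.

    The schedule may be abridged: runs of up to four missing interior ages
    (a 5-year grid) are filled by linear interpolation of log q.  If the
    supplied schedule does not reach q = 1, it is extended to ``omega`` by
    log-linear extrapolation of q, capped at 1, and the terminal q is forced
    to 1 so that the table closes.

    Raises
    ------
    LifeTableError
        On an empty schedule, probabilities outside [0, 1], or interior gaps
        wider than the interpolation limit.
    """
    if isinstance(q_schedule, pd.Series):
        items = list(q_schedule.items())
    else:
        items = list(q_schedule.items())
    if not items:
        raise LifeTableError("empty q schedule")
    items.sort(key=lambda kv: kv[0])
    ages = np.array([int(a) for a, _ in items])
    q = np.array([float(v) for _, v in items])
    if np.any((q < 0.0) | (q > 1.0)) or np.any(~np.isfinite(q)):
        raise LifeTableError("q values must lie in [0, 1]")
    # truncate anything after the first q = 1 (the table is closed there)
    hit = np.flatnonzero(q >= 1.0)
    if hit.size:
        ages, q = ages[: hit[0] + 1], q[: hit[0] + 1]
        q[-1] = 1.0
    ages, q = _interpolate_gaps(ages, q)
    ages, q = _extend_to_omega(ages, q, omega)
    return LifeTable(
        sex=sex, cohort_year=cohort_year, state=state,
        age_start=int(ages[0]), q=q, radix=radix,
    )


# -- functional wrappers (CLI / scripting surface) ---------------------------


def survival_prob(table: LifeTable, x: int, t: int) -> float:
    """Probability a life aged ``x`` in ``table`` survives ``t`` more years."""
    return table.survival_prob(x, t)


def force_of_mortality(table: LifeTable, x: int) -> float:
    """Piecewise-constant force of mortality over [x, x+1)."""
    return table.force_of_mortality(x)


def life_expectancy(table: LifeTable, x: int, convention: Convention = "complete") -> float:
    """Residual life expectancy at ``x`` under the given convention."""
    return table.life_expectancy(x, convention)


# -- CSV I/O -----------------------------------------------------------------


def read_qx_csv(path: str | Path, **build_kwargs) -> LifeTable:
    """Read an ``age,qx`` CSV (1-year or abridged grid) into a LifeTable.

    A sidecar ``<path>.meta.json`` with sex / cohort_year / state / radix is
    honoured when present; keyword arguments override it.
    """
    df = pd.read_csv(path)
    if not {"age", "qx"} <= set(df.columns):
        raise LifeTableError("CSV must have columns 'age' and 'qx'")
    meta_path = Path(str(path) + ".meta.json")
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    meta.update(build_kwargs)
    allowed = {"sex", "cohort_year", "state", "radix", "omega"}
    meta = {k: v for k, v in meta.items() if k in allowed}
    return build_life_table(dict(zip(df["age"].astype(int), df["qx"])), **meta)


def write_qx_csv(table: LifeTable, path: str | Path, sidecar: bool = True) -> None:
    """Write the table's q schedule as ``age,qx`` CSV (UTF-8, decimal point)."""
    table.to_frame()[["age", "qx"]].to_csv(path, index=False)
    if sidecar:
        meta = table.metadata()
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))
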