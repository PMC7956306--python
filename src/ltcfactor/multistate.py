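"""Discrete annual multistate model: active / retired / dependent /
disabled / dead.

One transition per year, no return to previous states.  Before retirement
an active life can stay active, become disabled, die, or retire; a retiree
can stay retired, die, or — if they choose to convert their pension —
become (severely/highly) dependent; a dependent life can only stay or die.
Each age's exit probabilities must sum to one exactly.

The conversion decision is exogenous: a 0/1 indicator per age.  While the
indicator is 0 the dependency-exit mass stays in the retired state (the
beneficiary keeps the retirement pension); once it switches to 1 it stays 1
(no return).  :func:`project_cohort` propagates expected state counts;
``simulate_paths`` is a seeded Monte-Carlo illustration of the same chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionRow",
    "ConversionDecision",
    "RowReport",
    "validate_row",
    "project_cohort",
    "simulate_paths",
    "STATES",
]

Phase = Literal["active", "retired", "dependent"]

#: Projection state order (dead is cumulative).
STATES = ("active", "retired", "dependent", "disabled", "dead")

_REQUIRED_KEYS = {
    "active": ("p_stay", "q_disab", "q_death", "q_retire"),
    "retired": ("p_stay", "q_death", "q_dependent"),
    "dependent": ("p_stay", "q_death"),
}


@dataclass(frozen=True)
class TransitionRow:
    """One age's exit probabilities for one phase of life."""

    age: int
    phase: Phase
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        keys = _REQUIRED_KEYS.get(self.phase)
        if keys is None:
            raise ValueError(f"unknown phase {self.phase!r}")
        missing = set(keys) - set(self.probabilities)
        if missing:
            raise ValueError(f"{self.phase} row at age {self.age} missing {missing}")

    def vector(self) -> np.ndarray:
        return np.array([self.probabilities[k] for k in _REQUIRED_KEYS[self.phase]])


@dataclass(frozen=True)
class ConversionDecision:
    """Per-age 0/1 conversion indicator; once 1, it must remain 1."""

    indicator: dict[int, int]

    def __post_init__(self) -> None:
        ages = sorted(self.indicator)
        seen_one = False
        for a in ages:
            v = self.indicator[a]
            if v not in (0, 1):
                raise ValueError(f"indicator at age {a} must be 0 or 1")
            if seen_one and v == 0:
                raise ValueError("conversion decision cannot revert to 0")
            seen_one = seen_one or v == 1
        object.__setattr__(self, "indicator", dict(self.indicator))

    def at(self, age: int) -> int:
        if age in self.indicator:
            return self.indicator[age]
        prior = [a for a in self.indicator if a <= age]
        return self.indicator[max(prior)] if prior else 0

    @classmethod
    def never(cls) -> "ConversionDecision":
        return cls(indicator={})

    @classmethod
    def from_age(cls, age: int) -> "ConversionDecision":
        return cls(indicator={age: 1})


@dataclass(frozen=True)
class RowReport:
    """Validation outcome for one transition row."""

    age: int
    phase: str
    total: float
    deviation: float
    passed: bool
    out_of_range: tuple[str, ...] = field(default_factory=tuple)


def validate_row(row: TransitionRow, tolerance: float = 1e-9) -> RowReport:
    """Check the closure identity: probabilities in [0,1] and summing to 1.

    Always returns a report; never raises.
    """
    vec = row.vector()
    total = float(vec.sum())
    bad = tuple(
        k for k, v in zip(_REQUIRED_KEYS[row.phase], vec)
        if not 0.0 <= v <= 1.0
    )
    dev = abs(total - 1.0)
    return RowReport(
        age=row.age, phase=row.phase, total=total, deviation=dev,
        passed=(dev <= tolerance and not bad), out_of_range=bad,
    )


def _rows_by_key(rows: Iterable[TransitionRow]) -> dict[tuple[int, str], TransitionRow]:
    out: dict[tuple[int, str], TransitionRow] = {}
    for r in rows:
        out[(r.age, r.phase)] = r
    return out


def project_cohort(
    rows: Sequence[TransitionRow],
    initial: dict[str, float] | Sequence[float],
    age_start: int,
    horizon: int,
    decision: ConversionDecision | None = None,
    check_mass: bool = True,
) -> pd.DataFrame:
    """Deterministic expected-count projection of the cohort.

    Parameters
    ----------
    rows : transition rows covering every (age, phase) with mass.
    initial : state counts at ``age_start`` in the order of :data:`STATES`
        (or a dict keyed by state name); ``dead`` is cumulative.
    horizon : number of annual steps to project.
    decision : conversion indicator; default never converts, so the
        dependency-exit mass remains retired.

    Returns
    -------
    DataFrame indexed by age (``age_start .. age_start + horizon``) with
    one column per state.  Disabled and dead are absorbing.  Total mass is
    conserved at every step (checked to 1e-9 unless ``check_mass=False``).
    """
    if decision is None:
        decision = ConversionDecision.never()
    table = _rows_by_key(rows)
    counts = np.zeros(len(STATES))
    if isinstance(initial, dict):
        for k, v in initial.items():
            counts[STATES.index(k)] = float(v)
    else:
        counts[: len(initial)] = np.asarray(initial, dtype=float)
    if np.any(counts < 0):
        raise ValueError("initial counts must be non-negative")
    total0 = counts.sum()

    out = [counts.copy()]
    iA, iR, iD, iI, iM = range(5)
    for step in range(horizon):
        age = age_start + step
        new = counts.copy()
        # active transitions
        if counts[iA] > 0:
            row = table.get((age, "active"))
            if row is None:
                raise KeyError(f"missing active transition row at age {age}")
            p = row.probabilities
            new[iA] -= counts[iA] * (p["q_disab"] + p["q_death"] + p["q_retire"])
            new[iI] += counts[iA] * p["q_disab"]
            new[iM] += counts[iA] * p["q_death"]
            new[iR] += counts[iA] * p["q_retire"]
        # retired transitions
        if counts[iR] > 0:
            row = table.get((age, "retired"))
            if row is None:
                raise KeyError(f"missing retired transition row at age {age}")
            p = row.probabilities
            q_dep = p["q_dependent"] * decision.at(age)
            new[iR] -= counts[iR] * (p["q_death"] + q_dep)
            new[iM] += counts[iR] * p["q_death"]
            new[iD] += counts[iR] * q_dep
        # dependent transitions
        if counts[iD] > 0:
            row = table.get((age, "dependent"))
            if row is None:
                raise KeyError(f"missing dependent transition row at age {age}")
            p = row.probabilities
            # only mass present at the start of the step can exit: lives
            # that became dependent this year make no second transition
            new[iD] -= counts[iD] * p["q_death"]
            new[iM] += counts[iD] * p["q_death"]
        counts = new
        if check_mass and abs(counts.sum() - total0) > 1e-9 * max(total0, 1.0):
            raise AssertionError(
                f"mass not conserved at age {age + 1}: "
                f"{counts.sum()} vs {total0}"
            )
        out.append(counts.copy())
    ages = np.arange(age_start, age_start + horizon + 1)
    return pd.DataFrame(out, index=pd.Index(ages, name="age"), columns=STATES)


def simulate_paths(
    rows: Sequence[TransitionRow],
    n: int,
    age_start: int,
    horizon: int,
    decision: ConversionDecision | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo occupancy counts for ``n`` lives starting active (or
    retired if no active row exists at ``age_start``).  Illustrative
    companion to :func:`project_cohort`; same chain, sampled."""
    if decision is None:
        decision = ConversionDecision.never()
    rng = np.random.default_rng(seed)
    table = _rows_by_key(rows)
    start_state = 0 if (age_start, "active") in table else 1
    states = np.full(n, start_state)
    counts = [np.bincount(states, minlength=len(STATES))]
    for step in range(horizon):
        age = age_start + step
        new = states.copy()
        for idx, phase in ((0, "active"), (1, "retired"), (2, "dependent")):
            mask = states == idx
            if not mask.any():
                continue
            row = table.get((age, phase))
            if row is None:
                raise KeyError(f"missing {phase} transition row at age {age}")
            p = dict(row.probabilities)
            if phase == "active":
                dests = [0, 4, 3, 1]  # stay, die, disable, retire
                probs = [p["p_stay"], p["q_death"], p["q_disab"], p["q_retire"]]
            elif phase == "retired":
                q_dep = p["q_dependent"] * decision.at(age)
                dests = [1, 4, 2]
                probs = [p["p_stay"] + p["q_dependent"] - q_dep, p["q_death"], q_dep]
            else:
                dests = [2, 4]
                probs = [p["p_stay"], p["q_death"]]
            draw = rng.choice(len(dests), size=int(mask.sum()), p=np.array(probs) / sum(probs))
            new[mask] = np.array(dests)[draw]
        states = new
        counts.append(np.bincount(states, minlength=len(STATES)))
    ages = np.arange(age_start, age_start + horizon + 1)
    return pd.DataFrame(counts, index=pd.Index(ages, name="age"), columns=STATES)


def rows_from_tables(
    ind, dep, retirement_age: int,
    q_dependent: float | dict[int, float] = 0.0,
) -> list[TransitionRow]:
    """Build retired/dependent transition rows from a pair of life tables.

    The retired phase uses the independent table's mortality and a
    user-supplied annual dependency-incidence probability; the dependent
    phase uses the dependent table's mortality.  Rows cover ages from
    ``retirement_age`` to the common omega.
    """
    rows: list[TransitionRow] = []
    hi = min(ind.omega, dep.omega)
    for age in range(retirement_age, hi + 1):
        qd = q_dependent.get(age, 0.0) if isinstance(q_dependent, dict) else q_dependent
        qm = ind.qx(age)
        qd = min(qd, 1.0 - qm)
        rows.append(TransitionRow(age, "retired", {
            "p_stay": 1.0 - qm - qd, "q_death": qm, "q_dependent": qd,
        }))
        qdm = dep.qx(age)
        rows.append(TransitionRow(age, "dependent", {
            "p_stay": 1.0 - qdm, "q_death": qdm,
        }))
    return rows
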