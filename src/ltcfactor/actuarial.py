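"""Discounting, present values of pension benefits, and the cost-free
equivalence check.

The present value of future benefits (PVFB) for a pensioner aged ``x`` is
the expected discounted benefit stream up to the terminal age ``w``,
discretised as an annual annuity-due (payment at the start of each survived
year)::

    PVFB_x = sum_{t=0}^{w-x-1} b(x+t) * tPx * v(t)

with ``v(t) = exp(-integral of the discount intensity over [0, t])``.

The conversion is *cost-free* when ``lambda * PVFB(dependent) =
PVFB(independent)``.  With the factor defined as a ratio of life
expectancies this identity is exact at zero interest under the matching
truncated-curtate convention; at positive interest the signed relative
residual quantifies the approximation, and :func:`annuity_lambda` computes
the PVFB-ratio factor that restores exactness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lifetable import LifeTable

__all__ = [
    "DiscountCurve",
    "PensionSpec",
    "discount_factor",
    "pvfb",
    "check_equivalence",
    "annuity_lambda",
]


@dataclass(frozen=True)
class DiscountCurve:
    """Piecewise-constant instantaneous discount intensity.

    ``boundaries`` are the (sorted, positive) times at which the intensity
    changes; ``rates`` has one more entry than ``boundaries`` (the last rate
    extends to infinity).  A single rate gives the constant-intensity
    shortcut ``v(T) = exp(-rate * T)``.
    """

    rates: tuple[float, ...]
    boundaries: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more rate than boundary")
        if any(b <= 0 for b in self.boundaries) or list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("boundaries must be positive and increasing")

    @classmethod
    def flat(cls, rate: float) -> "DiscountCurve":
        return cls(rates=(float(rate),))

    def integrated(self, T: float) -> float:
        """Exact integral of the intensity over [0, T]."""
        if T < 0:
            raise ValueError("T must be non-negative")
        total, prev = 0.0, 0.0
        for rate, b in zip(self.rates, self.boundaries):
            if T <= b:
                return total + rate * (T - prev)
            total += rate * (b - prev)
            prev = b
        return total + self.rates[-1] * (T - prev)

    def factor(self, T: float) -> float:
        """Discount factor v(T) = exp(-integrated intensity)."""
        return float(np.exp(-self.integrated(T)))


@dataclass(frozen=True)
class PensionSpec:
    """Benefit definition: annual amount ``b`` (level, per-age array over
    [r, w), or a callable of age), retirement age ``r`` and terminal age
    ``w`` (payments stop at w)."""

    b: float | Sequence[float] | Callable[[int], float]
    retirement_age: int
    terminal_age: int

    def __post_init__(self) -> None:
        if self.retirement_age >= self.terminal_age:
            raise ValueError("retirement age must precede terminal age")
        if isinstance(self.b, (int, float)) and self.b < 0:
            raise ValueError("benefit must be non-negative")

    def benefit_at(self, age: int) -> float:
        if callable(self.b):
            return float(self.b(age))
        if isinstance(self.b, (int, float)):
            return float(self.b)
        return float(self.b[age - self.retirement_age])


def discount_factor(curve: DiscountCurve, T: float) -> float:
    """v(T) for the given curve; v(0) = 1."""
    return curve.factor(T)


def pvfb(
    table: LifeTable,
    spec: PensionSpec,
    curve: DiscountCurve,
    x: int,
    timing: str = "due",
) -> float:
    """Actuarial present value at age ``x`` of the benefit stream to ``w``.

    ``timing="due"`` (default) pays at the start of each survived year;
    ``"immediate"`` at the end.  With a unit benefit and zero interest the
    annuity-due value equals one plus the curtate expectancy truncated at
    ``w``.
    """
    r, w = spec.retirement_age, spec.terminal_age
    if not r <= x < w:
        raise ValueError(f"age {x} outside payment window [{r}, {w})")
    if x not in table:
        raise ValueError(f"age {x} not covered by the table")
    n = min(w - x, table.omega + 1 - x)
    total = 0.0
    if timing == "due":
        for t in range(n):
            tpx = table.survival_prob(x, t)
            if tpx == 0.0:
                break
            total += spec.benefit_at(x + t) * tpx * curve.factor(t)
    elif timing == "immediate":
        for t in range(1, n + 1):
            tpx = table.survival_prob(x, t)
            if tpx == 0.0:
                break
            total += spec.benefit_at(x + t - 1) * tpx * curve.factor(t)
    else:
        raise ValueError("timing must be 'due' or 'immediate'")
    return total


def annuity_lambda(
    ind: LifeTable,
    dep: LifeTable,
    spec: PensionSpec,
    curve: DiscountCurve,
    x: int,
) -> float:
    """PVFB-ratio conversion factor: exactly cost-free at any interest."""
    denom = pvfb(dep, spec, curve, x)
    if denom == 0.0:
        raise ZeroDivisionError("dependent PVFB is zero")
    return pvfb(ind, spec, curve, x) / denom


def check_equivalence(
    ind: LifeTable,
    dep: LifeTable,
    spec: PensionSpec,
    curve: DiscountCurve,
    x: int,
    lam: float,
) -> float:
    """Signed relative residual of the cost-free identity.

    Returns ``(lambda * PVFB_dep - PVFB_ind) / PVFB_ind``.  Zero (to
    floating tolerance) when ``lambda`` is the truncated-curtate expectancy
    ratio and the interest is zero; otherwise the value measures how far the
    expectancy-ratio factor is from exact actuarial equivalence.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    base = pvfb(ind, spec, curve, x)
    if base == 0.0:
        raise ZeroDivisionError("independent PVFB is zero")
    return (lam * pvfb(dep, spec, curve, x) - base) / base
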