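"""Matplotlib views of the toolkit's main outputs.

Each function draws onto a supplied Axes (creating one if needed) and
returns it, so figures compose in user scripts.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

from .conversion import ConversionSchedule
from .lifetable import LifeTable

__all__ = [
    "plot_excess_mortality",
    "plot_payment_reduction",
    "plot_sex_differential",
    "plot_lambda",
]


def _ax(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_excess_mortality(ind: LifeTable, dep: LifeTable, ax=None,
                          relative: bool = True):
    """Dependent-over-general mortality by age: q_dep/q - 1 (relative,
    default) or the two schedules on a log scale."""
    ax = _ax(ax)
    lo = max(ind.age_start, dep.age_start)
    hi = min(ind.omega, dep.omega)
    ages = np.arange(lo, hi + 1)
    qi = np.array([ind.qx(a) for a in ages])
    qd = np.array([dep.qx(a) for a in ages])
    if relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            ax.plot(ages, np.where(qi > 0, qd / qi - 1.0, np.nan))
        ax.set_ylabel("relative excess mortality  $q^d_x/q_x - 1$")
    else:
        ax.semilogy(ages, qi, label="general")
        ax.semilogy(ages, qd, label="dependent")
        ax.set_ylabel("$q_x$")
        ax.legend()
    ax.set_xlabel("age")
    return ax


def plot_payment_reduction(schedule: ConversionSchedule, ax=None):
    """Expected payment-years forgone on dependency, by conversion age."""
    ax = _ax(ax)
    ax.plot(schedule.frame["age"], schedule.frame["payment_reduction"])
    ax.set_xlabel("age at conversion")
    ax.set_ylabel("reduction in expected payments (years)")
    return ax


def plot_sex_differential(schedule: ConversionSchedule, ax=None):
    """Female/male dependent-mortality differential by age."""
    ax = _ax(ax)
    ax.plot(schedule.frame["age"], schedule.frame["sex_diff"])
    ax.axhline(0.0, lw=0.5, color="k")
    ax.set_xlabel("age")
    ax.set_ylabel("$q^d_{x,f}/q^d_{x,m} - 1$")
    return ax


def plot_lambda(schedule: ConversionSchedule, ax=None, label=None):
    """Conversion factor by age."""
    ax = _ax(ax)
    ax.plot(schedule.frame["age"], schedule.frame["lambda"], label=label)
    ax.set_xlabel("age at conversion")
    ax.set_ylabel(r"conversion factor $\lambda_x$")
    if label:
        ax.legend()
    return ax
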