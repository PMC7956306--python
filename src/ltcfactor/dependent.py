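"""Excess mortality of severely / highly dependent lives.

Dependent (long-term-care) lives die faster than the general insured
population at every age.  Three corrections map a general schedule
``q_x`` to a dependent schedule ``q_x^d``:

* multiplicative: ``q^d = theta * q`` with a constant loading ``theta > 1``;
* additive: ``q^d = q + eps(x)`` with an age-indexed excess;
* mixed: an additive logistic-in-age term plus, from a switch age onward,
  a multiplicative loading that reproduces the narrowing of the absolute
  differentials at the oldest ages::

      q^d(x) = q(x)           + delta / (1 + gamma**(x_i - x))   x <  switch_age
      q^d(x) = q(x)*(1+beta)  + delta / (1 + gamma**(x_i - x))   x >= switch_age

  ``delta`` is the asymptotic excess (the logistic term tends to ``delta``
  as x grows when ``gamma > 1``), ``gamma`` the slope, ``x_i`` the
  inflection age (the term equals ``delta/2`` there) and ``beta`` the
  old-age loading.

The mixed-correction parameters for Spain (severe and high dependency) are
shipped as presets; :class:`ExcessMortalityModel` refits them to observed
(age, q_general, q_dependent) triples by bounded nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .lifetable import LifeTable

__all__ = [
    "ExcessParams",
    "SimpleCorrection",
    "MortalityOrderingError",
    "apply_multiplicative",
    "apply_additive",
    "apply_mixed",
    "derive_dependent_table",
    "fit_excess_params",
    "ExcessMortalityModel",
    "ExcessMortalityResults",
    "SPAIN_SEVERE_MEN",
    "SPAIN_SEVERE_WOMEN",
    "PRESETS",
]


class MortalityOrderingError(ValueError):
    """A correction produced q_dependent < q_general at some age, violating
    the required stochastic ordering of dependent over general mortality."""


@dataclass(frozen=True)
class ExcessParams:
    """Mixed-correction parameter set.

    Attributes
    ----------
    delta : float
        Asymptotic additive excess on the probability scale, in (0, 1).
    gamma : float
        Logistic slope factor, > 0 (monotone increasing in age iff > 1).
    x_i : float
        Inflection age in years (additive term = delta/2 there).
    beta : float
        Multiplicative loading on general mortality from ``switch_age``
        onward, >= 0.
    switch_age : int
        Attained age at which the multiplicative branch activates.
    exponent_convention : {"printed", "mirrored"}
        Sign convention of the logistic exponent: ``gamma**(x_i - x)``
        (default) or the mirrored ``gamma**(x - x_i)``.
    """

    delta: float
    gamma: float
    x_i: float
    beta: float = 0.0
    switch_age: int = 95
    exponent_convention: Literal["printed", "mirrored"] = "printed"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be positive")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")

    def logistic_term(self, x) -> np.ndarray:
        """Additive excess at attained age(s) ``x``."""
        x = np.asarray(x, dtype=float)
        if self.exponent_convention == "printed":
            expo = self.x_i - x
        else:
            expo = x - self.x_i
        return self.delta / (1.0 + np.power(self.gamma, expo))


#: Spanish severe/high-dependency excess-mortality presets (least-squares
#: fits to graduated Spanish dependent-lives data).
SPAIN_SEVERE_MEN = ExcessParams(delta=0.245, gamma=1.135, x_i=62.50, beta=0.1142)
SPAIN_SEVERE_WOMEN = ExcessParams(delta=0.165, gamma=1.09, x_i=58.61, beta=0.0962)
PRESETS: dict[str, ExcessParams] = {
    "spain_severe_men": SPAIN_SEVERE_MEN,
    "spain_severe_women": SPAIN_SEVERE_WOMEN,
}


@dataclass(frozen=True)
class SimpleCorrection:
    """Constant multiplicative (theta) or age-indexed additive (epsilon)
    correction, the two classical alternatives to the mixed form."""

    kind: Literal["multiplicative", "additive"]
    theta: float | None = None
    epsilon: Callable[[np.ndarray], np.ndarray] | float | None = None

    def __post_init__(self) -> None:
        if self.kind == "multiplicative":
            if self.theta is None or self.theta < 1.0:
                raise ValueError("multiplicative correction needs theta >= 1")
        elif self.kind == "additive":
            if self.epsilon is None:
                raise ValueError("additive correction needs epsilon")
        else:
            raise ValueError(f"unknown correction kind {self.kind!r}")


def apply_multiplicative(q, theta: float):
    """``min(theta * q, 1)`` with a constant loading ``theta >= 1``."""
    if theta < 1.0:
        raise ValueError("theta < 1 would make dependent mortality lighter")
    return np.clip(np.asarray(q, dtype=float) * theta, 0.0, 1.0)[()]


def apply_additive(q, x, epsilon):
    """``clip(q + eps(x), 0, 1)`` with an age-indexed additive excess."""
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    eps = epsilon(x) if callable(epsilon) else np.broadcast_to(float(epsilon), x.shape)
    return np.clip(q + eps, 0.0, 1.0)[()]


def apply_mixed(q, x, params: ExcessParams):
    """Mixed logistic-plus-loading correction at attained age(s) ``x``.

    Below ``params.switch_age`` only the logistic term is added; from the
    switch age the general rate is also loaded by ``(1 + beta)``.  Output is
    clipped to [0, 1].
    """
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    add = params.logistic_term(x)
    loaded = np.where(x < params.switch_age, q, q * (1.0 + params.beta))
    return np.clip(loaded + add, 0.0, 1.0)[()]


def branch_jump(q_at_switch: float, params: ExcessParams) -> float:
    """Magnitude of the discontinuity introduced at ``switch_age`` by the
    piecewise form (the corrected rate jumps by ``beta * q``).  Reported,
    not hidden: the piecewise definition is not continuous."""
    return float(params.beta * q_at_switch)


def derive_dependent_table(
    base: LifeTable,
    correction: ExcessParams | SimpleCorrection,
    on_violation: Literal["raise", "ignore"] = "raise",
) -> LifeTable:
    """Map an independent-state table to its dependent-state counterpart.

    The corrected schedule must dominate the base schedule at every age
    (dependent lives cannot die more slowly); a violation raises
    :class:`MortalityOrderingError` unless ``on_violation="ignore"``.
    """
    ages = base.ages.astype(float)
    q = base.q
    if isinstance(correction, ExcessParams):
        q_dep = apply_mixed(q, ages, correction)
    elif correction.kind == "multiplicative":
        q_dep = apply_multiplicative(q, correction.theta)
    else:
        q_dep = apply_additive(q, ages, correction.epsilon)
    q_dep = np.atleast_1d(np.asarray(q_dep, dtype=float))
    q_dep[-1] = 1.0  # closure survives the correction
    bad = q_dep < q - 1e-15
    if bad.any() and on_violation == "raise":
        ages_bad = base.ages[bad]
        raise MortalityOrderingError(
            f"q_dependent < q_general at ages {ages_bad.tolist()[:8]}"
        )
    return LifeTable(
        sex=base.sex, cohort_year=base.cohort_year, state="dependent",
        age_start=base.age_start, q=q_dep, radix=base.radix,
    )


# -- fitting ---------------------------------------------------------------


class ExcessMortalityModel:
    """Mixed excess-mortality correction, fitted to observed rates.

    The data are triples ``(age, q_general, q_dependent)``; the model is the
    mixed correction with parameters ``(delta, gamma, x_i, beta)`` and a
    fixed ``switch_age``.  ``fit`` minimises the sum of squared residuals
    between observed and predicted dependent rates with bounded nonlinear
    least squares, multistarted over a coarse (gamma, x_i) grid to escape
    local minima of the logistic surface.

    Examples
    --------
    >>> model = ExcessMortalityModel(age, q_general, q_dependent)
    >>> res = model.fit()
    >>> res.params.delta
    """

    def __init__(self, age, q_general, q_dependent, switch_age: int = 95,
                 exponent_convention: str = "printed") -> None:
        age = np.asarray(age, dtype=float)
        q_general = np.asarray(q_general, dtype=float)
        q_dependent = np.asarray(q_dependent, dtype=float)
        if not (age.shape == q_general.shape == q_dependent.shape):
            raise ValueError("age, q_general, q_dependent must share a shape")
        if age.size < 6:
            raise ValueError("need at least 6 observations to fit 4 parameters")
        order = np.argsort(age)
        self.age = age[order]
        self.q_general = q_general[order]
        self.q_dependent = q_dependent[order]
        self.switch_age = int(switch_age)
        self.exponent_convention = exponent_convention

    @classmethod
    def from_dataframe(cls, df, age_col="age", general_col="q_general",
                       dependent_col="q_dependent", **kwargs):
        return cls(df[age_col], df[general_col], df[dependent_col], **kwargs)

    @classmethod
    def from_observations(cls, observations: Sequence[tuple[float, float, float]],
                          **kwargs) -> "ExcessMortalityModel":
        arr = np.asarray(list(observations), dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], **kwargs)

    # parameter vector order: (delta, gamma, x_i, beta)
    def _params_obj(self, vec) -> ExcessParams:
        return ExcessParams(
            delta=float(vec[0]), gamma=float(vec[1]), x_i=float(vec[2]),
            beta=float(vec[3]), switch_age=self.switch_age,
            exponent_convention=self.exponent_convention,  # type: ignore[arg-type]
        )

    def predict(self, params: ExcessParams, age=None, q_general=None):
        """Predicted dependent rates under ``params`` (defaults: the data grid)."""
        age = self.age if age is None else np.asarray(age, dtype=float)
        q = self.q_general if q_general is None else np.asarray(q_general, dtype=float)
        return apply_mixed(q, age, params)

    def _residuals(self, vec) -> np.ndarray:
        return self.predict(self._params_obj(vec)) - self.q_dependent

    def fit(self, start: ExcessParams | None = None, multistart: bool = True
            ) -> "ExcessMortalityResults":
        """Bounded least-squares fit; returns a results object.

        Non-convergence does not raise: the best parameter set found is
        returned with ``converged=False``.
        """
        lo = np.array([1e-6, 1e-3, self.age.min() - 30.0, 0.0])
        hi = np.array([1.0 - 1e-6, 10.0, self.age.max() + 30.0, 5.0])
        d0 = float(np.clip(np.max(self.q_dependent - self.q_general), 1e-3, 0.9))
        starts: list[np.ndarray] = []
        if start is not None:
            starts.append(np.array([start.delta, start.gamma, start.x_i, start.beta]))
        mid_age = float(np.median(self.age))
        if multistart:
            for g in (1.05, 1.1, 1.2, 1.5):
                for xi in np.quantile(self.age, [0.25, 0.5, 0.75]):
                    starts.append(np.array([d0, g, xi, 0.05]))
        else:
            starts.append(np.array([d0, 1.1, mid_age, 0.05]))
        best = None
        for s0 in starts:
            s0 = np.clip(s0, lo + 1e-9, hi - 1e-9)
            sol = least_squares(self._residuals, s0, bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        assert best is not None
        params = self._params_obj(best.x)
        rss = float(2.0 * best.cost)
        se = self._standard_errors(best)
        return ExcessMortalityResults(
            model=self, params=params, rss=rss, converged=bool(best.success),
            n_obs=self.age.size, bse=se,
        )

    def _standard_errors(self, sol) -> np.ndarray:
        """Gauss-Newton standard errors from the solution Jacobian; NaN when
        the fit is degenerate (e.g. an exact interpolation)."""
        m, k = sol.jac.shape
        dof = m - k
        if dof <= 0:
            return np.full(k, np.nan)
        rss = 2.0 * sol.cost
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
            return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)


@dataclass
class ExcessMortalityResults:
    """Fit results: parameter estimates, their Gauss-Newton standard errors,
    the residual sum of squares and a convergence flag."""

    model: ExcessMortalityModel
    params: ExcessParams
    rss: float
    converged: bool
    n_obs: int
    bse: np.ndarray

    _names = ("delta", "gamma", "x_i", "beta")

    @property
    def estimates(self) -> np.ndarray:
        p = self.params
        return np.array([p.delta, p.gamma, p.x_i, p.beta])

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    def resid(self) -> np.ndarray:
        return self.fittedvalues() - self.model.q_dependent

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Mixed excess-mortality correction — least-squares fit",
            "=" * 56,
            f"n obs: {self.n_obs:<6d}  switch age: {self.model.switch_age:<4d}"
            f"  converged: {self.converged}",
            f"residual sum of squares: {self.rss:.6e}",
            "-" * 56,
            f"{'param':>8s} {'estimate':>14s} {'std err':>12s}",
        ]
        for name, est, se in zip(self._names, self.estimates, self.bse):
            se_s = f"{se:12.4g}" if np.isfinite(se) else "         nan"
            lines.append(f"{name:>8s} {est:14.6f} {se_s}")
        lines.append("=" * 56)
        return "\n".join(lines)


def fit_excess_params(
    observations: Sequence[tuple[float, float, float]],
    switch_age: int = 95,
    start: ExcessParams | None = None,
) -> ExcessMortalityResults:
    """Fit the mixed correction to ``(age, q_general, q_dependent)`` triples.

    Functional wrapper around :class:`ExcessMortalityModel`; see its docs.
    """
    model = ExcessMortalityModel.from_observations(observations, switch_age=switch_age)
    return model.fit(start=start)
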