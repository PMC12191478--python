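"""Simple-order kinetic fits and Arrhenius analysis.

Each response is fitted to the three classical integrated rate laws by
ordinary least squares on the linearized form:

* zero order:   C = C0 + k0*t          (regress C on t)
* first order:  C = C0 * exp(k1*t)     (regress ln C on t)
* second order: 1/C - 1/C0 = k2*t      (regress through the origin,
  with C0 anchored to the first observation)

Times are supplied in minutes and converted to hours before regression so
rate constants come out in h^-1, the convention of the food-kinetics
literature.  R^2 is computed on the regressed (linearized) scale, which
is also the scale on which the model order is selected.

Temperature dependence of a rate constant follows the Arrhenius law
k = A*exp(-Ea/(R*T)); ln|k| is regressed on 1/T_K and Ea = -slope*R.
Using |k| admits rate constants of decreasing responses (e.g. L*), whose
magnitude grows with temperature like any other rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15

MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class KineticFitResult:
    """One response fitted to one reaction order."""

    order: int
    k: float                 # rate constant, h^-1
    C0_hat: float            # fitted (order 0/1) or anchored (order 2) initial value
    r_squared: float
    n_points: int
    response: str = ""

    def __post_init__(self):
        if self.order not in (0, 1, 2):
            raise ValidationError(f"order must be 0, 1 or 2, got {self.order}")
        if self.n_points < 3:
            raise ValidationError("a kinetic fit needs at least 3 points")
        if self.r_squared > 1 + 1e-12:
            raise ValidationError("r_squared cannot exceed 1")


@dataclass(frozen=True)
class ArrheniusResult:
    """Activation energy from rate constants at several temperatures."""

    Ea: float                # kJ/mol
    Ea_stderr: float         # kJ/mol; NaN with only 2 points
    lnA: float
    r_squared: float
    n_points: int
    gas_constant: float = GAS_CONSTANT


def _validate_series(times_min: Sequence[float], values: Sequence[float]):
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(values, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-D and equal length")
    if t.size < 3:
        raise ValidationError("fitting needs at least 3 points")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(c)):
        raise ValidationError("non-finite data")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    return t, c


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of y on x by ordinary least squares."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_order(times_min: Sequence[float], values: Sequence[float],
              order: int, response: str = "") -> KineticFitResult:
    """Fit one integrated rate law to a sampled response.

    Parameters
    ----------
    times_min : sequence of float
        Sampling times in minutes, strictly increasing.
    values : sequence of float
        Response values; strictly positive for order 1, nonzero for order 2.
    order : {0, 1, 2}
        Reaction order of the integrated rate law.
    """
    if order not in (0, 1, 2):
        raise ValidationError(f"order must be 0, 1 or 2, got {order}")
    t, c = _validate_series(times_min, values)
    t_h = t / MINUTES_PER_HOUR
    if order == 0:
        k, c0, r2 = _ols(t_h, c)
    elif order == 1:
        if np.any(c <= 0):
            raise ValidationError(
                "first-order fit requires strictly positive values "
                "(log transform)"
            )
        slope, intercept, r2 = _ols(t_h, np.log(c))
        k, c0 = slope, math.exp(intercept)
    else:
        if np.any(c == 0):
            raise ValidationError("second-order fit requires nonzero values")
        c0 = float(c[0])
        y = 1.0 / c - 1.0 / c0
        # regression through the origin, as the integrated form dictates
        k = float(np.sum(t_h * y) / np.sum(t_h * t_h))
        ym = y.mean()
        ss_tot = float(np.sum((y - ym) ** 2))
        ss_res = float(np.sum((y - k * t_h) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return KineticFitResult(order=order, k=float(k), C0_hat=float(c0),
                            r_squared=float(r2), n_points=int(t.size),
                            response=response)


def fit_all_orders(times_min: Sequence[float], values: Sequence[float],
                   response: str = "") -> list[KineticFitResult]:
    """Fit every applicable order; orders whose domain constraints fail
    (e.g. first order on nonpositive data) are silently skipped."""
    fits = []
    for order in (0, 1, 2):
        try:
            fits.append(fit_order(times_min, values, order, response))
        except ValidationError:
            continue
    return fits


def select_model(fits: Sequence[KineticFitResult]) -> KineticFitResult:
    """Best fit by R^2; exact ties go to the lowest order."""
    fits = list(fits)
    if not fits:
        raise ValidationError("select_model needs at least one fit")
    return max(fits, key=lambda f: (f.r_squared, -f.order))


def arrhenius_fit(rate_constants: Sequence[tuple[float, float]]) -> ArrheniusResult:
    """Activation energy from (k in h^-1, T in Celsius) pairs.

    Regresses ln|k| on 1/T_K.  All k must share a sign: magnitudes of
    same-direction rates are comparable, but mixing growth and decay
    constants in one Arrhenius line is meaningless.
    """
    pairs = list(rate_constants)
    if len(pairs) < 2:
        raise ValidationError("arrhenius_fit needs at least 2 (k, T) pairs")
    k = np.array([p[0] for p in pairs], dtype=float)
    T = np.array([p[1] for p in pairs], dtype=float)
    if np.any(~np.isfinite(k)) or np.any(~np.isfinite(T)):
        raise ValidationError("non-finite rate constants or temperatures")
    if np.any(k == 0):
        raise ValidationError("zero rate constant has no Arrhenius slope")
    if np.unique(np.sign(k)).size > 1:
        raise ValidationError("rate constants must share a sign")
    if np.unique(T).size != T.size:
        raise ValidationError("duplicate temperatures")
    x = 1.0 / (T + KELVIN_OFFSET)
    y = np.log(np.abs(k))
    slope, intercept, r2 = _ols(x, y)
    Ea = -slope * GAS_CONSTANT / 1000.0  # J/mol -> kJ/mol
    if len(pairs) > 2:
        res = stats.linregress(x, y)
        stderr = res.stderr * GAS_CONSTANT / 1000.0
    else:
        stderr = float("nan")
    return ArrheniusResult(Ea=float(Ea), Ea_stderr=float(stderr),
                           lnA=float(intercept), r_squared=float(r2),
                           n_points=len(pairs))


def rate_ratio(k_high: float, k_low: float) -> float:
    """|k_high| / |k_low| for same-sign rate constants."""
    if k_low == 0:
        raise ValidationError("zero denominator in rate ratio")
    if k_high * k_low < 0:
        raise ValidationError("rate constants must share a sign")
    return abs(k_high) / abs(k_low)
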