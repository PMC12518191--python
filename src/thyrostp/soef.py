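"""Sum-of-exponentials retention models for :sup:`131`\\ I thyroid biokinetics.

Two structural models are provided for the fraction of administered activity
retained in the thyroid at time ``t`` (hours) after oral administration:

``a4c`` (four adjustable parameters)
    .. math::

        a(t) = \\frac{\\lambda_1}{\\lambda_2+\\lambda_1-\\lambda_3}
               \\left(e^{-(\\lambda_3+\\lambda_{phys})t}
                     - e^{-(\\lambda_1+\\lambda_2+\\lambda_{phys})t}\\right)
               + a_1 e^{-(\\lambda_1+\\lambda_2+\\lambda_{phys})t}

``a3b`` (three adjustable parameters)
    the same expression with the blood-pool background amplitude
    :math:`a_1` structurally fixed to zero.

:math:`\\lambda_1` scales the thyroidal in-flow, :math:`\\lambda_2` adds to
the uptake-phase rate, :math:`\\lambda_3` is the biological washout rate, and
:math:`a_1` absorbs any residual blood-pool count rate left after the thigh
background subtraction.  All rates are in 1/h; :math:`\\lambda_{phys}` is the
physical decay constant of :sup:`131`\\ I.

The first term is evaluated through the numerically stable identity

.. math:: a(t) = \\lambda_1\\, t\\, e^{-(\\lambda_3+\\lambda_{phys})t}\\,
          \\varphi\\!\\left((\\lambda_1+\\lambda_2-\\lambda_3)\\,t\\right)
          + a_1 e^{-(\\lambda_1+\\lambda_2+\\lambda_{phys})t},
   \\qquad \\varphi(x) = \\frac{1-e^{-x}}{x},\\ \\varphi(0)=1,

which is continuous through the removable singularity
:math:`\\lambda_1+\\lambda_2 = \\lambda_3`.  The time-integrated activity
(TIA, units: fraction of administered activity × hours) has the closed form

.. math:: \\mathrm{TIA} =
   \\frac{\\lambda_1}{(\\lambda_3+\\lambda_{phys})
                     (\\lambda_1+\\lambda_2+\\lambda_{phys})}
   + \\frac{a_1}{\\lambda_1+\\lambda_2+\\lambda_{phys}},

again free of the singularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhysicalConstants",
    "SOEFParams",
    "LAMBDA_PHYS_PER_H",
    "evaluate_soef",
    "evaluate_soef_grad",
    "analytic_tia",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical decay data for :sup:`131`\\ I (half-life 8.022 d)."""

    half_life_days: float = 8.022

    @property
    def half_life_hours(self) -> float:
        return self.half_life_days * 24.0

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in 1/h."""
        return math.log(2.0) / self.half_life_hours


#: Physical decay constant of 131-I in 1/h (= ln 2 / 192.528 h).
LAMBDA_PHYS_PER_H: float = PhysicalConstants().lambda_phys

_MODEL_IDS = ("a4c", "a3b")


@dataclass(frozen=True)
class SOEFParams:
    """Parameters of a sum-of-exponentials retention function.

    Parameters
    ----------
    lambda1, lambda2, lambda3
        Non-negative biological uptake/clearance rates in 1/h.
    a1
        Non-negative blood-pool background amplitude (fraction of
        administered activity).  Must be 0 for model ``a3b``.
    model_id
        ``"a4c"`` or ``"a3b"``.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    a1: float = 0.0
    model_id: str = "a4c"
    lambda_phys: float = field(default=LAMBDA_PHYS_PER_H, repr=False)

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.a1) or self.a1 < 0.0:
            raise ValueError(f"a1 must be finite and >= 0, got {self.a1}")
        if self.model_id == "a3b" and self.a1 != 0.0:
            raise ValueError("a1 must be 0 for model a3b")
        if self.lambda_phys <= 0.0:
            raise ValueError("lambda_phys must be > 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the adjustable parameters of this model."""
        if self.model_id == "a3b":
            return ("lambda1", "lambda2", "lambda3")
        return ("lambda1", "lambda2", "lambda3", "a1")

    def as_array(self) -> np.ndarray:
        """Adjustable parameters as a 1-d array (model order)."""
        return np.array([getattr(self, n) for n in self.free_names])

    def with_values(self, values: np.ndarray) -> "SOEFParams":
        """Return a copy with the adjustable parameters replaced."""
        kw = dict(zip(self.free_names, (float(v) for v in values)))
        return replace(self, **kw)


def _pq(x: np.ndarray, e3: np.ndarray, es: np.ndarray):
    """Stable difference quotients of the two exponentials.

    ``P = e3 * phi(x) = (e3 - es) / x`` and
    ``Q = e3 * phi'(x) = (es * (1 + x) - e3) / x**2`` with
    ``phi(x) = (1 - e^{-x}) / x`` and ``es = e3 * e^{-x}``; both are
    computed from the bounded exponentials directly (no overflow for any
    sign of ``x``) with Taylor fills near the removable singularity.
    """
    x = np.asarray(x, dtype=float)
    P = np.empty_like(x)
    Q = np.empty_like(x)
    small_p = np.abs(x) < 1e-5
    small_q = np.abs(x) < 1e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(small_p, 0.0, (e3 - es) / np.where(small_p, 1.0, x))
        Q = np.where(
            small_q, 0.0, (es * (1.0 + x) - e3) / np.where(small_q, 1.0, x * x)
        )
    xs = x[small_p]
    P[small_p] = e3[small_p] * (1.0 - xs / 2.0 + xs * xs / 6.0)
    xq = x[small_q]
    Q[small_q] = e3[small_q] * (-0.5 + xq / 3.0 - xq * xq / 8.0)
    return P, Q


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    return t


def evaluate_soef(params: SOEFParams, t) -> np.ndarray | float:
    """Retention fraction at time(s) ``t`` (hours).

    Accepts a scalar or array of non-negative times and returns the same
    shape.  Continuous in the parameters, including across
    ``lambda1 + lambda2 == lambda3``.
    """
    t = _check_times(t)
    scalar = t.ndim == 0
    ta = np.atleast_1d(t)
    val = _eval_raw(
        ta,
        params.lambda1,
        params.lambda2,
        params.lambda3,
        params.a1,
        params.lambda_phys,
    )
    return float(val[0]) if scalar else val


def _eval_raw(t, l1, l2, l3, a1, lp):
    s = l1 + l2
    e3 = np.exp(-(l3 + lp) * t)
    es = np.exp(-(s + lp) * t)
    x = (s - l3) * t
    P, _ = _pq(x, e3, es)
    return l1 * t * P + a1 * es


def evaluate_soef_grad(params: SOEFParams, t) -> tuple[np.ndarray, np.ndarray]:
    """Retention and its gradient w.r.t. the adjustable parameters.

    Returns ``(f, J)`` with ``J`` of shape ``(len(t), n_free)``; the column
    order matches :attr:`SOEFParams.free_names`.
    """
    t = np.atleast_1d(_check_times(t))
    l1, l2, l3, a1 = params.lambda1, params.lambda2, params.lambda3, params.a1
    lp = params.lambda_phys
    s = l1 + l2
    e3 = np.exp(-(l3 + lp) * t)
    es = np.exp(-(s + lp) * t)
    x = (s - l3) * t
    P, Q = _pq(x, e3, es)
    f = l1 * t * P + a1 * es
    d_l1 = t * (P + l1 * t * Q) - a1 * t * es
    d_l2 = l1 * t * t * Q - a1 * t * es
    d_l3 = -l1 * t * t * (P + Q)
    cols = [d_l1, d_l2, d_l3]
    if params.model_id == "a4c":
        cols.append(es)
    return f, np.stack(cols, axis=-1)


def analytic_tia(params: SOEFParams) -> float:
    """Closed-form time-integrated activity :math:`\\int_0^\\infty a(t)\\,dt`.

    Units: (fraction of administered activity) × hours.
    """
    l1, l2, l3, a1 = params.lambda1, params.lambda2, params.lambda3, params.a1
    lp = params.lambda_phys
    s_lp = l1 + l2 + lp
    return l1 / ((l3 + lp) * s_lp) + a1 / s_lp
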