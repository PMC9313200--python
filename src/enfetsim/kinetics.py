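"""Closed-form kinetics of an irreversible n-th-order reaction A -> P.

The enzymatic membrane of an ENFET consumes the analyte A and releases
an ionic product P.  In the limiting regimes of the Michaelis-Menten or
Hill law the rate collapses to a power law

    v(t) = -d[A]/dt = d[P]/dt = k [A]^n,

which integrates in closed form for every real order n >= 0:

    [A](t) = (A0^(1-n) + (n-1) k t)^(1/(1-n))        (n != 1)
    [A](t) = A0 exp(-k t)                            (n == 1)

with [P](t) = A0 - [A](t).  The order-1 case is the removable
singularity of the general expression; orders below 1 exhaust the
analyte in finite time t_ex = A0^(1-n) / ((1-n) k), after which the
physical solution is pinned at [A] = 0, [P] = A0, v = 0.

Units are mol/L for concentrations and seconds for time at every public
boundary; the rate constant k carries (mol/L)^(1-n) s^-1 as dictated by
the order.  A numerical ODE integrator (`ode_oracle`) is provided as an
independent reference for the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ORDER_DEGENERACY_TOL",
    "KineticsSpec",
    "KineticsTrajectory",
    "IntegrationError",
    "analyte_concentration",
    "reaction_rate",
    "product_concentration",
    "time_to_fraction",
    "simulate",
    "ode_oracle",
]

#: |n - 1| below this switches to the exponential branch; the general
#: closed form divides by (1 - n) and loses precision near order one.
ORDER_DEGENERACY_TOL = 1e-9

ArrayLike = Union[float, np.ndarray]


class IntegrationError(RuntimeError):
    """Raised when the reference ODE solver fails to converge."""


@dataclass(frozen=True)
class KineticsSpec:
    """Parameters of a power-law reaction.

    Attributes
    ----------
    A0 : float
        Initial analyte concentration, mol/L.  Strictly positive.
    n : float
        Reaction order, any real >= 0 (non-integer orders arise from
        Hill cooperativity, where the exponent h plays the role of n).
    k : float
        Rate constant, (mol/L)^(1-n) s^-1.  Strictly positive.
    """

    A0: float
    n: float
    k: float

    def __post_init__(self) -> None:
        if not (self.A0 > 0 and math.isfinite(self.A0)):
            raise ValueError(f"A0 must be a positive finite concentration, got {self.A0}")
        if not (self.n >= 0 and math.isfinite(self.n)):
            raise ValueError(f"reaction order n must be >= 0, got {self.n}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"rate constant k must be positive, got {self.k}")

    @property
    def k_units(self) -> str:
        """Units of k implied by the order, e.g. ``'(mol/L)^-1 s^-1'`` for n=2."""
        p = 1.0 - self.n
        if abs(p) < ORDER_DEGENERACY_TOL:
            return "s^-1"
        return f"(mol/L)^{p:g} s^-1"

    @property
    def exhaustion_time(self) -> float:
        """Time at which the analyte is fully consumed; inf for n >= 1."""
        if self.n >= 1.0 - ORDER_DEGENERACY_TOL:
            return math.inf
        return self.A0 ** (1.0 - self.n) / ((1.0 - self.n) * self.k)


@dataclass(frozen=True)
class KineticsTrajectory:
    """Sampled time evolution of one reaction: t, [A](t), v(t), [P](t)."""

    t: np.ndarray
    A: np.ndarray
    v: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing with t[0] >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "A_mol_per_L": self.A,
                "v_mol_per_L_s": self.v,
                "P_mol_per_L": self.P,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trajectory at full double precision."""
        self.to_frame().to_csv(path, index=False)


def _validate_times(t: ArrayLike) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    return arr


def _maybe_scalar(arr: np.ndarray, template: ArrayLike) -> ArrayLike:
    return float(arr) if np.isscalar(template) or np.ndim(template) == 0 else arr


def analyte_concentration(spec: KineticsSpec, t: ArrayLike) -> ArrayLike:
    """[A](t) by the closed form for the spec's order, clamped to [0, A0].

    For orders below one the expression reaches zero at the exhaustion
    time and is held there afterwards (mass balance; the raw power-law
    expression turns negative or complex past that point).
    """
    tt = _validate_times(t)
    A0, n, k = spec.A0, spec.n, spec.k
    if abs(n - 1.0) < ORDER_DEGENERACY_TOL:
        A = A0 * np.exp(-k * tt)
    else:
        base = A0 ** (1.0 - n) + (n - 1.0) * k * tt
        # n < 1: base hits zero at exhaustion; exponent 1/(1-n) > 0 so 0**p = 0
        base = np.maximum(base, 0.0)
        A = np.power(base, 1.0 / (1.0 - n))
    A = np.clip(A, 0.0, A0)
    return _maybe_scalar(A, t)


def reaction_rate(spec: KineticsSpec, t: ArrayLike) -> ArrayLike:
    """v(t) = k [A](t)^n, identically zero once the analyte is exhausted."""
    A = np.asarray(analyte_concentration(spec, t), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(A > 0.0, spec.k * np.power(np.maximum(A, 0.0), spec.n), 0.0)
    return _maybe_scalar(v, t)


def product_concentration(spec: KineticsSpec, t: ArrayLike) -> ArrayLike:
    """[P](t) = A0 - [A](t), capped at A0."""
    A = np.asarray(analyte_concentration(spec, t), dtype=float)
    P = np.clip(spec.A0 - A, 0.0, spec.A0)
    return _maybe_scalar(P, t)


def time_to_fraction(spec: KineticsSpec, fraction: float) -> float:
    """Time at which the product reaches ``fraction`` of A0.

    Solved analytically by inverting the closed form:
    t = -ln(1-f)/k for order one, otherwise
    t = A0^(1-n) ((1-f)^(1-n) - 1) / ((n-1) k).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    A0, n, k = spec.A0, spec.n, spec.k
    if abs(n - 1.0) < ORDER_DEGENERACY_TOL:
        return -math.log1p(-fraction) / k
    rem = 1.0 - fraction
    return A0 ** (1.0 - n) * (rem ** (1.0 - n) - 1.0) / ((n - 1.0) * k)


def simulate(spec: KineticsSpec, t_grid: ArrayLike) -> KineticsTrajectory:
    """Evaluate the closed forms on a grid and bundle them as a trajectory."""
    t = np.asarray(_validate_times(t_grid), dtype=float)
    A = np.asarray(analyte_concentration(spec, t), dtype=float)
    v = np.asarray(reaction_rate(spec, t), dtype=float)
    P = np.asarray(product_concentration(spec, t), dtype=float)
    return KineticsTrajectory(t=t, A=A, v=v, P=P)


def ode_oracle(
    spec: KineticsSpec, t_grid: ArrayLike, rtol: float = 1e-11
) -> KineticsTrajectory:
    """Reference trajectory by direct numerical integration of d[A]/dt = -k [A]^n.

    Integrates from t = 0 with tight error control (default rtol 1e-11)
    and a terminal event at analyte exhaustion so that sub-first-order
    reactions stop cleanly at [A] = 0.  Intended as an independent check
    of the closed forms, not for production use.
    """
    t = np.asarray(_validate_times(t_grid), dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")

    def rhs(_t, y):
        a = max(y[0], 0.0)
        return (-spec.k * a**spec.n,)

    def exhausted(_t, y):
        return y[0]

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        (spec.A0,),
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=spec.A0 * 1e-15,
        events=exhausted,
        dense_output=False,
    )
    if sol.status < 0:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    A = np.zeros_like(t)
    m = sol.y.shape[1]
    A[:m] = np.clip(sol.y[0], 0.0, spec.A0)  # points beyond the event stay at 0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(A > 0.0, spec.k * np.power(np.maximum(A, 0.0), spec.n), 0.0)
    P = np.clip(spec.A0 - A, 0.0, spec.A0)
    return KineticsTrajectory(t=t, A=A, v=v, P=P)
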