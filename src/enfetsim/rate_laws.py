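"""Michaelis-Menten and Hill rate laws and parameter extraction.

The enzymatic rate surface is

    v = v_max [A] / (K_M + [A])                (Michaelis-Menten)
    v = v_max [A]^h / (K_M^h + [A]^h)          (Hill)

with K_M the half-saturation concentration (v = v_max/2 at [A] = K_M)
and h the cooperativity exponent (h > 1 positive, 0 < h < 1 negative
cooperativity; h = 1 recovers Michaelis-Menten exactly).

In the saturation limit [A] >> K_M the rate is constant (effective
zero-order constant k = v_max); in the dilute limit [A] << K_M it is
linear (first-order k = v_max / K_M) or, for Hill kinetics, an h-order
power law with k = v_max / K_M^h.  These reductions feed the power-law
kinetics module.

Parameter extraction is offered through scikit-learn style estimators
(`LineweaverBurkRegressor`, `HillRegressor`, `InitialRateOrderEstimator`)
plus thin functional wrappers matching the classic workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RateLawParams",
    "EnzymeLoading",
    "RateDataset",
    "ProgressCurve",
    "FitError",
    "mm_rate",
    "hill_rate",
    "limiting_rate_constant",
    "k2_from_loading",
    "LineweaverBurkRegressor",
    "HillRegressor",
    "InitialRateOrderEstimator",
    "fit_lineweaver_burk",
    "fit_mm_nonlinear",
    "fit_hill",
    "estimate_order_initial_rates",
]

Regime = Literal["zero_order", "first_order", "h_order"]


class FitError(RuntimeError):
    """A parameter fit failed or the data contradict the model."""


@dataclass(frozen=True)
class RateLawParams:
    """Rate-surface parameters: v_max mol/(L s), K_M mol/L, Hill h."""

    v_max: float
    K_M: float
    h: float = 1.0
    model_tag: Literal["michaelis_menten", "hill"] = "michaelis_menten"

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if self.K_M <= 0:
            raise ValueError(f"K_M must be positive, got {self.K_M}")
        if self.h <= 0:
            raise ValueError(f"Hill coefficient h must be positive, got {self.h}")
        if self.model_tag == "michaelis_menten" and self.h != 1.0:
            raise ValueError("michaelis_menten model requires h = 1")
        if self.model_tag not in ("michaelis_menten", "hill"):
            raise ValueError(f"unknown model_tag {self.model_tag!r}")


@dataclass(frozen=True)
class EnzymeLoading:
    """Molar concentration of immobilised enzyme, mol/L."""

    E: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"enzyme loading must be positive, got {self.E}")


@dataclass(frozen=True)
class RateDataset:
    """Initial-rate measurements: (analyte concentration, rate) pairs."""

    A: np.ndarray
    v: np.ndarray
    noise_meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if A.shape != v.shape or A.ndim != 1:
            raise ValueError("A and v must be 1-D arrays of equal length")
        if np.any(A <= 0) or np.any(v <= 0):
            raise ValueError("all concentrations and rates must be positive")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return self.A.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"A_mol_per_L": self.A, "v_mol_per_L_s": self.v})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(A=df["A_mol_per_L"].to_numpy(), v=df["v_mol_per_L_s"].to_numpy())


@dataclass(frozen=True)
class ProgressCurve:
    """One product-vs-time table at a known initial analyte concentration."""

    t: np.ndarray
    P: np.ndarray
    A0: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if t.shape != P.shape or t.ndim != 1:
            raise ValueError("t and P must be 1-D arrays of equal length")
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "P", P)


def _validate_conc(A) -> np.ndarray:
    arr = np.asarray(A, dtype=float)
    if np.any(arr < 0):
        raise ValueError("analyte concentration must be non-negative")
    return arr


def mm_rate(params: RateLawParams, A):
    """Michaelis-Menten rate v_max A / (K_M + A)."""
    if params.model_tag != "michaelis_menten":
        raise ValueError("mm_rate requires michaelis_menten parameters")
    arr = _validate_conc(A)
    out = params.v_max * arr / (params.K_M + arr)
    return float(out) if np.ndim(A) == 0 else out


def hill_rate(params: RateLawParams, A):
    """Hill rate v_max A^h / (K_M^h + A^h); equals mm_rate at h = 1."""
    arr = _validate_conc(A)
    ah = np.power(arr, params.h)
    out = params.v_max * ah / (params.K_M**params.h + ah)
    return float(out) if np.ndim(A) == 0 else out


def limiting_rate_constant(params: RateLawParams, regime: Regime) -> tuple[float, float]:
    """Effective power-law (k, n) in a limiting regime of the rate surface.

    zero_order  (A >> K_M): k = v_max,          n = 0
    first_order (A << K_M): k = v_max / K_M,    n = 1
    h_order     (A << K_M, Hill): k = v_max / K_M^h, n = h
    """
    if regime == "zero_order":
        return params.v_max, 0.0
    if regime == "first_order":
        return params.v_max / params.K_M, 1.0
    if regime == "h_order":
        if params.model_tag != "hill":
            raise ValueError("h_order regime requires a hill rate law")
        return params.v_max / params.K_M**params.h, params.h
    raise ValueError(f"unknown regime {regime!r}")


def k2_from_loading(v_max: float, loading: EnzymeLoading) -> float:
    """Turnover number k2 = v_max / E, s^-1."""
    if v_max <= 0:
        raise ValueError(f"v_max must be positive, got {v_max}")
    return v_max / loading.E


def _as_conc_column(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("X must be a 1-D array or single-column matrix of concentrations")
    return arr


class LineweaverBurkRegressor(RegressorMixin, BaseEstimator):
    """Michaelis-Menten extraction by the double-reciprocal (Lineweaver-Burk) line.

    Ordinary least squares of 1/v on 1/[A]; the intercept b gives
    v_max = 1/b and the slope m gives K_M = m/b.  Unweighted, as the
    classic graphical construction draws a plain straight line.

    Attributes (after fit)
    ----------------------
    v_max_, K_M_ : float
        Extracted parameters.
    params_ : RateLawParams
        The same parameters bundled with model_tag ``michaelis_menten``.
    r_squared_ : float
        Coefficient of determination of the reciprocal-space line.
    residuals_ : ndarray
        Reciprocal-space residuals, one per observation.
    """

    def fit(self, X, y):
        A = _as_conc_column(X)
        v = np.asarray(y, dtype=float)
        if A.size != v.size:
            raise ValueError("X and y must have the same length")
        if A.size < 3:
            raise FitError("Lineweaver-Burk fit needs at least 3 points")
        if np.any(A <= 0) or np.any(v <= 0):
            raise ValueError("concentrations and rates must be positive")
        x = 1.0 / A
        yy = 1.0 / v
        slope, intercept = np.polyfit(x, yy, 1)
        if intercept <= 0:
            raise FitError(
                "non-positive Lineweaver-Burk intercept: data are inconsistent "
                "with a Michaelis-Menten law"
            )
        self.v_max_ = 1.0 / intercept
        self.K_M_ = slope / intercept
        if self.K_M_ <= 0:
            raise FitError("non-positive fitted K_M: data inconsistent with MM law")
        fitted = intercept + slope * x
        self.residuals_ = yy - fitted
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        ss_res = float(np.sum(self.residuals_**2))
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        self.params_ = RateLawParams(self.v_max_, self.K_M_, 1.0, "michaelis_menten")
        return self

    def predict(self, X):
        return mm_rate(self.params_, _as_conc_column(X))


class HillRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the Hill rate law.

    Deterministic multi-start Levenberg-Marquardt over a fixed grid of
    Hill exponents (default 0.3, 1, 2, 4); the start with the smallest
    residual norm wins.  No random initialisation.
    """

    def __init__(self, h_starts: Sequence[float] = (0.3, 1.0, 2.0, 4.0)):
        self.h_starts = h_starts

    def fit(self, X, y):
        A = _as_conc_column(X)
        v = np.asarray(y, dtype=float)
        if A.size != v.size:
            raise ValueError("X and y must have the same length")
        if A.size < 4:
            raise FitError("Hill fit needs at least 4 points")
        if np.any(A <= 0) or np.any(v <= 0):
            raise ValueError("concentrations and rates must be positive")

        def model(a, v_max, k_m, h):
            ah = np.power(a, h)
            return v_max * ah / (k_m**h + ah)

        best = None
        for h0 in self.h_starts:
            p0 = (float(v.max()) * 1.2, float(np.median(A)), float(h0))
            try:
                popt, _ = curve_fit(
                    model,
                    A,
                    v,
                    p0=p0,
                    bounds=([1e-300, 1e-300, 1e-6], [np.inf, np.inf, 1e3]),
                    maxfev=20000,
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
            except RuntimeError:
                continue
            ssr = float(np.sum((model(A, *popt) - v) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
        if best is None:
            raise FitError("Hill fit did not converge from any start")
        ssr, (v_max, k_m, h) = best
        self.v_max_, self.K_M_, self.h_ = float(v_max), float(k_m), float(h)
        self.residual_norm_ = math.sqrt(ssr)
        self.params_ = RateLawParams(self.v_max_, self.K_M_, self.h_, "hill")
        return self

    def predict(self, X):
        return hill_rate(self.params_, _as_conc_column(X))


class InitialRateOrderEstimator(BaseEstimator):
    """Reaction order and rate constant by the initial-rate method.

    For each progress curve (product vs time at a fixed starting analyte
    concentration A0) the initial rate v0 is the slope at t = 0 of a
    quadratic fitted to the first max(4, 20%) points — a second-order
    local model that tolerates early curvature without chasing it.
    The order n and constant k then come from ordinary least squares of
    log v0 on log A0 (slope = n, intercept = log k).
    """

    early_fraction: float = 0.2
    min_points: int = 4

    def fit(self, curves: Sequence[ProgressCurve]):
        curves = list(curves)
        if len(curves) < 2:
            raise ValueError("need at least 2 progress curves at distinct A0")
        a0s = np.array([c.A0 for c in curves])
        if np.unique(a0s).size < 2:
            raise ValueError("progress curves must span at least 2 distinct A0 values")
        v0s = np.array([self._initial_rate(c) for c in curves])
        if np.any(v0s <= 0):
            raise FitError("estimated a non-positive initial rate; check early-time data")
        res = stats.linregress(np.log(a0s), np.log(v0s))
        self.n_ = float(res.slope)
        self.k_ = float(math.exp(res.intercept))
        self.n_stderr_ = float(res.stderr) if res.stderr is not None else math.nan
        se_int = res.intercept_stderr if res.intercept_stderr is not None else math.nan
        self.k_stderr_ = self.k_ * float(se_int)  # delta method on exp(intercept)
        self.v0_ = v0s
        return self

    def _initial_rate(self, curve: ProgressCurve) -> float:
        n_pts = curve.t.size
        if n_pts < 4:
            raise ValueError("each progress curve needs at least 4 early-time points")
        m = max(self.min_points, math.ceil(self.early_fraction * n_pts))
        m = min(m, n_pts)
        coeffs = np.polyfit(curve.t[:m], curve.P[:m], 2)
        return float(coeffs[1])  # d[P]/dt at t = 0


# ---------------------------------------------------------------------------
# Functional wrappers (the estimator classes do the work)


def fit_lineweaver_burk(data: RateDataset) -> RateLawParams:
    """Extract (v_max, K_M) from initial-rate data via the reciprocal line."""
    return LineweaverBurkRegressor().fit(data.A, data.v).params_


def fit_mm_nonlinear(data: RateDataset) -> RateLawParams:
    """Direct nonlinear MM fit; cross-check for the reciprocal-line extraction."""
    def model(a, v_max, k_m):
        return v_max * a / (k_m + a)

    popt, _ = curve_fit(
        model,
        data.A,
        data.v,
        p0=(float(data.v.max()) * 1.2, float(np.median(data.A))),
        bounds=([1e-300, 1e-300], [np.inf, np.inf]),
        maxfev=20000,
        xtol=1e-15,
        ftol=1e-15,
    )
    return RateLawParams(float(popt[0]), float(popt[1]), 1.0, "michaelis_menten")


def fit_hill(data: RateDataset) -> RateLawParams:
    """Extract (v_max, K_M, h) by deterministic multi-start nonlinear least squares."""
    return HillRegressor().fit(data.A, data.v).params_


def estimate_order_initial_rates(
    curves: Iterable[ProgressCurve],
) -> tuple[float, float]:
    """(order n, rate constant k) from progress curves at several A0."""
    est = InitialRateOrderEstimator().fit(list(curves))
    return est.n_, est.k_
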