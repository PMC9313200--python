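"""End-to-end ENFET pipeline and the transistor design procedure.

An ENFET is two blocks in series: the enzymatic membrane converts an
analyte concentration A0 into an ionic product concentration [P] after
a measurement time t_meas (power-law kinetics, possibly obtained as a
limiting regime of a Michaelis-Menten/Hill law), and the FET transducer
converts [P] into a drain current.

The design procedure maps a target analyte range plus kinetics
constants onto a transistor operating point:

1.  pick the effective reaction order from the position of the analyte
    range relative to K_M (A >> K_M: zero order, k = v_max;
    A << K_M: first order, k = v_max/K_M; Hill: h-order,
    k = v_max/K_M^h),
2.  propagate both range ends through the kinetics block to get the
    product range at t_meas,
3.  evaluate the gate capacitance, aspect factor, Nernst potential,
    threshold shift and drain current at both ends, and
4.  if a target aspect factor is requested, back-solve the geometry
    W/L = K / (mu_c C_tot).

"Much larger/smaller than K_M" is operationalised as a ratio of 10
(``regime_ratio``); ranges that straddle K_M require an explicit regime
override rather than a silent guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import fet
from .kinetics import KineticsSpec, product_concentration, time_to_fraction
from .rate_laws import RateLawParams, limiting_rate_constant

__all__ = [
    "AmbiguousRegimeError",
    "EnfetSystem",
    "TransferCurve",
    "DesignReport",
    "enfet_response",
    "transfer_curve",
    "design_enfet",
]

DesignRegime = Literal["auto", "zero_order", "first_order", "h_order"]

TRANSFER_COLUMNS = (
    "A0_mol_per_L",
    "P_mol_per_L",
    "V_N_V",
    "dVT_V",
    "V_GS_V",
    "V_T_V",
    "I_D_A",
    "in_regime",
)


class AmbiguousRegimeError(ValueError):
    """The analyte range straddles K_M; no limiting regime applies cleanly."""


@dataclass(frozen=True)
class EnfetSystem:
    """Enzyme block + FET block + measurement time.

    ``kinetics`` carries the order and rate constant; its A0 is treated
    as a template and replaced per evaluated analyte concentration.
    """

    kinetics: KineticsSpec
    device: fet.Device
    t_meas: float

    def __post_init__(self) -> None:
        if self.t_meas <= 0:
            raise ValueError(f"measurement time must be positive, got {self.t_meas}")


@dataclass(frozen=True)
class TransferCurve:
    """Analyte-to-current table; out-of-regime rows are flagged, not dropped."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRANSFER_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"transfer table missing columns: {missing}")
        a0 = self.table["A0_mol_per_L"].to_numpy()
        if np.any(np.diff(a0) <= 0):
            raise ValueError("transfer table must be sorted by ascending A0")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class DesignReport:
    """Outcome of the design procedure at both ends of the analyte range."""

    C_tot: float          # F/cm^2
    K: float              # A/V^2
    W_over_L: float
    V_ext: float          # V
    regime: str
    k_eff: float          # effective power-law rate constant
    n_eff: float          # effective reaction order
    t_meas: float         # s
    A0_range: tuple[float, float]
    P_range: tuple[float, float]
    I_D_range: tuple[Optional[float], Optional[float]]  # None where out of regime
    in_regime: tuple[bool, bool]


def enfet_response(sys: EnfetSystem, A0: float) -> tuple[float, float]:
    """(product concentration, drain current) for one analyte concentration.

    P comes from the closed-form kinetics at t_meas; the current from
    the FET transduction chain at that P.  Out-of-regime bias raises.
    """
    if A0 <= 0:
        raise ValueError(f"A0 must be positive, got {A0}")
    spec = replace(sys.kinetics, A0=A0)
    P = float(product_concentration(spec, sys.t_meas))
    point = sys.device.transduce(P)
    return P, point.I_D


def transfer_curve(sys: EnfetSystem, A0_grid: Sequence[float]) -> TransferCurve:
    """One transduction row per grid concentration, sorted ascending.

    Rows where the bias leaves saturation are kept with ``in_regime``
    False and NaN current, so the caller sees where the design fails.
    """
    grid = np.asarray(A0_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("A0 grid must not be empty")
    if np.any(grid <= 0):
        raise ValueError("A0 grid values must be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("A0 grid must be strictly increasing")

    rows = []
    for a0 in grid:
        spec = replace(sys.kinetics, A0=float(a0))
        P = float(product_concentration(spec, sys.t_meas))
        try:
            pt = sys.device.transduce(P)
            rows.append((a0, P, pt.V_N, pt.dVT, pt.V_GS, pt.V_T, pt.I_D, True))
        except fet.OperatingRegimeError:
            v_n = fet.nernst_potential(sys.device.electrochem, P)
            dvt = fet.threshold_shift(sys.device.helmholtz, P)
            v_gs = fet.gate_source_voltage(sys.device.bias, v_n)
            v_t = fet.threshold_voltage(sys.device.transistor.V_T_FET, dvt)
            rows.append((a0, P, v_n, dvt, v_gs, v_t, math.nan, False))
    return TransferCurve(pd.DataFrame(rows, columns=TRANSFER_COLUMNS))


def _select_regime(
    lo: float, hi: float, params: RateLawParams, regime: DesignRegime, ratio: float
) -> str:
    if regime != "auto":
        return regime
    if lo / params.K_M >= ratio:
        return "zero_order"
    if hi / params.K_M <= 1.0 / ratio:
        return "h_order" if params.model_tag == "hill" and params.h != 1.0 else "first_order"
    raise AmbiguousRegimeError(
        f"analyte range [{lo:g}, {hi:g}] mol/L straddles K_M = {params.K_M:g} mol/L "
        f"(regime ratio {ratio:g}); pass regime='zero_order'/'first_order'/'h_order' explicitly"
    )


def design_enfet(
    analyte_range: tuple[float, float],
    params: RateLawParams,
    device: fet.Device,
    t_meas: Optional[float] = None,
    target_K: Optional[float] = None,
    regime: DesignRegime = "auto",
    regime_ratio: float = 10.0,
) -> DesignReport:
    """Map an analyte range and rate-law constants to an operating point.

    Parameters
    ----------
    analyte_range : (min, max) in mol/L
        The concentrations the sensor must resolve.  min == max gives a
        single-point report.
    params : RateLawParams
        Michaelis-Menten or Hill constants from kinetics studies.
    device : Device
        Geometry/electrochemistry template.  If ``target_K`` is given,
        the channel W/L is back-solved as K/(mu_c C_tot) and replaces
        the template's geometry in all reported currents.
    t_meas : float, optional
        Measurement time, s.  Defaults to the 99%-conversion time of the
        slowest point of the range, so the reported product essentially
        equals the analyte concentration.
    target_K : float, optional
        Desired aspect factor, A/V².
    regime, regime_ratio
        Limiting-regime selection; see module docstring.
    """
    lo, hi = analyte_range
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError(f"invalid analyte range ({lo}, {hi}): need 0 < min <= max")

    chosen = _select_regime(lo, hi, params, regime, regime_ratio)
    k_eff, n_eff = limiting_rate_constant(params, chosen)

    if t_meas is None:
        t_meas = max(
            time_to_fraction(KineticsSpec(A0=a, n=n_eff, k=k_eff), 0.99) for a in (lo, hi)
        )

    C_tot = fet.total_capacitance(device.gate_stack)
    if target_K is not None:
        if target_K <= 0:
            raise ValueError("target aspect factor must be positive")
        W_over_L = target_K / (device.transistor.mu_c * C_tot)
        tr = replace(device.transistor, W=W_over_L * device.transistor.L)
        device = replace(device, transistor=tr)
        K = target_K
    else:
        W_over_L = device.transistor.W / device.transistor.L
        K = fet.aspect_factor(device.transistor, C_tot)

    sys = EnfetSystem(
        kinetics=KineticsSpec(A0=lo, n=n_eff, k=k_eff), device=device, t_meas=t_meas
    )
    ends: list[Optional[float]] = []
    flags: list[bool] = []
    products: list[float] = []
    for a in (lo, hi):
        spec = KineticsSpec(A0=a, n=n_eff, k=k_eff)
        P = float(product_concentration(spec, t_meas))
        products.append(P)
        try:
            pt = sys.device.transduce(P)
            ends.append(pt.I_D)
            flags.append(True)
        except fet.OperatingRegimeError:
            ends.append(None)
            flags.append(False)

    return DesignReport(
        C_tot=C_tot,
        K=K,
        W_over_L=W_over_L,
        V_ext=device.bias.V_ext,
        regime=chosen,
        k_eff=k_eff,
        n_eff=n_eff,
        t_meas=t_meas,
        A0_range=(lo, hi),
        P_range=(products[0], products[1]),
        I_D_range=(ends[0], ends[1]),
        in_regime=(flags[0], flags[1]),
    )
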