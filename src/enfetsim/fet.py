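"""FET transduction chain of an ENFET biosensor.

Ionic reaction products accumulating in the Helmholtz layer over the
gate insulator shift the transistor threshold; the gate electrode in
contact with the solution contributes a Nernst potential.  In strong
inversion the drain current follows the square law:

    C_tot^-1 = sum_i t_i / eps_i            (series gate insulators)
    K        = (W/L) mu_c C_tot             (aspect factor)
    V_N      = V0 + (V_th / z) ln(p/c_ref)  (Nernst gate potential)
    Q_c      = z_q e [P] N_A t_H            (Helmholtz surface charge)
    C_H      = eps_H / t_H
    dV_T     = Q_c / C_H = z_q e [P] N_A t_H^2 / eps_H
    V_GS     = V_ext + V_N
    V_T      = V_T,FET + dV_T
    I_D      = K/2 (V_GS - V_T)^2           (valid only for V_GS > V_T)

Two independent signed valences are exposed: ``z_nernst`` enters the
logarithmic electrode potential while ``z_q`` sets the per-ion charge of
the adsorbed product.  They describe different physics (electrode redox
couple vs accumulated ion charge) and need not coincide; the worked Ag /
O^- glucose-sensor numbers in fact require z_nernst = -2 with a 1 mM
log normalisation but a single elementary charge in the threshold
shift.  The Nernst logarithm is normalised by an explicit reference
concentration ``c_ref`` to keep it dimensionless.

Electrostatics is cm-based (F/cm, F/cm², C/cm²); concentrations are
mol/L at the API and converted to mol/cm³ internally.  Only the
saturation regime is modelled: a bias that leaves the channel out of
strong inversion raises :class:`OperatingRegimeError` rather than
extrapolating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .constants import CODATA, PER_LITRE_TO_PER_CM3

__all__ = [
    "OperatingRegimeError",
    "InsulatorLayer",
    "GateStack",
    "TransistorParams",
    "ElectroChem",
    "HelmholtzModel",
    "BiasPoint",
    "Device",
    "TransductionPoint",
    "total_capacitance",
    "aspect_factor",
    "nernst_potential",
    "surface_charge",
    "helmholtz_capacitance",
    "threshold_shift",
    "gate_source_voltage",
    "threshold_voltage",
    "drain_current",
    "transduction_current",
    "transfer_points_frame",
]


class OperatingRegimeError(ValueError):
    """The transistor left the saturation (strong-inversion) regime."""


@dataclass(frozen=True)
class InsulatorLayer:
    """One gate insulator: thickness in cm, relative permittivity."""

    thickness: float
    rel_permittivity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer thickness must be positive, got {self.thickness}")
        if self.rel_permittivity <= 0:
            raise ValueError(
                f"relative permittivity must be positive, got {self.rel_permittivity}"
            )


@dataclass(frozen=True)
class GateStack:
    """Ordered series of gate insulators, enzymatic/aqueous layer included."""

    layers: tuple[InsulatorLayer, ...]

    def __init__(self, layers: Sequence[InsulatorLayer]):
        layers = tuple(layers)
        if not layers:
            raise ValueError("gate stack needs at least one insulator layer")
        object.__setattr__(self, "layers", layers)


@dataclass(frozen=True)
class TransistorParams:
    """Channel geometry (cm), mobility (cm²/Vs) and intrinsic threshold (V)."""

    W: float
    L: float
    mu_c: float
    V_T_FET: float

    def __post_init__(self) -> None:
        for name in ("W", "L", "mu_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class ElectroChem:
    """Electrode parameters of the Nernst gate potential.

    thermal_voltage defaults to RT/F = 0.025 V at room temperature;
    c_ref (default 1 mmol/L) normalises the concentration inside the
    logarithm.
    """

    V0: float
    z_nernst: int
    thermal_voltage: float = 0.025
    c_ref: float = 1e-3

    def __post_init__(self) -> None:
        if self.z_nernst == 0:
            raise ValueError("Nernst valence must be a nonzero signed integer")
        if self.thermal_voltage <= 0:
            raise ValueError("thermal voltage must be positive")
        if self.c_ref <= 0:
            raise ValueError("reference concentration must be positive")


@dataclass(frozen=True)
class HelmholtzModel:
    """Rigid ion layer: thickness t_H (cm), per-ion charge number z_q,
    layer permittivity eps_H (F/cm, default vacuum)."""

    t_H: float = 1e-5  # 100 nm, appropriate for micromolar ion ranges
    z_q: int = -1
    eps_H: float = CODATA.eps0

    def __post_init__(self) -> None:
        if self.t_H <= 0:
            raise ValueError("Helmholtz thickness must be positive")
        if self.z_q == 0:
            raise ValueError("ion charge number must be a nonzero signed integer")
        if self.eps_H <= 0:
            raise ValueError("Helmholtz permittivity must be positive")


@dataclass(frozen=True)
class BiasPoint:
    """Externally applied gate bias, V."""

    V_ext: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.V_ext):
            raise ValueError("V_ext must be finite")


@dataclass(frozen=True)
class Device:
    """Full parameter bundle of the FET half of an ENFET."""

    transistor: TransistorParams
    gate_stack: GateStack
    electrochem: ElectroChem
    helmholtz: HelmholtzModel
    bias: BiasPoint

    def transduce(self, P: float) -> "TransductionPoint":
        return transduction_current(
            self.transistor, self.gate_stack, self.electrochem, self.helmholtz, self.bias, P
        )


@dataclass(frozen=True)
class TransductionPoint:
    """Drain current at one product concentration, with every intermediate."""

    P: float
    C_tot: float
    K: float
    V_N: float
    dVT: float
    V_GS: float
    V_T: float
    I_D: float


def total_capacitance(stack: GateStack) -> float:
    """Series specific capacitance of the gate stack, F/cm²."""
    return 1.0 / sum(
        layer.thickness / (layer.rel_permittivity * CODATA.eps0) for layer in stack.layers
    )


def aspect_factor(tr: TransistorParams, C_tot: float) -> float:
    """Square-law prefactor K = (W/L) mu_c C_tot, A/V²."""
    if C_tot <= 0:
        raise ValueError(f"C_tot must be positive, got {C_tot}")
    return (tr.W / tr.L) * tr.mu_c * C_tot


def nernst_potential(ec: ElectroChem, p: float) -> float:
    """Electrode potential V_N = V0 + (V_th/z) ln(p / c_ref), V."""
    if p <= 0:
        raise ValueError(f"ion concentration must be positive, got {p}")
    return ec.V0 + (ec.thermal_voltage / ec.z_nernst) * math.log(p / ec.c_ref)


def surface_charge(hm: HelmholtzModel, P: float) -> float:
    """Signed areal charge Q_c = z_q e [P] N_A t_H, C/cm².

    [P] enters in mol/cm³; the ions within one Helmholtz thickness of
    the electrode are counted as a sheet charge.
    """
    if P < 0:
        raise ValueError(f"product concentration must be non-negative, got {P}")
    return hm.z_q * CODATA.e * (P * PER_LITRE_TO_PER_CM3) * CODATA.N_A * hm.t_H


def helmholtz_capacitance(hm: HelmholtzModel) -> float:
    """Specific capacitance C_H = eps_H / t_H, F/cm²."""
    return hm.eps_H / hm.t_H


def threshold_shift(hm: HelmholtzModel, P: float) -> float:
    """Signed threshold shift dV_T = Q_c / C_H = z_q e [P] N_A t_H² / eps_H, V."""
    if P < 0:
        raise ValueError(f"product concentration must be non-negative, got {P}")
    return (
        hm.z_q
        * CODATA.e
        * (P * PER_LITRE_TO_PER_CM3)
        * CODATA.N_A
        * hm.t_H**2
        / hm.eps_H
    )


def gate_source_voltage(bias: BiasPoint, V_N: float) -> float:
    """V_GS = V_ext + V_N."""
    return bias.V_ext + V_N


def threshold_voltage(V_T_FET: float, dVT: float) -> float:
    """V_T = V_T,FET + dV_T (the shift keeps its sign; anions lower V_T)."""
    return V_T_FET + dVT


def drain_current(K: float, V_GS: float, V_T: float) -> float:
    """Saturation drain current I_D = K/2 (V_GS - V_T)², A.

    Raises :class:`OperatingRegimeError` unless V_GS > V_T (strong
    inversion); the square law has no validity outside it.
    """
    overdrive = V_GS - V_T
    if overdrive <= 0:
        raise OperatingRegimeError(
            f"out of saturation regime: V_GS - V_T = {overdrive:.6g} V <= 0 "
            f"(V_GS = {V_GS:.6g} V, V_T = {V_T:.6g} V); increase V_ext"
        )
    return 0.5 * K * overdrive**2


def transduction_current(
    tr: TransistorParams,
    stack: GateStack,
    ec: ElectroChem,
    hm: HelmholtzModel,
    bias: BiasPoint,
    P: float,
) -> TransductionPoint:
    """Full product-concentration -> drain-current chain.

    Every returned intermediate equals the corresponding standalone
    operation evaluated on the same inputs (same floating-point path).
    """
    if P <= 0:
        raise ValueError(f"product concentration must be positive, got {P}")
    C_tot = total_capacitance(stack)
    K = aspect_factor(tr, C_tot)
    V_N = nernst_potential(ec, P)
    dVT = threshold_shift(hm, P)
    V_GS = gate_source_voltage(bias, V_N)
    V_T = threshold_voltage(tr.V_T_FET, dVT)
    try:
        I_D = drain_current(K, V_GS, V_T)
    except OperatingRegimeError as exc:
        raise OperatingRegimeError(f"at [P] = {P:.6g} mol/L: {exc}") from None
    return TransductionPoint(P=P, C_tot=C_tot, K=K, V_N=V_N, dVT=dVT, V_GS=V_GS, V_T=V_T, I_D=I_D)


def transfer_points_frame(points: Sequence[TransductionPoint]) -> pd.DataFrame:
    """Tabulate transduction points with the standard CSV column names."""
    return pd.DataFrame(
        {
            "P_mol_per_L": [pt.P for pt in points],
            "V_N_V": [pt.V_N for pt in points],
            "dVT_V": [pt.dVT for pt in points],
            "V_GS_V": [pt.V_GS for pt in points],
            "V_T_V": [pt.V_T for pt in points],
            "I_D_A": [pt.I_D for pt in points],
        }
    )
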