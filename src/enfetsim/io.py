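"""Config and table I/O.

Device configs are JSON with sections ``transistor``, ``gate_stack``,
``electrochem``, ``helmholtz``, ``bias``.  File units follow bench
conventions — lengths in nm, concentrations in mol/L, voltages in V —
and are converted to the internal cm-based system exactly once at load
time; dumping converts back, so load(dump(x)) == x.

Schema violations raise :class:`ConfigError` naming the offending field
and constraint.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .constants import NM_TO_CM, CODATA
from .design import DesignReport
from .fet import (
    BiasPoint,
    Device,
    ElectroChem,
    GateStack,
    HelmholtzModel,
    InsulatorLayer,
    TransistorParams,
)
from .kinetics import KineticsSpec
from .rate_laws import ProgressCurve, RateDataset

__all__ = [
    "ConfigError",
    "load_device_config",
    "device_config_dict",
    "dump_device_config",
    "load_kinetics_config",
    "write_design_report",
    "read_design_report",
    "read_progress_curve",
    "write_progress_curve",
    "read_rate_dataset",
]

PathLike = Union[str, Path]


class ConfigError(ValueError):
    """A config document violates the schema or a physical invariant."""


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigError(f"{where}: missing required field '{key}'")
    return section[key]


def _load_json(source: Union[PathLike, dict]) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return json.load(fh)


def load_device_config(source: Union[PathLike, dict]) -> Device:
    """Parse and validate a device JSON document (path or dict)."""
    doc = _load_json(source)
    for section in ("transistor", "gate_stack", "electrochem", "helmholtz", "bias"):
        if section not in doc:
            raise ConfigError(f"device config: missing section '{section}'")

    tr_doc = doc["transistor"]
    try:
        transistor = TransistorParams(
            W=_require(tr_doc, "W_nm", "transistor") * NM_TO_CM,
            L=_require(tr_doc, "L_nm", "transistor") * NM_TO_CM,
            mu_c=_require(tr_doc, "mu_c_cm2_per_Vs", "transistor"),
            V_T_FET=_require(tr_doc, "V_T_FET_V", "transistor"),
        )
        layers = []
        if not doc["gate_stack"]:
            raise ConfigError("gate_stack: must list at least one layer")
        for i, layer in enumerate(doc["gate_stack"]):
            layers.append(
                InsulatorLayer(
                    thickness=_require(layer, "thickness_nm", f"gate_stack[{i}]") * NM_TO_CM,
                    rel_permittivity=_require(layer, "rel_permittivity", f"gate_stack[{i}]"),
                    label=layer.get("label", ""),
                )
            )
        ec_doc = doc["electrochem"]
        electrochem = ElectroChem(
            V0=_require(ec_doc, "V0_V", "electrochem"),
            z_nernst=_require(ec_doc, "z_nernst", "electrochem"),
            thermal_voltage=ec_doc.get("thermal_voltage_V", 0.025),
            c_ref=ec_doc.get("c_ref_mol_per_L", 1e-3),
        )
        hm_doc = doc["helmholtz"]
        helmholtz = HelmholtzModel(
            t_H=_require(hm_doc, "t_H_nm", "helmholtz") * NM_TO_CM,
            z_q=_require(hm_doc, "z_q", "helmholtz"),
            eps_H=hm_doc.get("rel_permittivity", 1.0) * CODATA.eps0,
        )
        bias = BiasPoint(V_ext=_require(doc["bias"], "V_ext_V", "bias"))
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    return Device(
        transistor=transistor,
        gate_stack=GateStack(layers),
        electrochem=electrochem,
        helmholtz=helmholtz,
        bias=bias,
    )


def device_config_dict(device: Device) -> dict:
    """Serialise a Device back to the file schema (lengths in nm)."""
    return {
        "transistor": {
            "W_nm": device.transistor.W / NM_TO_CM,
            "L_nm": device.transistor.L / NM_TO_CM,
            "mu_c_cm2_per_Vs": device.transistor.mu_c,
            "V_T_FET_V": device.transistor.V_T_FET,
        },
        "gate_stack": [
            {
                "label": layer.label,
                "thickness_nm": layer.thickness / NM_TO_CM,
                "rel_permittivity": layer.rel_permittivity,
            }
            for layer in device.gate_stack.layers
        ],
        "electrochem": {
            "V0_V": device.electrochem.V0,
            "z_nernst": device.electrochem.z_nernst,
            "thermal_voltage_V": device.electrochem.thermal_voltage,
            "c_ref_mol_per_L": device.electrochem.c_ref,
        },
        "helmholtz": {
            "t_H_nm": device.helmholtz.t_H / NM_TO_CM,
            "z_q": device.helmholtz.z_q,
            "rel_permittivity": device.helmholtz.eps_H / CODATA.eps0,
        },
        "bias": {"V_ext_V": device.bias.V_ext},
    }


def dump_device_config(device: Device, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(device_config_dict(device), fh, indent=2)


def load_kinetics_config(source: Union[PathLike, dict]) -> tuple[KineticsSpec, float]:
    """Parse a kinetics JSON: {A0_mol_per_L, order, k, t_meas_s}."""
    doc = _load_json(source)
    try:
        spec = KineticsSpec(
            A0=_require(doc, "A0_mol_per_L", "kinetics"),
            n=_require(doc, "order", "kinetics"),
            k=_require(doc, "k", "kinetics"),
        )
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    t_meas = _require(doc, "t_meas_s", "kinetics")
    if t_meas <= 0:
        raise ConfigError("kinetics: t_meas_s must be positive")
    return spec, t_meas


def write_design_report(report: DesignReport, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)


def read_design_report(path: PathLike) -> DesignReport:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("A0_range", "P_range", "I_D_range", "in_regime"):
        doc[key] = tuple(doc[key])
    return DesignReport(**doc)


def write_progress_curve(curve: ProgressCurve, csv_path: PathLike) -> None:
    """Time-series CSV plus a sidecar JSON carrying A0."""
    pd.DataFrame({"t_s": curve.t, "P_mol_per_L": curve.P}).to_csv(csv_path, index=False)
    sidecar = Path(csv_path).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"A0_mol_per_L": curve.A0}, fh)


def read_progress_curve(csv_path: PathLike, A0: float | None = None) -> ProgressCurve:
    """Read a (t, P) CSV; A0 comes from the sidecar JSON unless given."""
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if A0 is None:
        sidecar = Path(csv_path).with_suffix(".json")
        if not sidecar.exists():
            raise ConfigError(f"no A0 given and no sidecar {sidecar} found")
        with open(sidecar) as fh:
            A0 = json.load(fh)["A0_mol_per_L"]
    return ProgressCurve(
        t=df["t_s"].to_numpy(), P=df["P_mol_per_L"].to_numpy(), A0=float(A0)
    )


def read_rate_dataset(path: PathLike) -> RateDataset:
    return RateDataset.from_csv(path)
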