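"""Physical constants in the cm-based electrostatic unit system.

Electrostatics throughout the package is expressed per cm (F/cm, F/cm²,
C/cm²) because device gate stacks are conventionally quoted that way;
concentrations cross from mol/L to mol/cm³ only inside the charge
formulas.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 exact values; immutable."""

    e: float = 1.602176634e-19      # elementary charge, C
    N_A: float = 6.02214076e23      # Avogadro number, mol^-1
    eps0: float = 8.8541878128e-14  # vacuum permittivity, F/cm
    R: float = 8.31446261815324     # molar gas constant, J/(mol K)
    F: float = 96485.33212331001    # Faraday constant, C/mol


#: Shared immutable instance used by every module.
CODATA = PhysicalConstants()

#: mol/L -> mol/cm^3
PER_LITRE_TO_PER_CM3 = 1e-3

#: nm -> cm (config files carry lengths in nm)
NM_TO_CM = 1e-7
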