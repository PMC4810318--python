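"""Physical constants used throughout the package.

Values follow the CODATA conventions customarily rounded in charged-particle
dosimetry work.  The Bethe prefactor ``K`` is the standard
``4 pi N_A r_e^2 m_e c^2`` combination expressed in MeV cm^2 mol^-1, so that
multiplying by (Z/A) of the medium in mol g^-1 yields a mass stopping power
in MeV cm^2 g^-1.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicsConstants:
    """Bundle of constants for stopping-power and dosimetry arithmetic.

    Attributes
    ----------
    k : float
        Bethe prefactor, MeV cm^2 mol^-1 (0.307075).
    electron_rest_energy : float
        m_e c^2 in MeV.
    nucleon_rest_energy : float
        Rest energy per nucleon used for projectile kinematics, MeV.
        The proton mass is used for all ions; binding-energy differences
        are negligible at the percent level relevant here.
    avogadro : float
        Avogadro constant, mol^-1.
    let_dose_conversion : float
        Gy per (keV/um * cm^-2) fluence-LET product in a unit-density
        medium: 1 keV/um = 1.602e-9 Gy cm^2 / g * (rho = 1 g/cm^3).
    """

    k: float = 0.307075
    electron_rest_energy: float = 0.51099895
    nucleon_rest_energy: float = 938.272
    avogadro: float = 6.02214076e23
    let_dose_conversion: float = 1.602e-9

    def __post_init__(self) -> None:
        for name in ("k", "electron_rest_energy", "nucleon_rest_energy",
                     "avogadro", "let_dose_conversion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Module-level default constants instance.
CONSTANTS = PhysicsConstants()

#: 1 mb = 1e-27 cm^2
MB_TO_CM2 = 1.0e-27

#: 1 fm^2 = 10 mb
FM2_TO_MB = 10.0

#: MeV cm^2/g (in water, rho=1) -> keV/um conversion for LET:
#: 1 MeV/cm = 1e3 keV / 1e4 um = 0.1 keV/um.
MEV_CM2_G_TO_KEV_UM = 0.1
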