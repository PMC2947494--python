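"""Physical constants and unit conversions.

Internal unit system: lengths in Å, charges in elementary charges (e),
potentials as the dimensionless reduced potential phi = e*psi/(kB*T).
In these units the Poisson equation for a uniform medium reads

    -eps * laplacian(phi) = C * rho,      C = e^2 / (eps0 * kB * T)  [Å]

with rho a number-charge density in e/Å^3, so the point-charge solution is
phi(r) = (C/4pi) * q / (eps * r).  C/4pi is the vacuum Bjerrum length
(~560 Å at 298.15 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants as _sc

__all__ = ["PhysicalConstants", "CONSTANTS_298"]

_M_TO_ANGSTROM = 1e10


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature plus the fundamental constants used throughout.

    All defaults come from scipy.constants (CODATA).  Only the temperature
    is normally varied.
    """

    temperature: float = 298.15  # K
    boltzmann: float = _sc.k  # J/K
    elementary_charge: float = _sc.e  # C
    avogadro: float = _sc.N_A  # 1/mol
    vacuum_permittivity: float = _sc.epsilon_0  # F/m

    def __post_init__(self) -> None:
        for name in (
            "temperature",
            "boltzmann",
            "elementary_charge",
            "avogadro",
            "vacuum_permittivity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in joules."""
        return self.boltzmann * self.temperature

    @property
    def coulomb_factor(self) -> float:
        """e^2/(eps0*kB*T) in Å — the source-term prefactor C above."""
        return (
            self.elementary_charge**2
            / (self.vacuum_permittivity * self.kT)
            * _M_TO_ANGSTROM
        )

    @property
    def bjerrum_vacuum(self) -> float:
        """Vacuum Bjerrum length e^2/(4 pi eps0 kB T) in Å."""
        return self.coulomb_factor / (4.0 * math.pi)

    @property
    def phi_per_mV(self) -> float:
        """Reduced potential corresponding to 1 mV (e * 1 mV / kT)."""
        return self.elementary_charge * 1e-3 / self.kT

    @property
    def kT_kJ_per_mol(self) -> float:
        """kB*T in kJ/mol."""
        return self.kT * self.avogadro / 1000.0

    @property
    def kT_kcal_per_mol(self) -> float:
        """kB*T in kcal/mol (1 kcal = 4.184 kJ)."""
        return self.kT_kJ_per_mol / 4.184

    def number_density(self, molar: float) -> float:
        """Convert a molar concentration (mol/L) to a number density in Å^-3."""
        return molar * self.avogadro / 1e27


#: Shared default constants at 298.15 K.
CONSTANTS_298 = PhysicalConstants()
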