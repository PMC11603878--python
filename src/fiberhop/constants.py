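"""Physical constants (CODATA 2018) and the unit conversions used throughout.

Energies are carried in eV (or meV where noted), temperatures in K, rates and
currents in SI.  Everything that converts between these scales lives here so
that no module hard-codes its own Boltzmann constant.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 exact values with accessors in the two unit systems used.

    Attributes
    ----------
    e : elementary charge in C.
    k_B_J : Boltzmann constant in J/K.
    k_B_eV : Boltzmann constant in eV/K.
    hbar_Js : reduced Planck constant in J*s.
    hbar_eVs : reduced Planck constant in eV*s.
    """

    e: float = 1.602176634e-19
    k_B_J: float = 1.380649e-23
    k_B_eV: float = 8.617333262e-5
    hbar_Js: float = 1.054571817e-34
    hbar_eVs: float = 6.582119569e-16


CONST = PhysicalConstants()

#: 1 cm^-1 in meV (h*c / e, CODATA): photon energy of a 1 cm^-1 mode.
MEV_PER_WAVENUMBER = 0.12398419843320026


def wavenumber_to_energy(nu: float) -> float:
    """Convert a vibrational wavenumber (cm^-1) to an energy quantum (meV).

    Parameters
    ----------
    nu : wavenumber in cm^-1, must be non-negative.

    Returns
    -------
    Energy h*c*nu in meV (1 cm^-1 = 0.1239842 meV).
    """
    if nu < 0:
        raise ValueError(f"wavenumber must be non-negative, got {nu}")
    return nu * MEV_PER_WAVENUMBER
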