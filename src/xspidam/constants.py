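"""Physical constants in the package unit system.

Internal units: length in Angstrom, time in femtosecond, energy in eV.
The derived mass unit is eV fs^2 / A^2 (so that KE = m v^2 / 2 comes out
in eV when v is in A/fs). Cross sections are carried in cm^2 because the
shipped tables and the fluence bookkeeping use CGS areas; ``CM2_TO_A2``
converts where a geometric comparison in sample coordinates is needed.
"""

import numpy as np

# speed of light, Angstrom per femtosecond
C_AA_FS = 2997.92458

# electron rest mass, eV fs^2 / A^2  (m_e c^2 = 510998.95 eV)
M_E = 510998.95 / C_AA_FS**2

# atomic mass unit, eV fs^2 / A^2
AMU = 931494103.0 / C_AA_FS**2

# Coulomb constant e^2 / (4 pi eps0), eV * Angstrom
COULOMB_EV_AA = 14.399645

# classical electron radius and Thomson scale
R_E_CM = 2.8179403262e-13
R_E2_CM2 = R_E_CM**2

# photon energy (keV) * wavelength (A) product
HC_KEV_AA = 12.39841984

# Joule per keV
KEV_TO_J = 1.602176634e-16

CM2_TO_A2 = 1.0e16

HBAR_EV_FS = 0.6582119569


def electron_speed(kinetic_energy_ev):
    """Non-relativistic electron speed in A/fs from kinetic energy in eV.

    At the photoelectron energies used here (<~ 5 keV) the relativistic
    correction to the speed is below 1% and is ignored.
    """
    return np.sqrt(2.0 * np.asarray(kinetic_energy_ev, dtype=float) / M_E)


def wavelength_A(photon_energy_keV: float) -> float:
    """X-ray wavelength in Angstrom."""
    return HC_KEV_AA / photon_energy_keV
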