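"""Physical constants and unit conversions.

Internal convention: atomic units for energies/gradients/charges, Å for
coordinates at the interfaces, cm⁻¹ for spectroscopic energies.  All
conversion factors used anywhere in the package live here.
"""

import numpy as np

# CODATA-2018 values.
HARTREE_TO_CM = 219474.6313632
CM_TO_HARTREE = 1.0 / HARTREE_TO_CM
BOHR_TO_ANG = 0.529177210903
ANG_TO_BOHR = 1.0 / BOHR_TO_ANG
AMU_TO_AU = 1822.888486209
EV_TO_CM = 8065.543937
KCALMOL_TO_HARTREE = 1.0 / 627.5094740631

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def nm_to_cm(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) to wavenumber (cm⁻¹): 10⁷/λ."""
    return 1.0e7 / wavelength_nm


def cm_to_nm(wavenumber_cm: float) -> float:
    """Wavenumber (cm⁻¹) to vacuum wavelength (nm)."""
    return 1.0e7 / wavenumber_cm
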