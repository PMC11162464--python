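"""Unit conventions and conversion constants.

Energies are expressed in eV, vibrational frequencies in cm^-1, time in fs.
Nuclear coordinates are dimensionless mass-frequency-scaled normal
coordinates, with the ground-state equilibrium geometry at q = 0.
All conversions go through the constants defined here.
"""

import math

#: 1 cm^-1 in eV.
EV_PER_CM1 = 1.239841984e-4

#: Reduced Planck constant in eV*fs.
HBAR_EV_FS = 0.6582119569

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian profile.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def cm1_to_ev(freq_cm1):
    """Convert a wavenumber (cm^-1) to an energy quantum (eV)."""
    return freq_cm1 * EV_PER_CM1


def ev_to_cm1(energy_ev):
    """Convert an energy (eV) to a wavenumber (cm^-1)."""
    return energy_ev / EV_PER_CM1


def vibrational_period_fs(freq_cm1):
    """Classical period T = 2*pi*hbar / (hbar*omega) of a mode, in fs.

    For 1600 cm^-1 this evaluates to 20.85 fs, i.e. T(fs) ~ 33356.4/nu(cm^-1).
    """
    return 2.0 * math.pi * HBAR_EV_FS / cm1_to_ev(freq_cm1)
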