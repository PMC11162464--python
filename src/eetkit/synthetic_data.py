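"""Synthetic fixtures with known ground truth.

Two generators emulate the data the analysis chain consumes:

* :func:`make_nadh_model` — a three-diabatic-state heterodimer model
  (bright donor state ``La``, dark charge-transfer state ``CT``, acceptor
  state ``Nic*``) with high-frequency tuning modes near 1400 and 1600 cm^-1
  on the donor, a low-frequency band of CT<->acceptor coupling modes, and
  electronic couplings into the CT state larger than the direct LE-LE ones
  (the one-electron character of LE/CT coupling).  Absolute energies are
  synthetic: the donor is pinned at the 4.7 eV pump resonance and the
  acceptor/CT offsets default to -0.5 eV.

* :func:`make_ta_map` — a delay x probe-energy differential-absorption map
  built from sequential kinetics (default lifetimes 157 and 894 fs)
  convolved with a 30 fs Gaussian instrument response, plus i.i.d. Gaussian
  noise scaled to the peak signal over SNR.  The ground-truth lifetimes,
  spectra and time zero are returned alongside for recovery studies.

Both generators are pure functions of their configuration: the same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from .kinetics import TAMap, sequential_profiles
from .vibronic_model import BasisSpec, VibronicModel

__all__ = ["SynthConfig", "make_nadh_model", "make_nadh_basis", "make_ta_map"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generators (energies eV, frequencies
    cm^-1, times fs)."""

    seed: int = 0
    # -- vibronic model --
    e_la: float = 4.7                     # donor pinned at the pump resonance
    nic_offset: float = -0.5              # E_Nic* - E_La (synthetic default)
    ct_offset: float = -0.5               # E_CT - E_La at Franck-Condon
    tuning_frequencies: Tuple[float, ...] = (1400.0, 1600.0)
    n_coupling_modes: int = 2
    coupling_band: Tuple[float, float] = (300.0, 500.0)  # low-frequency band
    kappa_la: float = -0.20               # tuning gradient of the donor
    kappa_other: float = 0.05             # residual tuning on CT / acceptor
    v0_la_ct: float = 0.13                # |V/Delta| ~ 0.27 at a 0.5 eV gap
    v0_ct_nic: float = 0.10
    v0_la_nic: float = 0.02               # direct LE-LE coupling, weaker
    lam_ct_nic: float = 0.05              # low-frequency CT<->acceptor coupling
    lam_la_nic: float = 0.04              # direct vibronic channel (tuning modes)
    lam_la_ct: float = 0.03
    # -- TA map --
    lifetimes: Tuple[float, ...] = (157.0, 894.0)
    amplitude_scale: float = 1.0          # global EAS amplitude factor
    irf_fwhm: float = 30.0
    snr: float = 50.0
    t0: float = 0.0
    delay_start: float = -100.0
    delay_stop: float = 1500.0
    delay_step: float = 5.0
    probe_min: float = 1.9
    probe_max: float = 3.2
    n_probe: int = 80
    pump_ev: float = 4.7

    def __post_init__(self):
        if any(f <= 0 for f in self.tuning_frequencies):
            raise ValueError("tuning frequencies must be positive")
        if self.coupling_band[0] <= 0 or self.coupling_band[1] < self.coupling_band[0]:
            raise ValueError("coupling_band must be a positive increasing pair")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if any(tau <= 0 for tau in self.lifetimes):
            raise ValueError("lifetimes must be positive")


def make_nadh_model(config: SynthConfig = SynthConfig()) -> VibronicModel:
    """Build the default donor/CT/acceptor LVC model.

    Mode layout: the tuning modes come first, then ``n_coupling_modes``
    low-frequency modes evenly spaced across ``coupling_band``.  The donor
    carries the tuning gradients; the direct donor->acceptor vibronic
    coupling rides on the tuning modes while the CT->acceptor coupling
    rides on the low-frequency band.  Deterministic per configuration.
    """
    labels = ("La", "CT", "Nic*")
    E = np.array([config.e_la,
                  config.e_la + config.ct_offset,
                  config.e_la + config.nic_offset])
    n_tun = len(config.tuning_frequencies)
    n_low = config.n_coupling_modes
    low = np.linspace(config.coupling_band[0], config.coupling_band[1], n_low) \
        if n_low else np.empty(0)
    omega = np.concatenate([np.asarray(config.tuning_frequencies, dtype=float), low])
    nm = omega.size

    kappa = np.zeros((3, nm))
    kappa[0, :n_tun] = config.kappa_la
    kappa[1, :n_tun] = -config.kappa_other   # CT relaxes opposite to the donor
    kappa[2, :n_tun] = config.kappa_other

    lam = np.zeros((3, 3, nm))
    lam[0, 2, :n_tun] = lam[2, 0, :n_tun] = config.lam_la_nic
    lam[0, 1, :n_tun] = lam[1, 0, :n_tun] = config.lam_la_ct
    lam[1, 2, n_tun:] = lam[2, 1, n_tun:] = config.lam_ct_nic

    V0 = np.zeros((3, 3))
    V0[0, 1] = V0[1, 0] = config.v0_la_ct
    V0[1, 2] = V0[2, 1] = config.v0_ct_nic
    V0[0, 2] = V0[2, 0] = config.v0_la_nic
    return VibronicModel(labels, E, omega, kappa, lam, V0)


def make_nadh_basis(config: SynthConfig = SynthConfig()) -> BasisSpec:
    """Desk-scale ladder truncation matched to the default model.

    High-frequency tuning modes stay close to their ground level (8 levels
    suffice); the low-frequency coupling modes absorb vibrational energy
    during the sustained CT/acceptor exchange and need ladders deepening
    with 1/frequency (about 6000/omega levels).  Sized so the leakage
    monitor stays silent over a 200 fs propagation.
    """
    levels = []
    for f in config.tuning_frequencies:
        levels.append(8)
    n_low = config.n_coupling_modes
    low = np.linspace(config.coupling_band[0], config.coupling_band[1], n_low) \
        if n_low else np.empty(0)
    for f in low:
        levels.append(max(10, int(np.ceil(6000.0 / f))))
    return BasisSpec(np.asarray(levels, dtype=int))


def _eas_shapes(probe: np.ndarray) -> np.ndarray:
    """Two synthetic evolution-associated spectra (mOD): a broad donor
    photoinduced-absorption band peaking above 3 eV, and a long-lived
    acceptor band at 3.1 eV."""
    donor = 4.0 * np.exp(-0.5 * ((probe - 2.6) / 0.5) ** 2) \
        + 3.0 * np.exp(-0.5 * ((probe - 3.05) / 0.12) ** 2)
    acceptor = 2.0 * np.exp(-0.5 * ((probe - 3.1) / 0.15) ** 2) \
        + 0.3 * np.exp(-0.5 * ((probe - 2.3) / 0.4) ** 2)
    return np.vstack([donor, acceptor])


def make_ta_map(config: SynthConfig = SynthConfig()) -> Tuple[TAMap, dict]:
    """Generate a TA map from sequential kinetics plus Gaussian noise.

    Returns the map and a ground-truth record ``{"tau", "eas", "t0",
    "irf_fwhm"}``.  Noise is additive i.i.d. Gaussian per cell with standard
    deviation peak|dA|/SNR.
    """
    delays = np.arange(config.delay_start, config.delay_stop + config.delay_step / 2,
                       config.delay_step)
    probe = np.linspace(config.probe_min, config.probe_max, config.n_probe)
    taus = np.asarray(config.lifetimes, dtype=float)
    C = sequential_profiles(delays, taus, config.irf_fwhm, config.t0)
    eas = config.amplitude_scale * _eas_shapes(probe)
    if eas.shape[0] < taus.size:
        raise ValueError("not enough EAS shapes for the requested components")
    eas = eas[: taus.size]
    clean = C @ eas
    rng = np.random.default_rng(config.seed)
    noise = np.abs(clean).max() / config.snr * rng.standard_normal(clean.shape) \
        if np.isfinite(config.snr) and np.abs(clean).max() > 0 else np.zeros_like(clean)
    tamap = TAMap(delays, probe, clean + noise,
                  irf_fwhm=config.irf_fwhm, pump_ev=config.pump_ev)
    truth = {"tau": taus, "eas": eas, "t0": config.t0, "irf_fwhm": config.irf_fwhm}
    return tamap, truth
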