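"""Wavepacket propagation: closed forms, oracles and unitarity invariants."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from eetkit.quantum_dynamics import (
    BasisLeakageWarning,
    Trajectory,
    burst_spacing,
    classify_pathway,
    coherences,
    initial_wavepacket,
    propagate,
    transfer_burst_times,
)
from eetkit.units import HBAR_EV_FS, cm1_to_ev, vibrational_period_fs
from eetkit.vibronic_model import BasisSpec, VibronicModel, build_hamiltonian

from test_vibronic_model import random_model, simple_model


def rabi_model(V0=0.1):
    return VibronicModel(("a", "b"), [1.0, 1.0], [], np.zeros((2, 0)),
                         np.zeros((2, 2, 0)), [[0.0, V0], [V0, 0.0]])


NO_MODES = BasisSpec(np.empty(0, dtype=int))


class TestInitialWavepacket:
    def test_franck_condon_is_pure_state_at_origin(self):
        m = simple_model(ns=2, nm=1)
        traj = propagate(m, BasisSpec.uniform(1, 6), t_final=1.0, dt_out=0.5,
                         initial_state="s0")
        assert traj.populations[0] == pytest.approx([1.0, 0.0])
        assert np.all(traj.coherences[0] - np.diag(np.diag(traj.coherences[0])) == 0)
        assert traj.q_expect[0] == pytest.approx(0.0)

    def test_unknown_label(self):
        m = simple_model()
        with pytest.raises(Exception, match="unknown state"):
            initial_wavepacket(m, BasisSpec.uniform(1, 4), "zz")

    def test_zero_point_energy_uncoupled(self):
        m = simple_model(ns=2, nm=2, omega=np.array([1400.0, 1600.0]))
        traj = propagate(m, BasisSpec.uniform(2, 5), t_final=1.0, dt_out=0.5,
                         initial_state="s0")
        zpe = 0.5 * (cm1_to_ev(1400.0) + cm1_to_ev(1600.0))
        assert traj.energy[0] == pytest.approx(1.0 + zpe, abs=1e-12)


class TestClosedForms:
    def test_rabi_populations_and_coherence(self):
        """Two degenerate states, no modes: P2 = sin^2(V0 t / hbar) and
        |rho_12| = |sin(2 V0 t / hbar)|/2."""
        traj = propagate(rabi_model(0.1), NO_MODES, t_final=20.0, dt_out=0.05,
                         initial_state="a")
        t = traj.times
        assert traj.population("b") == pytest.approx(
            np.sin(0.1 * t / HBAR_EV_FS) ** 2, abs=1e-6)
        assert coherences(traj, ("a", "b")) == pytest.approx(
            0.5 * np.abs(np.sin(2 * 0.1 * t / HBAR_EV_FS)), abs=1e-6)
        # full population inversion at t = pi*hbar/(2 V0) = 10.34 fs
        i = np.argmin(np.abs(t - np.pi * HBAR_EV_FS / 0.2))
        assert traj.population("b")[i] > 0.99999

    def test_displaced_oscillator_ehrenfest(self):
        """Single surface with gradient kappa: <q>(t) = (kappa/omega)(cos wt - 1),
        period 20.85 fs at 1600 cm^-1."""
        m = VibronicModel(("s",), [0.0], [1600.0], [[0.1]],
                          np.zeros((1, 1, 1)), [[0.0]])
        traj = propagate(m, BasisSpec.uniform(1, 30), t_final=42.0, dt_out=0.05,
                         initial_state="s")
        w = cm1_to_ev(1600.0)
        expected = (0.1 / w) * (np.cos(w * traj.times / HBAR_EV_FS) - 1.0)
        assert traj.q_expect[:, 0] == pytest.approx(expected, abs=1e-6)
        assert vibrational_period_fs(1600.0) == pytest.approx(20.85, abs=0.01)

    def test_dense_matrix_exponential_oracle(self):
        """Sparse-action propagation agrees with dense expm on a 2-mode model
        to 1e-8 in every population sample."""
        rng = np.random.default_rng(5)
        m = random_model(rng, ns=3, nm=2)
        basis = BasisSpec.uniform(2, 5)
        traj = propagate(m, basis, t_final=30.0, dt_out=1.0, initial_state="s0")
        H = build_hamiltonian(m, basis).toarray()
        psi = initial_wavepacket(m, basis, "s0").coeffs
        U = expm(-1j * H * 1.0 / HBAR_EV_FS)
        for it in range(traj.times.size):
            pops = np.sum(np.abs(psi.reshape(-1, 3)) ** 2, axis=0)
            assert np.max(np.abs(pops - traj.populations[it])) < 1e-8
            psi = U @ psi


class TestInvariants:
    def test_unitarity_over_200fs(self):
        rng = np.random.default_rng(7)
        m = random_model(rng, ns=3, nm=2)
        traj = propagate(m, BasisSpec.uniform(2, 8), t_final=200.0, dt_out=1.0,
                         initial_state="s0")
        traj.validate()  # norm/energy drift <= 1e-6, populations sum to 1
        assert np.max(np.abs(traj.norm - 1.0)) < 1e-9
        assert np.max(np.abs(traj.energy - traj.energy[0])) < 1e-9

    def test_cauchy_schwarz_bound(self, default_trajectory):
        p = default_trajectory.populations
        bound = np.sqrt(p[:, :, None] * p[:, None, :])
        assert np.max(default_trajectory.coherences - bound) <= 1e-8
        off = ~np.eye(3, dtype=bool)
        assert np.max(default_trajectory.coherences[:, off]) <= 0.5 + 1e-8

    def test_phase_flip_gauge_invariance(self):
        """Flipping the sign of every coupling into one state leaves the
        populations and coherence magnitudes unchanged."""
        rng = np.random.default_rng(9)
        m = random_model(rng, ns=3, nm=2)
        s = 1
        V0, lam = m.V0.copy(), m.lam.copy()
        V0[s, :] *= -1; V0[:, s] *= -1; V0[s, s] = 0.0
        lam[s, :, :] *= -1; lam[:, s, :] *= -1; lam[s, s, :] = 0.0
        flipped = dataclasses.replace(m, V0=V0, lam=lam)
        basis = BasisSpec.uniform(2, 6)
        t1 = propagate(m, basis, t_final=40.0, dt_out=1.0, initial_state="s0")
        t2 = propagate(flipped, basis, t_final=40.0, dt_out=1.0, initial_state="s0")
        assert t1.populations == pytest.approx(t2.populations, abs=1e-10)
        assert t1.coherences == pytest.approx(t2.coherences, abs=1e-10)

    def test_basis_convergence_is_monotonic(self):
        """Max population deviation from a large-basis reference decreases
        as the ladder deepens."""
        m = simple_model(ns=2, nm=1, kappa=np.array([[-0.2], [0.0]]),
                         V0=np.array([[0.0, 0.05], [0.05, 0.0]]),
                         E=np.array([4.7, 4.4]))
        ref = propagate(m, BasisSpec.uniform(1, 40), t_final=50.0, dt_out=1.0,
                        initial_state="s0").populations
        devs = []
        for levels in (6, 10, 20):
            p = propagate(m, BasisSpec.uniform(1, levels), t_final=50.0,
                          dt_out=1.0, initial_state="s0",
                          leak_threshold=1.1).populations
            devs.append(np.max(np.abs(p - ref)))
        assert devs[0] > devs[1] > devs[2]

    def test_leakage_warning_names_mode(self):
        m = simple_model(ns=1, nm=1, state_labels=("s",), E=np.array([0.0]),
                         kappa=np.array([[0.3]]))
        with pytest.warns(BasisLeakageWarning, match="mode 0"):
            propagate(m, BasisSpec.uniform(1, 3), t_final=20.0, dt_out=1.0,
                      initial_state="s")


class TestPathwayAndBursts:
    @staticmethod
    def _fake_traj(p_ct):
        nt = p_ct.size
        pops = np.column_stack([1.0 - p_ct, p_ct])
        return Trajectory(np.arange(nt, dtype=float), pops,
                          np.zeros((nt, 2, 2)), np.zeros(nt), np.ones(nt),
                          np.zeros((nt, 0)), ("La", "CT"))

    def test_classification_thresholds(self):
        t = np.linspace(0, 1, 50)
        assert classify_pathway(self._fake_traj(0.05 * np.sin(np.pi * t)), "CT") == "direct"
        assert classify_pathway(self._fake_traj(0.8 * t), "CT") == "ct_trapped"
        transient = 0.4 * np.sin(np.pi * t)  # peaks at 0.4, ends near 0
        assert classify_pathway(self._fake_traj(transient), "CT") == "ct_mediated"

    def test_default_model_is_ct_mediated(self, default_trajectory):
        assert classify_pathway(default_trajectory, "CT") == "ct_mediated"

    def test_two_state_burst_spacing_half_period(self):
        """A 1600 cm^-1 tuning mode carries the surfaces through degeneracy
        twice per 20.85 fs period: bursts spaced ~10.4 fs."""
        m = VibronicModel(("donor", "acceptor"), [4.7, 4.4], [1600.0],
                          [[-0.25], [0.0]], np.zeros((2, 2, 1)),
                          [[0.0, 0.02], [0.02, 0.0]])
        traj = propagate(m, BasisSpec.uniform(1, 60), t_final=100.0,
                         dt_out=0.05, initial_state="donor")
        times = transfer_burst_times(traj, "acceptor")
        assert times.size >= 6
        spacing = burst_spacing(traj, "acceptor")
        assert spacing == pytest.approx(vibrational_period_fs(1600.0) / 2, abs=1.5)

    def test_burst_spacing_requires_two_bursts(self):
        traj = self._fake_traj(np.zeros(10))
        with pytest.raises(ValueError, match="fewer than two"):
            burst_spacing(traj, "CT")
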