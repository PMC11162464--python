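"""TA global analysis and the folded/EET lifetime decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad, solve_ivp

from eetkit.kinetics import (
    KineticsError,
    TAMap,
    decompose_eet,
    eet_time,
    folded_lifetime,
    global_fit,
    irf_exp,
    mc_uncertainty,
    sequential_profiles,
)
from eetkit.synthetic_data import SynthConfig, make_ta_map


class TestIRFExp:
    def test_delta_irf_is_step_exponential(self):
        t = np.linspace(-50, 300, 100)
        c = irf_exp(t, tau=100.0, irf_fwhm=0.0, t0=10.0)
        after = t >= 10.0
        assert c[after] == pytest.approx(np.exp(-(t[after] - 10.0) / 100.0))
        assert np.all(c[~after] == 0.0)

    def test_vanishes_far_before_time_zero(self):
        assert irf_exp(np.array([-1e4]), 157.0, 30.0)[0] == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(irf_exp(np.array([1e5]), 157.0, 30.0))[0]

    def test_matches_numerical_convolution(self):
        """Closed form against direct quadrature of exp decay (x) Gaussian."""
        tau, fwhm = 157.0, 30.0
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        t = np.linspace(-100, 500, 61)

        def oracle(tt):
            f = lambda s: np.exp(-s / tau) * \
                np.exp(-(tt - s) ** 2 / (2 * sig ** 2)) / (sig * np.sqrt(2 * np.pi))
            return quad(f, 0.0, tt + 12 * sig, limit=400, points=[max(tt, 0.0)])[0] \
                if tt + 12 * sig > 0 else 0.0

        num = np.array([oracle(x) for x in t])
        assert irf_exp(t, tau, fwhm) == pytest.approx(num, abs=1e-6)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(KineticsError):
            irf_exp(np.array([0.0]), tau=-1.0, irf_fwhm=10.0)


class TestSequentialProfiles:
    def test_chain_matches_ode_oracle(self):
        """With no IRF, the closed-form chain equals the integrated
        sequential rate equations."""
        taus = [157.0, 894.0, 3000.0]
        k = 1.0 / np.asarray(taus)

        def rhs(t, c):
            return [-k[0] * c[0],
                    k[0] * c[0] - k[1] * c[1],
                    k[1] * c[1] - k[2] * c[2]]

        t_eval = np.linspace(0, 2000, 80)
        sol = solve_ivp(rhs, (0, 2000), [1.0, 0.0, 0.0], t_eval=t_eval,
                        rtol=1e-11, atol=1e-13)
        C = sequential_profiles(t_eval, taus, irf_fwhm=0.0)
        assert C == pytest.approx(sol.y.T, abs=1e-8)

    def test_equal_lifetimes_rejected(self):
        with pytest.raises(KineticsError, match="distinct"):
            sequential_profiles(np.linspace(0, 10, 5), [100.0, 100.0], 0.0)


class TestGlobalFit:
    def test_noiseless_single_component(self):
        tamap, truth = make_ta_map(SynthConfig(snr=np.inf, lifetimes=(157.0,)))
        fit = global_fit(tamap, 1)
        assert fit.success
        assert fit.tau[0] == pytest.approx(157.0, rel=1e-3)

    def test_noiseless_two_components(self):
        tamap, truth = make_ta_map(SynthConfig(snr=np.inf))
        fit = global_fit(tamap, 2)
        assert fit.tau == pytest.approx([157.0, 894.0], rel=1e-3)
        assert fit.rmse < 1e-8

    def test_recovery_under_noise_20_seeds(self):
        """tau1 recovered within +-5% at SNR 50; bias < 1%, RMSE < 5%."""
        rel_err = []
        for seed in range(20):
            tamap, _ = make_ta_map(SynthConfig(seed=seed, snr=50.0))
            fit = global_fit(tamap, 2)
            assert fit.success
            rel_err.append(fit.tau[0] / 157.0 - 1.0)
        rel_err = np.asarray(rel_err)
        assert np.max(np.abs(rel_err)) < 0.05
        assert abs(rel_err.mean()) < 0.01
        assert np.sqrt(np.mean(rel_err ** 2)) < 0.05

    def test_deterministic_given_seed(self):
        tamap, _ = make_ta_map(SynthConfig(seed=3, snr=50.0))
        f1 = global_fit(tamap, 2, seed=5)
        f2 = global_fit(tamap, 2, seed=5)
        assert np.array_equal(f1.tau, f2.tau)

    def test_axis_validation(self):
        with pytest.raises(KineticsError, match="strictly increasing"):
            TAMap(np.array([0.0, 0.0, 1.0]), np.array([1.9, 3.2]),
                  np.zeros((3, 2)))
        with pytest.raises(KineticsError, match="does not match"):
            TAMap(np.array([0.0, 1.0]), np.array([1.9, 3.2]), np.zeros((3, 2)))


class TestDecomposition:
    def test_headline_chain(self):
        """122 fs mixture, 157 fs unfolded/IC, folded fraction 0.3 gives a
        ~40 fs folded lifetime and a ~54 fs transfer time."""
        assert folded_lifetime(122.0, 157.0, 0.3) == pytest.approx(40.333, abs=0.001)
        assert eet_time(40.0, 157.0) == pytest.approx(53.68, abs=0.01)
        d = decompose_eet(122.0, 157.0, 0.3, 157.0)
        assert d.tau_folded == pytest.approx(40.333, abs=0.001)
        assert d.tau_eet == pytest.approx(54.28, abs=0.01)
        assert d.k_total == pytest.approx(d.k_ic + d.k_et, abs=1e-12)

    def test_pure_folded_limit(self):
        assert folded_lifetime(80.0, 157.0, 1.0) == pytest.approx(80.0)

    def test_round_trip_identity(self):
        tau_mix = 0.6 * 150.0 + 0.4 * 50.0
        assert tau_mix == pytest.approx(110.0)
        assert folded_lifetime(tau_mix, 150.0, 0.4) == pytest.approx(50.0, abs=1e-10)

    @given(st.floats(10.0, 500.0), st.floats(0.05, 1.0), st.floats(10.0, 500.0))
    def test_compose_decompose_random(self, tau_u, f, tau_f):
        mix = (1 - f) * tau_u + f * tau_f
        assert folded_lifetime(mix, tau_u, f) == pytest.approx(tau_f, rel=1e-9)

    def test_inconsistent_mixture_rejected(self):
        with pytest.raises(KineticsError, match="inconsistent"):
            folded_lifetime(100.0, 157.0, 0.1)  # would need negative tau_f

    def test_eet_time_limits(self):
        assert eet_time(50.0, 100.0) == pytest.approx(100.0)
        assert math.isinf(eet_time(157.0, 157.0))
        with pytest.raises(KineticsError, match="negative"):
            eet_time(200.0, 157.0)

    def test_eet_time_monotone_in_total_rate(self):
        taus = [eet_time(tt, 157.0) for tt in (30.0, 40.0, 50.0)]
        assert taus[0] < taus[1] < taus[2]


class TestMCUncertainty:
    def test_zero_sigma_gives_zero_spread(self):
        res = mc_uncertainty([122.0, 157.0], [0.0, 0.0],
                             lambda m, u: folded_lifetime(m, u, 0.3),
                             n_draws=1000, seed=1)
        assert res.sigma == pytest.approx(0.0, abs=1e-12)
        assert res.rejection_fraction == 0.0

    def test_linear_function_slope(self):
        res = mc_uncertainty([1.0], [0.5], lambda x: 3.0 * x + 1.0,
                             n_draws=100000, seed=2)
        assert res.sigma == pytest.approx(1.5, rel=0.03)
        assert res.p84 - res.p16 == pytest.approx(2 * 1.5, rel=0.05)

    def test_matches_delta_method_for_folded_lifetime(self):
        """sigma(tau_folded) from resampling equals first-order propagation
        sqrt((s_mix/f)^2 + ((1-f) s_unf / f)^2) within 5%."""
        f = 0.3
        res = mc_uncertainty([122.0, 157.0], [4.0, 4.0],
                             lambda m, u: folded_lifetime(m, u, f),
                             n_draws=100000, seed=3)
        delta = math.sqrt((4.0 / f) ** 2 + ((1 - f) * 4.0 / f) ** 2)
        assert res.sigma == pytest.approx(delta, rel=0.05)

    def test_invalid_draws_rejected_and_counted(self):
        # huge sigma drives many draws into the invalid (negative tau) region
        res = mc_uncertainty([122.0, 157.0], [60.0, 0.0],
                             lambda m, u: folded_lifetime(m, u, 0.3),
                             n_draws=5000, seed=4)
        assert res.rejection_fraction > 0.0
        assert res.n_valid + round(res.rejection_fraction * 5000) == 5000

    def test_requires_enough_draws(self):
        with pytest.raises(KineticsError, match="1000"):
            mc_uncertainty([1.0], [0.1], lambda x: x, n_draws=10)
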