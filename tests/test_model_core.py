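"""Single-neuron dynamics: gating rates, synapse kernel, Heun integrator."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from ctcsim.model_core import (
    AMPA,
    EXC_NEURON,
    GABA_A,
    INH_NEURON,
    IntegrationError,
    NeuronParams,
    NeuronState,
    SynapseParams,
    _resting_potential,
    dual_exp_norm,
    gating_rates,
    heun_step,
    kernel_peak_time,
    m_inf,
    membrane_derivative,
    steady_state,
    synaptic_current,
    synaptic_kernel,
)

# frozen from a 30-digit mpmath evaluation of the closed-form rate functions
RATES_AT_M65 = {
    "alpha_n": 0.073120273719894471,
    "beta_n": 0.81261029260530694,
    "alpha_m": 0.15718708947376786,
    "beta_m": 5.280771153736481,
    "alpha_h": 0.49667364200764004,
    "beta_h": 0.12063510708834601,
}


class TestGatingRates:
    def test_matches_high_precision_evaluation(self):
        r = gating_rates(-65.0)
        for name, expected in RATES_AT_M65.items():
            assert getattr(r, name) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("v_sing", [-34.0, -35.0])
    def test_removable_singularity_yields_limit(self, v_sing):
        """x/(1-exp(-x/a)) at x=0 must evaluate to its L'Hopital limit a."""
        r = gating_rates(v_sing)
        assert np.all(np.isfinite(np.array(r)))
        # compare with a nearby non-singular voltage: continuity
        r_eps = gating_rates(v_sing + 1e-9)
        for a, b in zip(r, r_eps):
            assert a == pytest.approx(b, rel=1e-6)

    def test_rates_nonnegative_over_physiological_range(self):
        v = np.linspace(-100.0, 40.0, 701)
        r = gating_rates(v)
        for arr in r:
            assert np.all(arr >= 0)

    def test_m_inf_monotone_sigmoid(self):
        v = np.linspace(-100.0, 40.0, 281)
        m = m_inf(v)
        assert np.all(np.diff(m) >= 0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            gating_rates(np.nan)


class TestMembrane:
    def test_leaky_integrator_limit(self):
        """With g_Na = g_K = 0 the membrane relaxes exponentially to E_L."""
        p = NeuronParams(g_Na=0.0, g_K=0.0, g_L=0.1)
        tau_m = p.C_m / p.g_L  # 10 ms
        v0, dt, T = -75.0, 0.01, 20.0
        st = steady_state(v0)
        y = np.array([v0, float(st.n), float(st.h)])

        def f(yv):
            d = membrane_derivative(NeuronState(*yv), 0.0, 0.0, p)
            return np.array([d.V, d.n, d.h])

        for _ in range(int(T / dt)):
            y = heun_step(y, dt, f)
        expected = p.E_L + (v0 - p.E_L) * np.exp(-T / tau_m)
        assert y[0] == pytest.approx(expected, abs=1e-3)

    def test_resting_fixed_point_has_zero_derivatives(self):
        rest = _resting_potential(EXC_NEURON)
        d = membrane_derivative(steady_state(rest), 0.0, 0.0, EXC_NEURON)
        assert abs(d.V) < 1e-8
        assert abs(float(np.asarray(d.n))) < 1e-12
        assert abs(float(np.asarray(d.h))) < 1e-12

    def test_fi_curve_monotone(self):
        """Constant suprathreshold drive produces repetitive spiking with a
        firing rate increasing in the drive (brute-force integration)."""
        rates = []
        for i_ext in (0.6, 1.2, 2.4):
            st = steady_state(-64.0)
            y = np.array([-64.0, float(st.n), float(st.h)])
            dt, n_spikes, v_prev = 0.05, 0, y[0]

            def f(yv):
                d = membrane_derivative(NeuronState(*yv), 0.0, i_ext, EXC_NEURON)
                return np.array([d.V, d.n, d.h])

            for _ in range(int(600.0 / dt)):
                y = heun_step(y, dt, f)
                if v_prev < 0.0 <= y[0]:
                    n_spikes += 1
                v_prev = y[0]
            rates.append(n_spikes)
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]

    def test_invariants_of_default_parameters(self):
        for p in (EXC_NEURON, INH_NEURON):
            assert p.E_Na > p.E_L > p.E_K
        assert INH_NEURON.C_m < EXC_NEURON.C_m  # fast-spiking inhibitory cells

    def test_bad_reversal_ordering_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(E_Na=-100.0, E_K=50.0)


class TestSynapse:
    def test_kernel_zero_at_spike_time(self):
        assert synaptic_kernel(0.0, AMPA) == pytest.approx(0.0)

    @pytest.mark.parametrize("sp", [AMPA, GABA_A])
    def test_kernel_argmax_matches_closed_form(self, sp):
        t_peak = kernel_peak_time(sp.tau_r, sp.tau_d)
        res = minimize_scalar(
            lambda t: -synaptic_kernel(t, sp), bounds=(0.0, 20.0 * sp.tau_d), method="bounded"
        )
        assert res.x == pytest.approx(t_peak, abs=1e-5)
        # peak normalization: maximum equals g_max
        assert synaptic_kernel(t_peak, sp) == pytest.approx(sp.g_max, rel=1e-12)

    def test_kernel_integral_analytic(self):
        t = np.linspace(0.0, 200.0, 400001)
        num = np.trapezoid(synaptic_kernel(t, GABA_A), t)
        analytic = GABA_A.g_max * GABA_A.norm_c * (GABA_A.tau_d - GABA_A.tau_r)
        assert num == pytest.approx(analytic, rel=1e-6)

    def test_two_spike_superposition_of_state_representation(self):
        """The dual-exponential state pair (one rising, one decaying variable,
        incremented at each spike) reproduces the summed kernels of two
        spikes: conductance linearity."""
        sp = AMPA
        dt, d = 0.001, 5.0
        n = int(20.0 / dt)
        xd = xr = 0.0
        inc = sp.g_max * sp.norm_c
        g_sim = np.empty(n)
        for i in range(n):
            t = i * dt
            if abs(t - 0.0) < dt / 2 or abs(t - d) < dt / 2:
                xd += inc
                xr += inc
            g_sim[i] = xd - xr
            xd *= np.exp(-dt / sp.tau_d)
            xr *= np.exp(-dt / sp.tau_r)
        t = np.arange(n) * dt
        expected = synaptic_kernel(t, sp) + np.where(
            t >= d, synaptic_kernel(np.maximum(t - d, 0.0), sp), 0.0
        )
        np.testing.assert_allclose(g_sim, expected, atol=1e-8)

    def test_current_sign_convention(self):
        assert synaptic_current(1.0, AMPA.E_syn, AMPA.E_syn) == 0.0
        assert synaptic_current(0.5, -65.0, AMPA.E_syn) > 0  # depolarizing
        assert synaptic_current(0.5, -65.0, GABA_A.E_syn) < 0  # hyperpolarizing

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(tau_r=3.0, tau_d=2.0, g_max=1.0, E_syn=0.0)

    def test_gaba_stronger_than_ampa_default(self):
        # E/I balance against the 4:1 excitatory majority requires stronger
        # inhibitory conductance; enforced on the shipped defaults
        from ctcsim.pipeline import default_config

        cfg = default_config()
        assert cfg.g_inh > cfg.g_exc


class TestHeun:
    def test_identity_with_zero_drift(self):
        y = np.array([1.0, -2.0, 3.0])
        out = heun_step(y, 0.1, lambda v: np.zeros_like(v))
        np.testing.assert_array_equal(out, y)

    def test_second_order_convergence_exponential_decay(self):
        errs = []
        for dt in (0.1, 0.05):
            y, t = np.array([1.0]), 0.0
            while t < 1.0 - 1e-12:
                y = heun_step(y, dt, lambda v: -v)
                t += dt
            errs.append(abs(y[0] - np.exp(-1.0)))
        ratio = errs[0] / errs[1]
        assert 3.5 < ratio < 4.5

    def test_linear_system_matches_matrix_exponential(self):
        A = np.array([[-0.5, 1.0], [-1.0, -0.5]])
        y = np.array([1.0, 0.0])
        dt, T = 0.001, 2.0
        for _ in range(int(T / dt)):
            y = heun_step(y, dt, lambda v: A @ v)
        np.testing.assert_allclose(y, expm(A * T) @ np.array([1.0, 0.0]), atol=1e-6)

    def test_nan_state_raises_with_component(self):
        with pytest.raises(IntegrationError, match="component"):
            heun_step(np.array([1.0, 1.0]), 0.1, lambda v: np.array([np.inf, 0.0]))

    def test_gating_variables_stay_in_unit_interval(self):
        """Driven hard for 100 ms at the default step, n and h remain in [0,1]."""
        st = steady_state(-64.0)
        y = np.array([-64.0, float(st.n), float(st.h)])

        def f(yv):
            d = membrane_derivative(NeuronState(*yv), 0.0, 5.0, EXC_NEURON)
            return np.array([d.V, d.n, d.h])

        for _ in range(int(100.0 / 0.05)):
            y = heun_step(y, 0.05, f)
            assert 0.0 <= y[1] <= 1.0 and 0.0 <= y[2] <= 1.0
            assert -100.0 < y[0] < 60.0
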