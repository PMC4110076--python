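"""Single-neuron Hodgkin–Huxley dynamics, synapse kinetics and the Heun integrator.

The membrane model is a single-compartment Hodgkin–Huxley neuron with
Traub–Miles-type Na/K kinetics, in which the fast sodium activation gate
``m`` is replaced by its voltage-dependent steady state ``m_inf(V)``.  The
state of a neuron is therefore ``(V, n, h)``:

    C_m dV/dt = -g_Na m_inf(V)^3 h (V - E_Na) - g_K n^4 (V - E_K)
                - g_L (V - E_L) + I_syn + I_ext
    dn/dt     = alpha_n(V) (1 - n) - beta_n(V) n
    dh/dt     = alpha_h(V) (1 - h) - beta_h(V) h

Synaptic conductances follow a difference-of-exponentials kernel

    g(t) = g_max * norm_c * (exp(-t/tau_d) - exp(-t/tau_r)),

with ``norm_c`` chosen so that the kernel peak equals ``g_max``; the synaptic
current is ``I = g (E_syn - V)``.

Units follow the usual conductance-based conventions: mV, ms, mS/cm²,
µF/cm², µA/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, NamedTuple

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "GatingRates",
    "SynapseParams",
    "EXC_NEURON",
    "INH_NEURON",
    "AMPA",
    "GABA_A",
    "gating_rates",
    "m_inf",
    "steady_state",
    "membrane_derivative",
    "synaptic_kernel",
    "kernel_peak_time",
    "dual_exp_norm",
    "synaptic_current",
    "heun_step",
    "calibrate_peak_conductance",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of a conductance-based neuron.

    Capacitance ``C_m`` is in µF/cm², maximal conductances in mS/cm² and
    reversal potentials in mV.  Fast-spiking (inhibitory) neurons are modelled
    with a smaller membrane capacitance than excitatory (regular) cells.
    """

    C_m: float = 1.0
    g_Na: float = 35.0
    g_K: float = 9.0
    g_L: float = 0.1
    E_Na: float = 55.0
    E_K: float = -90.0
    E_L: float = -65.0

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.E_Na > self.E_L > self.E_K):
            raise ValueError("require E_Na > E_L > E_K")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")


#: Regular-spiking excitatory cell.
EXC_NEURON = NeuronParams(C_m=1.0)
#: Fast-spiking inhibitory cell: smaller capacitance, hence faster membrane.
INH_NEURON = NeuronParams(C_m=0.5)


@dataclass
class NeuronState:
    """Dynamical state ``(V, n, h)``; each field may be scalar or array."""

    V: np.ndarray | float
    n: np.ndarray | float
    h: np.ndarray | float

    def as_array(self) -> np.ndarray:
        return np.stack([np.asarray(self.V, float), np.asarray(self.n, float), np.asarray(self.h, float)])


class GatingRates(NamedTuple):
    """Voltage-dependent channel transition rates (1/ms)."""

    alpha_n: np.ndarray | float
    beta_n: np.ndarray | float
    alpha_m: np.ndarray | float
    beta_m: np.ndarray | float
    alpha_h: np.ndarray | float
    beta_h: np.ndarray | float


def _linexp(x, a):
    """``x / (1 - exp(-x/a))`` with the removable singularity at ``x = 0``.

    The limit as x -> 0 is ``a`` (L'Hôpital); near zero the series
    ``a + x/2 + O(x²)`` is used to avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7 * a
    safe = np.where(small, 1.0, x)
    out = np.where(small, a + x / 2.0, safe / (1.0 - np.exp(-safe / a)))
    return out if out.ndim else float(out)


def gating_rates(V) -> GatingRates:
    """Wang–Buzsáki-type transition rates for the ``n``, ``m`` and ``h`` gates
    (Traub–Miles-derived kinetics with the temperature factor folded in).

    Parameters
    ----------
    V : float or array
        Membrane voltage in mV.  Must be finite.

    Returns
    -------
    GatingRates
        Six non-negative rates in 1/ms.  Expressions of the form
        ``x / (1 - exp(-x/a))`` are evaluated by their analytic limit at the
        singular point.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane voltage must be finite")
    alpha_n = 0.05 * _linexp(V + 34.0, 10.0)
    beta_n = 0.625 * np.exp(-(V + 44.0) / 80.0)
    alpha_m = 0.1 * _linexp(V + 35.0, 10.0)
    beta_m = 4.0 * np.exp(-(V + 60.0) / 18.0)
    alpha_h = 0.35 * np.exp(-(V + 58.0) / 20.0)
    beta_h = 5.0 / (1.0 + np.exp(-(V + 28.0) / 10.0))
    return GatingRates(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)


def m_inf(V):
    """Steady-state sodium activation ``alpha_m / (alpha_m + beta_m)``.

    Monotonically increasing sigmoid of V, bounded in [0, 1].  The fast
    ``m`` gate is slaved to this steady state throughout the model.
    """
    r = gating_rates(V)
    return r.alpha_m / (r.alpha_m + r.beta_m)


def steady_state(V) -> NeuronState:
    """Resting gating values ``n_inf, h_inf`` for a (possibly array) voltage."""
    r = gating_rates(V)
    n = r.alpha_n / (r.alpha_n + r.beta_n)
    h = r.alpha_h / (r.alpha_h + r.beta_h)
    return NeuronState(V=np.asarray(V, float), n=n, h=h)


def membrane_derivative(
    state: NeuronState,
    I_syn: np.ndarray | float,
    I_ext: np.ndarray | float,
    p: NeuronParams,
) -> NeuronState:
    """Right-hand side of the membrane and gating equations.

    ``I_syn`` and ``I_ext`` are total currents in µA/cm² (positive =
    depolarizing).  Returns the time derivatives packaged as a
    :class:`NeuronState` (dV/dt in mV/ms, gate derivatives in 1/ms).
    """
    V = np.asarray(state.V, float)
    n = np.asarray(state.n, float)
    h = np.asarray(state.h, float)
    r = gating_rates(V)
    m = r.alpha_m / (r.alpha_m + r.beta_m)
    I_ion = (
        -p.g_Na * m**3 * h * (V - p.E_Na)
        - p.g_K * n**4 * (V - p.E_K)
        - p.g_L * (V - p.E_L)
    )
    dV = (I_ion + np.asarray(I_syn, float) + np.asarray(I_ext, float)) / p.C_m
    dn = r.alpha_n * (1.0 - n) - r.beta_n * n
    dh = r.alpha_h * (1.0 - h) - r.beta_h * h
    return NeuronState(V=dV, n=dn, h=dh)


@dataclass(frozen=True)
class SynapseParams:
    """Dual-exponential synapse: rise/decay times (ms), peak conductance
    scale ``g_max`` (mS/cm²) and reversal potential ``E_syn`` (mV).

    ``norm_c`` normalizes the kernel so its maximum equals ``g_max``; it is
    computed from the time constants unless given explicitly.
    """

    tau_r: float
    tau_d: float
    g_max: float
    E_syn: float
    norm_c: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("require tau_d > tau_r > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.norm_c is None:
            object.__setattr__(self, "norm_c", dual_exp_norm(self.tau_r, self.tau_d))


def kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """Time of the kernel maximum: ``tau_r tau_d / (tau_d - tau_r) * ln(tau_d/tau_r)``."""
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def dual_exp_norm(tau_r: float, tau_d: float) -> float:
    """Normalization constant making the dual-exponential peak equal one."""
    tp = kernel_peak_time(tau_r, tau_d)
    return 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))


# Default synapse classes.  The GABA_A decay constant sets the period of the
# collective gamma rhythm; its peak conductance exceeds the AMPA one so that
# recurrent inhibition balances the larger excitatory population.
AMPA = SynapseParams(tau_r=0.5, tau_d=2.0, g_max=1.0, E_syn=0.0)
GABA_A = SynapseParams(tau_r=0.5, tau_d=8.0, g_max=1.0, E_syn=-80.0)


def synaptic_kernel(t_since_spike, sp: SynapseParams):
    """Conductance ``t`` ms after a presynaptic spike.

    ``g(t) = g_max * norm_c * (exp(-t/tau_d) - exp(-t/tau_r))``; zero at the
    spike time and for negative lags, decaying to zero as t -> infinity.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    g = sp.g_max * sp.norm_c * (np.exp(-t / sp.tau_d) - np.exp(-t / sp.tau_r))
    return g if g.ndim else float(g)


def synaptic_current(g, V, E_syn):
    """Ohmic synaptic current ``I = g (E_syn - V)``; depolarizing when E_syn > V."""
    g = np.asarray(g, float)
    if np.any(g < 0):
        raise ValueError("conductance must be non-negative")
    out = g * (np.asarray(E_syn, float) - np.asarray(V, float))
    return out if out.ndim else float(out)


def heun_step(
    y: np.ndarray,
    dt: float,
    drift: Callable[[np.ndarray], np.ndarray],
    xi: np.ndarray | None = None,
) -> np.ndarray:
    """One predictor–corrector (Heun / stochastic Heun) step.

    ``y' = y + dt*f(y) + xi``;  ``y_next = y + dt/2*(f(y) + f(y')) + xi``,
    where ``xi`` is an optional additive noise increment (already scaled by
    ``sigma * sqrt(dt)``).  For smooth deterministic drift the scheme is
    second-order accurate; for additive-noise SDEs it is the standard Heun
    scheme for the Ornstein–Uhlenbeck process.

    Raises :class:`IntegrationError` if the step produces a non-finite state,
    reporting the first offending component.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(y, dtype=float)
    f0 = np.asarray(drift(y), dtype=float)
    pred = y + dt * f0 if xi is None else y + dt * f0 + xi
    f1 = np.asarray(drift(pred), dtype=float)
    out = y + 0.5 * dt * (f0 + f1)
    if xi is not None:
        out = out + xi
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(out)))[0])
        raise IntegrationError(f"non-finite state at component {bad} after Heun step")
    return out


def calibrate_peak_conductance(
    target_psp_mv: float,
    sp: SynapseParams,
    p: NeuronParams = EXC_NEURON,
    dt: float = 0.01,
    t_max: float = 60.0,
) -> float:
    """Scale ``g_max`` so a unitary synaptic event deflects the resting
    membrane by ``target_psp_mv`` (absolute peak deflection, mV).

    Integrates the full membrane response to a single kernel activation at
    rest and rescales by the (nearly linear for small PSPs) measured peak.
    Returns the calibrated ``g_max``.
    """
    if target_psp_mv <= 0:
        raise ValueError("target PSP amplitude must be positive")
    rest = _resting_potential(p)
    st = steady_state(rest)
    y = np.array([rest, float(st.n), float(st.h)])

    def drift_at(t: float):
        g = synaptic_kernel(t, sp)

        def f(yv):
            s = NeuronState(V=yv[0], n=yv[1], h=yv[2])
            d = membrane_derivative(s, synaptic_current(g, yv[0], sp.E_syn), 0.0, p)
            return np.array([d.V, d.n, d.h])

        return f

    peak = 0.0
    t = 0.0
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        y = heun_step(y, dt, drift_at(t + 0.5 * dt))
        t += dt
        peak = max(peak, abs(y[0] - rest))
    if peak == 0:
        raise RuntimeError("no deflection measured; cannot calibrate")
    return sp.g_max * target_psp_mv / peak


def _resting_potential(p: NeuronParams, v_lo: float = -90.0, v_hi: float = -58.0) -> float:
    """Resting fixed point: zero of the steady-state current in [v_lo, v_hi]."""
    from scipy.optimize import brentq

    def i_ss(V):
        s = steady_state(V)
        d = membrane_derivative(s, 0.0, 0.0, p)
        return d.V

    return float(brentq(i_ss, v_lo, v_hi))
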