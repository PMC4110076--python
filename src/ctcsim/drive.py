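"""External background drive and stimulation.

Every neuron receives an excitatory Poisson spike train whose instantaneous
rate nu(t) follows an Ornstein–Uhlenbeck (OU) process

    d nu = -(nu - nu0) / tau_ou dt + sigma sqrt(2 / tau_ou) xi(t),

so the stationary mean is ``nu0`` and the stationary standard deviation is
``sigma``; the rate spectrum is flat up to the cut-off frequency
``f_c = 1/(2 pi tau_ou)`` and falls off as a Lorentzian above it.  By default
one OU trace is shared by all neurons of a population (a common rate
fluctuation) while the Poisson thinning is independent per neuron; an
independent-per-neuron OU mode is available as a switch.

Stimuli are step increments of the mean rate applied to a subset of the
long-range projecting excitatory neurons of the emitter population during a
fixed time window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OUParams",
    "StimulusProtocol",
    "PopulationDrive",
    "ou_rate_trace",
    "poisson_spikes",
    "apply_stimulus",
]


@dataclass(frozen=True)
class OUParams:
    """OU rate-process parameters: mean ``nu0`` and std ``sigma`` in
    spikes/s, correlation time ``tau_ou`` in ms."""

    nu0: float = 1500.0
    sigma: float = 400.0
    tau_ou: float = 16.0
    clip_at_zero: bool = True
    independent: bool = False

    def __post_init__(self) -> None:
        if self.nu0 <= 0 or self.sigma < 0 or self.tau_ou <= 0:
            raise ValueError("require nu0 > 0, sigma >= 0, tau_ou > 0")

    @property
    def cutoff_hz(self) -> float:
        return 1000.0 / (2.0 * np.pi * self.tau_ou)


@dataclass(frozen=True)
class StimulusProtocol:
    """Set of external rate increments (spikes/s) applied to
    ``n_target_neurons`` projecting excitatory emitter neurons inside
    ``window`` (seconds)."""

    rate_increments: tuple[float, ...]
    n_target_neurons: int
    window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        incs = self.rate_increments
        if len(set(incs)) != len(incs) or any(x < 0 for x in incs):
            raise ValueError("rate increments must be distinct and non-negative")
        if self.window[1] <= self.window[0]:
            raise ValueError("stimulus window must have positive length")

    @property
    def n_stimuli(self) -> int:
        return len(self.rate_increments)

    @classmethod
    def uniform(cls, n_stimuli: int = 7, max_increment: float = 1200.0,
                n_target_neurons: int = 300, window: tuple[float, float] = (0.0, 1.0)):
        """Evenly spaced increments from 0 to ``max_increment``."""
        incs = tuple(np.linspace(0.0, max_increment, n_stimuli))
        return cls(rate_increments=incs, n_target_neurons=n_target_neurons, window=window)


@dataclass
class PopulationDrive:
    """Concrete drive for one population and one trial.

    ``rate`` is the shared OU rate trace (spikes/s, one value per integration
    step).  The stimulus fields describe an additive rate step of
    ``stim_delta`` spikes/s for the neurons in ``stim_targets`` between
    integration steps ``stim_window_steps``.
    """

    rate: np.ndarray
    dt: float
    stim_targets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    stim_delta: float = 0.0
    stim_window_steps: tuple[int, int] = (0, 0)


def ou_rate_trace(p: OUParams, dt: float, T: float, seed: int) -> np.ndarray:
    """Stationary OU rate trace sampled every ``dt`` ms for ``T`` seconds.

    Integrated with the stochastic Heun scheme (matching the network
    integrator).  The initial value is drawn from the stationary law, so the
    whole trace is stationary.  Negative excursions are clipped at zero when
    ``clip_at_zero`` is set; clip events are logged.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("require T > 0 and dt > 0")
    n = int(round(T * 1000.0 / dt))
    rng = np.random.default_rng(seed)
    if p.sigma == 0:
        return np.full(n, p.nu0)
    out = np.empty(n)
    x = p.nu0 + p.sigma * rng.standard_normal()
    amp = p.sigma * np.sqrt(2.0 * dt / p.tau_ou)
    a = dt / p.tau_ou
    for i in range(n):
        xi = amp * rng.standard_normal()
        # Heun for linear drift f(x) = -(x - nu0)/tau
        pred = x - a * (x - p.nu0) + xi
        x = x - 0.5 * a * ((x - p.nu0) + (pred - p.nu0)) + xi
        out[i] = x
    if p.clip_at_zero:
        n_clip = int(np.sum(out < 0))
        if n_clip:
            logger.info("OU rate clipped at zero in %d of %d steps", n_clip, n)
        np.clip(out, 0.0, None, out=out)
    return out


def poisson_spikes(rate: np.ndarray, dt: float, seed: int) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms) by per-bin thinning.

    Each bin of width ``dt`` ms emits at most one spike with probability
    ``nu(t) * dt``; raises if any bin probability reaches 1 (the time step is
    then too coarse for the requested rate).
    """
    rate = np.asarray(rate, float)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    prob = rate * dt * 1e-3  # rate in spikes/s, dt in ms
    if np.any(prob >= 1.0):
        raise ValueError("nu*dt >= 1 in at least one bin: decrease dt")
    rng = np.random.default_rng(seed)
    hits = rng.random(len(rate)) < prob
    return np.flatnonzero(hits) * dt


def apply_stimulus(
    base: PopulationDrive,
    proto: StimulusProtocol,
    s: int,
    seed: int,
    projecting_exc: np.ndarray | None = None,
) -> PopulationDrive:
    """Select stimulated emitter neurons and attach increment ``s`` to the drive.

    ``projecting_exc`` are the indices of long-range projecting excitatory
    neurons eligible for stimulation; ``n_target_neurons`` of them are chosen
    (reproducibly for a given seed).  Outside the stimulus window, and for a
    zero increment, the drive is unchanged.
    """
    if not (0 <= s < proto.n_stimuli):
        raise IndexError(f"stimulus index {s} outside protocol of size {proto.n_stimuli}")
    delta = float(proto.rate_increments[s])
    n_steps = len(base.rate)
    i_on = int(round(proto.window[0] * 1000.0 / base.dt))
    i_off = int(round(proto.window[1] * 1000.0 / base.dt))
    i_on, i_off = max(0, i_on), min(n_steps, i_off)
    if i_off <= i_on or delta == 0.0:
        return replace(base)
    if projecting_exc is None or len(projecting_exc) == 0:
        raise ValueError("stimulation requires the set of projecting excitatory neurons")
    if proto.n_target_neurons > len(projecting_exc):
        raise ValueError(
            f"cannot stimulate {proto.n_target_neurons} neurons: only "
            f"{len(projecting_exc)} projecting excitatory neurons available"
        )
    rng = np.random.default_rng(seed)
    targets = np.sort(rng.permutation(np.asarray(projecting_exc))[: proto.n_target_neurons])
    return replace(
        base,
        stim_targets=targets.astype(np.int64),
        stim_delta=delta,
        stim_window_steps=(i_on, i_off),
    )
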