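"""Surrogate generators emulating the statistical structure the analysis
modules assume, so the spectral and information estimators can be validated
without running the network simulator.

Three families are provided:

* paired oscillatory LFP-like signals with a controlled dominant frequency,
  phase lag and expected phase coherence (``surrogate_coherent_pair``);
* per-stimulus log-normal power samples with analytically known binned
  mutual information (``surrogate_power_channel``);
* miniature network configurations for fast simulator tests
  (``fixture_network``).

The coherent pairs are built from narrowband Gaussian processes: a complex
Ornstein–Uhlenbeck envelope modulating a carrier at ``f0`` (the envelope
diffusion mimics the finite self-coherence of network gamma).  Mixing a
shared and an independent narrowband component with weights sqrt(g) and
sqrt(1-g) makes the pair jointly Gaussian at each frequency bin with
spectral coherence g there, and for jointly Gaussian signals the expected
resultant length of cross-spectrum phase estimates is the closed form

    R(g) = (pi/4) g 2F1(1/2, 1/2; 2; g^2),

which is inverted to hit a requested ``coherence_level``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import hyp2f1
from scipy.stats import norm

from .infotheory import PowerSampleSet
from .observables import SignalTrace

__all__ = [
    "SurrogateSpec",
    "surrogate_coherent_pair",
    "expected_resultant",
    "coherence_to_mixing",
    "LogNormalChannel",
    "surrogate_power_channel",
    "fixture_network",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Construction parameters for a coherent LFP-like surrogate pair."""

    f0: float = 50.0
    phase_lag: float = 0.0
    coherence_level: float = 1.0
    noise_floor: float = 1e-3  # white-noise std relative to unit signal std
    n_trials: int = 10
    fs: float = 1000.0
    duration: float = 4.0  # s per trial
    envelope_tau: float = 200.0  # ms; slower -> narrower gamma line

    def __post_init__(self) -> None:
        if not (0 < self.f0 < self.fs / 2):
            raise ValueError("f0 must lie below Nyquist")
        if not (0 <= self.coherence_level <= 1):
            raise ValueError("coherence_level must lie in [0, 1]")


def expected_resultant(g: float) -> float:
    """Expected phase-coherence estimate (K -> inf) for jointly Gaussian
    signals with spectral coherence ``g`` at the analysed bin."""
    if g >= 1.0:
        return 1.0
    return float(np.pi / 4.0 * g * hyp2f1(0.5, 0.5, 2.0, g * g))


def coherence_to_mixing(level: float) -> float:
    """Invert ``expected_resultant``: mixing weight g giving the requested
    asymptotic coherence estimate."""
    if level <= 0.0:
        return 0.0
    if level >= 1.0:
        return 1.0
    return float(brentq(lambda g: expected_resultant(g) - level, 0.0, 1.0))


def _narrowband(n: int, fs: float, f0: float, tau_ms: float, rng) -> np.ndarray:
    """Unit-variance narrowband Gaussian process: complex-OU envelope times
    a carrier at f0."""
    dt = 1000.0 / fs
    rho = np.exp(-dt / tau_ms)
    drive = np.sqrt((1.0 - rho * rho) / 2.0)
    a = np.empty(n, dtype=complex)
    a[0] = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
    eps = drive * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    for t in range(1, n):
        a[t] = rho * a[t - 1] + eps[t]
    carrier = np.exp(2j * np.pi * f0 * np.arange(n) / fs)
    # Re[a e^{iwt}] with E|a|^2 = 1 has variance 1/2; rescale to unit variance
    return np.sqrt(2.0) * np.real(a * carrier)


def surrogate_coherent_pair(
    spec: SurrogateSpec, seed: int
) -> tuple[list[SignalTrace], list[SignalTrace]]:
    """Trials of paired narrowband-plus-noise signals.

    The first signal leads the second by ``phase_lag`` radians at ``f0``; the
    expected coherence estimate at ``f0`` equals ``coherence_level`` (up to
    the small positive finite-K bias and the noise floor).
    """
    g = coherence_to_mixing(spec.coherence_level)
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    lag_rot = np.exp(-1j * spec.phase_lag)
    for _ in range(spec.n_trials):
        # shared component, generated as analytic envelope so the y copy can
        # be rotated by the phase lag exactly
        dt = 1000.0 / spec.fs
        rho = np.exp(-dt / spec.envelope_tau)
        drive = np.sqrt((1.0 - rho * rho) / 2.0)
        a = np.empty(n, dtype=complex)
        a[0] = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
        eps = drive * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        for t in range(1, n):
            a[t] = rho * a[t - 1] + eps[t]
        carrier = np.exp(2j * np.pi * spec.f0 * np.arange(n) / spec.fs)
        shared_x = np.sqrt(2.0) * np.real(a * carrier)
        shared_y = np.sqrt(2.0) * np.real(a * carrier * lag_rot)

        ind_x = _narrowband(n, spec.fs, spec.f0, spec.envelope_tau, rng)
        ind_y = _narrowband(n, spec.fs, spec.f0, spec.envelope_tau, rng)
        x = np.sqrt(g) * shared_x + np.sqrt(1.0 - g) * ind_x
        y = np.sqrt(g) * shared_y + np.sqrt(1.0 - g) * ind_y
        x = x + spec.noise_floor * rng.standard_normal(n)
        y = y + spec.noise_floor * rng.standard_normal(n)
        xs.append(SignalTrace(values=x, fs=spec.fs, kind="LFP", population="a"))
        ys.append(SignalTrace(values=y, fs=spec.fs, kind="LFP", population="b"))
    return xs, ys


@dataclass
class LogNormalChannel:
    """Known stimulus->power channel: log10-power of stimulus s at frequency
    index j is Normal(mu[s, j], sigma^2)."""

    freqs: np.ndarray
    mu: np.ndarray  # (n_stimuli, n_freqs)
    sigma: float

    def bin_probs(self, j: int, edges: np.ndarray) -> np.ndarray:
        """P(bin | s) for log-power bin edges at frequency index j."""
        edges = np.asarray(edges, float)
        cuts = np.concatenate([[-np.inf], edges, [np.inf]])
        cdf = norm.cdf((cuts[None, :] - self.mu[:, j, None]) / self.sigma)
        return np.diff(cdf, axis=1)

    def exact_mi(self, j: int, edges: np.ndarray) -> float:
        """Exact binned MI (bits) by integration over the known densities."""
        p_rs = self.bin_probs(j, edges)  # (S, B)
        S = p_rs.shape[0]
        p_r = p_rs.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p_rs > 0, p_rs * np.log2(p_rs / np.where(p_r > 0, p_r, 1.0)), 0.0)
        return float(terms.sum() / S)


def surrogate_power_channel(
    n_stimuli: int,
    effect_profile: np.ndarray,
    noise: float,
    n_trials: int,
    seed: int,
    freqs: np.ndarray | None = None,
) -> tuple[PowerSampleSet, LogNormalChannel]:
    """Per-stimulus log-normal power samples with a known effect profile.

    At frequency ``f`` the median log10-power shifts by
    ``effect_profile[f] * s`` for stimulus index ``s``; ``noise`` is the
    log10-power standard deviation.  Returns the sampled power values (on
    the natural power scale; the analysis bins are rank-based, so the scale
    is irrelevant) together with the generating channel, whose exact binned
    MI is computable for any edges.
    """
    if n_stimuli < 2:
        raise ValueError("need at least two stimuli")
    effect = np.asarray(effect_profile, float)
    if freqs is None:
        freqs = np.arange(len(effect), dtype=float)
    if noise < 0:
        raise ValueError("noise must be non-negative")
    mu = np.outer(np.arange(n_stimuli), effect)  # baseline 0 + shift*s
    rng = np.random.default_rng(seed)
    samples = []
    sigma = max(noise, 1e-12)
    for s in range(n_stimuli):
        logp = mu[s][None, :] + noise * rng.standard_normal((n_trials, len(effect)))
        samples.append(10.0 ** logp)
    channel = LogNormalChannel(freqs=np.asarray(freqs, float), mu=mu, sigma=sigma)
    return PowerSampleSet(freqs=freqs, samples=samples), channel


def fixture_network(scale: str = "small"):
    """Reduced two-population configurations for fast end-to-end tests.

    ``tiny``: 2 x 100 neurons, 1 s — smoke tests.  ``small``: 2 x 400
    neurons, 2 s — regime tests (gamma peak, coherence transitions).  The
    parameter profile is the full-scale default with degrees scaled down
    proportionally to population size (per-edge conductances are rescaled
    automatically by the configuration to preserve total synaptic drive).
    """
    from .pipeline import default_config
    from dataclasses import replace

    cfg = default_config()
    if scale == "tiny":
        return replace(cfg, N=100, mean_degree=20, duration=1.0)
    if scale == "small":
        # degree is reduced less than proportionally: collective gamma needs
        # enough synaptic convergence per neuron to survive the small size
        return replace(cfg, N=400, mean_degree=80, duration=2.0)
    raise ValueError("scale must be 'tiny' or 'small'")
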