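"""Time-stepped co-simulation of two delay-coupled populations.

A trial draws fresh connectivity, initial conditions and noise from its
seed, integrates both populations with the Heun scheme, and returns a
:class:`SimulationRecord` holding the spike raster and the population-summed
synaptic current traces onto excitatory cells (the ingredients of the LFP).

Spikes are detected as upward threshold crossings (0 mV) under a refractory
lockout, and each spike is enqueued onto every outgoing edge with that
edge's conduction delay, rounded to integration steps (ties round up, with a
one-step minimum so delivery is always strictly causal).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import _kernel
from .drive import OUParams, PopulationDrive, StimulusProtocol, apply_stimulus, ou_rate_trace
from .model_core import AMPA, GABA_A, EXC_NEURON, INH_NEURON, IntegrationError, SynapseParams, steady_state
from .network import CouplingSpec, InterEdges, NetworkSpec, build_inter_coupling, build_population

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulationRecord", "run_trial", "run_experiment"]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a two-population experiment.

    Per-edge peak conductances (``g_exc``, ``g_inh``, ``g_ext``, ``g_inter``,
    mS/cm²) are given at the reference in-degree ``reference_degree``; when
    ``mean_degree`` differs (scaled-down fixtures) the recurrent and
    inter-areal weights are rescaled by ``reference_degree / mean_degree`` so
    the total synaptic conductance per neuron is preserved.
    """

    N: int = 2000
    mean_degree: int = 100
    rewiring_p: float = 0.3
    frac_exc: float = 0.8
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    ou: OUParams = field(default_factory=OUParams)
    stimulus: StimulusProtocol | None = None
    dt: float = 0.05  # ms
    duration: float = 2.0  # s, excluding warm-up
    warmup: float = 0.2  # s
    record_fs: float = 1000.0  # Hz
    ampa: SynapseParams = AMPA
    gaba: SynapseParams = GABA_A
    g_exc: float = 0.002
    g_inh: float = 0.02
    g_ext: float = 0.006
    g_inter: float = 0.004
    reference_degree: int = 100
    v_thresh: float = 0.0
    refractory: float = 2.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        stride = 1000.0 / (self.record_fs * self.dt)
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("dt must divide the recording interval")
        if self.duration <= 0 or self.warmup < 0:
            raise ValueError("invalid duration/warmup")

    @property
    def record_stride(self) -> int:
        return int(round(1000.0 / (self.record_fs * self.dt)))

    @property
    def degree_scale(self) -> float:
        return self.reference_degree / self.mean_degree

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimulus"] = None if self.stimulus is None else asdict(self.stimulus)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


@dataclass
class SimulationRecord:
    """One trial's output: spikes, LFP-ingredient current traces, metadata.

    ``i_exc_*`` / ``i_inh_*`` are the absolute excitatory / inhibitory
    synaptic currents averaged over the excitatory neurons of each
    population (µA/cm²), sampled at ``fs`` after the warm-up.  Spike times
    are in ms from simulation start (warm-up included).
    """

    spike_times: np.ndarray
    spike_neurons: np.ndarray
    n_a: int
    n_b: int
    exc_mask: np.ndarray
    i_exc_a: np.ndarray
    i_inh_a: np.ndarray
    i_exc_b: np.ndarray
    i_inh_b: np.ndarray
    v_probe: np.ndarray
    fs: float
    dt: float
    warmup: float
    duration: float
    tau_inter: float
    stimulus_index: int | None
    config_hash: str
    seed: int

    def population_spikes(self, pop: str, post_warmup: bool = True):
        """Spike (times_ms, neuron_ids) of population 'a' or 'b'."""
        if pop == "a":
            sel = self.spike_neurons < self.n_a
            neurons = self.spike_neurons[sel]
        elif pop == "b":
            sel = self.spike_neurons >= self.n_a
            neurons = self.spike_neurons[sel] - self.n_a
        else:
            raise ValueError("pop must be 'a' or 'b'")
        times = self.spike_times[sel]
        if post_warmup:
            keep = times >= self.warmup * 1000.0
            times, neurons = times[keep], neurons[keep]
        return times, neurons

    def firing_rates(self, pop: str) -> np.ndarray:
        """Mean firing rate per neuron (spikes/s) over the analysis window."""
        times, neurons = self.population_spikes(pop)
        n = self.n_a if pop == "a" else self.n_b
        counts = np.bincount(neurons, minlength=n)
        return counts / self.duration

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("spike_times", "spike_neurons", "exc_mask",
                         "i_exc_a", "i_inh_a", "i_exc_b", "i_inh_b", "v_probe"):
                f.create_dataset(name, data=getattr(self, name))
            for name in ("n_a", "n_b", "fs", "dt", "warmup", "duration",
                         "tau_inter", "config_hash", "seed"):
                f.attrs[name] = getattr(self, name)
            f.attrs["stimulus_index"] = -1 if self.stimulus_index is None else self.stimulus_index

    @classmethod
    def from_hdf5(cls, path) -> "SimulationRecord":
        import h5py

        with h5py.File(path, "r") as f:
            arrays = {
                name: f[name][:]
                for name in ("spike_times", "spike_neurons", "exc_mask",
                             "i_exc_a", "i_inh_a", "i_exc_b", "i_inh_b", "v_probe")
            }
            attrs = {name: f.attrs[name] for name in
                     ("n_a", "n_b", "fs", "dt", "warmup", "duration",
                      "tau_inter", "config_hash", "seed")}
            si = int(f.attrs["stimulus_index"])
        arrays["exc_mask"] = arrays["exc_mask"].astype(bool)
        return cls(
            stimulus_index=None if si < 0 else si,
            n_a=int(attrs.pop("n_a")), n_b=int(attrs.pop("n_b")),
            fs=float(attrs.pop("fs")), dt=float(attrs.pop("dt")),
            warmup=float(attrs.pop("warmup")), duration=float(attrs.pop("duration")),
            tau_inter=float(attrs.pop("tau_inter")),
            config_hash=str(attrs.pop("config_hash")), seed=int(attrs.pop("seed")),
            **arrays,
        )


def _delay_steps(delay_ms: np.ndarray, dt: float) -> np.ndarray:
    """Delays in integration steps: round half up, at least one step."""
    # epsilon guards against 0.075/0.05 = 1.4999... style float artifacts
    return np.maximum(1, np.floor(delay_ms / dt + 0.5 + 1e-9).astype(np.int64))


def _assemble_edges(
    spec_a: NetworkSpec, spec_b: NetworkSpec, inter: InterEdges, cfg: SimulationConfig
):
    """Merge intra- and inter-population edges into one CSR over all neurons."""
    n_a = spec_a.N
    scale = cfg.degree_scale
    w_exc = cfg.g_exc * scale
    w_inh = cfg.g_inh * scale
    w_inter = cfg.g_inter * scale

    pre = np.concatenate([
        spec_a.pre, spec_b.pre + n_a,
        inter.pre_a2b, inter.pre_b2a + n_a,
    ])
    tgt = np.concatenate([
        spec_a.post, spec_b.post + n_a,
        inter.post_a2b + n_a, inter.post_b2a,
    ])
    delay = np.concatenate([spec_a.delay, spec_b.delay, inter.delay_a2b, inter.delay_b2a])
    is_exc_pre = np.concatenate([
        spec_a.edge_is_exc, spec_b.edge_is_exc,
        np.ones(len(inter.pre_a2b), bool), np.ones(len(inter.pre_b2a), bool),
    ])
    weight = np.where(is_exc_pre, w_exc, w_inh)
    n_intra = spec_a.n_edges + spec_b.n_edges
    weight[n_intra:] = w_inter
    is_inh = (~is_exc_pre).astype(np.int64)

    order = np.argsort(pre, kind="stable")
    pre, tgt, delay, weight, is_inh = (a[order] for a in (pre, tgt, delay, weight, is_inh))
    n_total = n_a + spec_b.N
    ptr = np.zeros(n_total + 1, dtype=np.int64)
    np.add.at(ptr[1:], pre, 1)
    np.cumsum(ptr, out=ptr)
    dsteps = _delay_steps(delay, cfg.dt)
    return ptr, tgt.astype(np.int64), dsteps, weight.astype(float), is_inh


def run_trial(
    cfg: SimulationConfig, trial_seed: int, stimulus_index: int | None = None
) -> SimulationRecord:
    """Simulate one trial: fresh connectivity, initial conditions and noise.

    ``trial_seed`` is combined with the config master seed, so two calls with
    identical (config, trial_seed, stimulus_index) produce identical records.
    """
    ss = np.random.SeedSequence([cfg.seed, int(trial_seed)])
    s_net_a, s_net_b, s_inter, s_drive_a, s_drive_b, s_init, s_kernel, s_stim = (
        int(x.generate_state(1)[0] % 2**31) for x in ss.spawn(8)
    )

    spec_a = build_population(cfg.N, cfg.mean_degree, cfg.rewiring_p, cfg.frac_exc, s_net_a)
    spec_b = build_population(cfg.N, cfg.mean_degree, cfg.rewiring_p, cfg.frac_exc, s_net_b)
    inter = build_inter_coupling(spec_a, spec_b, cfg.coupling, s_inter)
    ptr, tgt, dsteps, weight, is_inh = _assemble_edges(spec_a, spec_b, inter, cfg)
    buf_len = int(dsteps.max()) + 1 if len(dsteps) else 2

    total_T = cfg.warmup + cfg.duration
    n_steps = int(round(total_T * 1000.0 / cfg.dt))
    warmup_steps = int(round(cfg.warmup * 1000.0 / cfg.dt))

    rate_a = ou_rate_trace(cfg.ou, cfg.dt, total_T, s_drive_a)
    rate_b = ou_rate_trace(cfg.ou, cfg.dt, total_T, s_drive_b)

    n_total = spec_a.N + spec_b.N
    stim_extra = np.zeros(n_total)
    stim_on, stim_off = 0, 0
    if stimulus_index is not None:
        if cfg.stimulus is None:
            raise ValueError("stimulus_index given but config has no stimulus protocol")
        # stimulation window is expressed relative to the end of the warm-up
        proto = cfg.stimulus
        window = (proto.window[0] + cfg.warmup, proto.window[1] + cfg.warmup)
        drive = PopulationDrive(rate=rate_a, dt=cfg.dt)
        projecting = np.unique(inter.pre_a2b)
        drive = apply_stimulus(
            drive, replace(proto, window=window), stimulus_index, s_stim, projecting_exc=projecting
        )
        stim_extra[drive.stim_targets] = drive.stim_delta
        stim_on, stim_off = drive.stim_window_steps

    exc_mask = np.concatenate([spec_a.exc_mask, spec_b.exc_mask])
    inv_cm = np.where(exc_mask, 1.0 / EXC_NEURON.C_m, 1.0 / INH_NEURON.C_m)

    rng_init = np.random.default_rng(s_init)
    rest = EXC_NEURON.E_L
    v0 = rest + rng_init.uniform(-5.0, 5.0, size=n_total)
    st = steady_state(v0)
    tab = _gating_tables()

    p = EXC_NEURON  # conductances/reversals shared between cell classes
    out = _kernel.run_network(
        n_total, spec_a.N, exc_mask,
        inv_cm,
        p.g_Na, p.g_K, p.g_L, p.E_Na, p.E_K, p.E_L,
        tab,
        cfg.ampa.tau_d, cfg.ampa.tau_r, cfg.ampa.norm_c, cfg.ampa.E_syn,
        cfg.gaba.tau_d, cfg.gaba.tau_r, cfg.gaba.norm_c, cfg.gaba.E_syn,
        ptr, tgt, dsteps, weight, is_inh,
        buf_len,
        rate_a, rate_b,
        cfg.g_ext * 1.0,
        cfg.ou.independent, cfg.ou.nu0, cfg.ou.sigma, cfg.ou.tau_ou,
        stim_extra, stim_on, stim_off,
        cfg.dt, n_steps, cfg.record_stride, warmup_steps,
        cfg.v_thresh, int(round(cfg.refractory / cfg.dt)),
        v0, np.asarray(st.n, float), np.asarray(st.h, float),
        s_kernel,
        int(n_total * total_T * 100) + 10000,
    )
    (sp_step, sp_neuron, ie_a, ii_a, ie_b, ii_b, v_probe, overflow, err_n, err_s) = out
    if err_n >= 0:
        raise IntegrationError(
            f"voltage out of range for neuron {err_n} at t={err_s * cfg.dt:.2f} ms"
        )
    if overflow:
        logger.warning("spike buffer overflow; raster truncated")

    return SimulationRecord(
        spike_times=sp_step * cfg.dt,
        spike_neurons=sp_neuron,
        n_a=spec_a.N, n_b=spec_b.N, exc_mask=exc_mask,
        i_exc_a=ie_a, i_inh_a=ii_a, i_exc_b=ie_b, i_inh_b=ii_b,
        v_probe=v_probe,
        fs=cfg.record_fs, dt=cfg.dt, warmup=cfg.warmup, duration=cfg.duration,
        tau_inter=cfg.coupling.tau_inter,
        stimulus_index=stimulus_index,
        config_hash=cfg.config_hash(),
        seed=int(trial_seed),
    )


_TAB_CACHE: dict[int, np.ndarray] = {}


def _gating_tables() -> np.ndarray:
    if 0 not in _TAB_CACHE:
        _TAB_CACHE[0] = _kernel.build_gating_tables()
    return _TAB_CACHE[0]


def run_experiment(
    cfg: SimulationConfig,
    tau_grid,
    stimulus_set,
    n_trials: int,
    out_dir,
) -> dict:
    """Sweep (tau, stimulus, trial), writing one HDF5 record per grid point.

    Results are written incrementally and the sweep is resumable: records
    already present (per the manifest) are not recomputed, and per-record
    seeds depend only on the grid point, so a resumed sweep produces the
    same records as an uninterrupted one.
    """
    tau_grid = list(tau_grid)
    if len(tau_grid) == 0 or n_trials < 1:
        raise ValueError("empty sweep grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = {"config_hash": cfg.config_hash(), "records": []}
    done = set()
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == manifest["config_hash"]:
            for r in prev["records"]:
                if (out_dir / r["file"]).exists():
                    manifest["records"].append(r)
                    done.add((r["tau"], r["stimulus"], r["trial"]))
        else:
            logger.warning("manifest config hash differs; restarting sweep")

    stimuli = list(stimulus_set) if stimulus_set is not None else [None]
    for tau in tau_grid:
        cfg_tau = replace(cfg, coupling=replace(cfg.coupling, tau_inter=float(tau)))
        for s in stimuli:
            for trial in range(n_trials):
                key = (float(tau), -1 if s is None else int(s), trial)
                if key in done:
                    continue
                trial_seed = _grid_seed(cfg.seed, tau, s, trial)
                rec = run_trial(cfg_tau, trial_seed, stimulus_index=s)
                fname = f"rec_tau{tau:g}_s{-1 if s is None else s}_t{trial}.h5"
                rec.to_hdf5(out_dir / fname)
                manifest["records"].append(
                    {"tau": float(tau), "stimulus": -1 if s is None else int(s),
                     "trial": trial, "seed": trial_seed, "file": fname}
                )
                manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _grid_seed(master: int, tau: float, s, trial: int) -> int:
    ss = np.random.SeedSequence(
        [int(master), int(round(float(tau) * 1000)), 0 if s is None else int(s) + 1, int(trial)]
    )
    return int(ss.generate_state(1)[0] % 2**31)
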