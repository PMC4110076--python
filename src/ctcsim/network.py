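"""Population graphs: small-world recurrent wiring, cell-type labels and
delayed inter-population projections.

Each population is a Watts–Strogatz small-world graph over its neurons.  The
undirected skeleton is duplicated into two directed chemical synapses, the
class of each synapse (AMPA/GABA_A) being set by the presynaptic cell type.
Conduction delays inside a population are gamma-distributed with shape and
scale one (i.e. Exponential(1) ms).  The two populations are linked by sparse
long-range excitatory projections whose delays follow a gamma distribution of
scale 1 and shape ``tau``, so the mean delay is ``tau`` ms and the
coefficient of variation shrinks as ``1/sqrt(tau)`` for longer paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSpec",
    "CouplingSpec",
    "InterEdges",
    "build_small_world",
    "assign_cell_types",
    "sample_intra_delays",
    "build_population",
    "build_inter_coupling",
    "lattice_clustering",
]


@dataclass
class NetworkSpec:
    """Directed synaptic graph of one population.

    ``pre``/``post`` are parallel integer arrays (one entry per directed
    edge), ``delay`` the per-edge conduction delay in ms, ``exc_mask`` the
    per-neuron excitatory flag.  An edge is excitatory iff its presynaptic
    neuron is.
    """

    N: int
    mean_degree: int
    rewiring_p: float
    pre: np.ndarray
    post: np.ndarray
    delay: np.ndarray = field(default=None)  # type: ignore[assignment]
    exc_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    @property
    def edge_is_exc(self) -> np.ndarray:
        return self.exc_mask[self.pre]

    def validate(self) -> None:
        if np.any(self.pre == self.post):
            raise ValueError("self-edges are not allowed")
        if self.delay is not None and np.any(self.delay <= 0):
            raise ValueError("all delays must be positive")
        mean_out = self.n_edges / self.N
        if abs(mean_out - self.mean_degree) > 0.05 * self.mean_degree:
            raise ValueError(
                f"average out-degree {mean_out:.1f} deviates >5% from target {self.mean_degree}"
            )

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, group) -> None:
        group.attrs["N"] = self.N
        group.attrs["mean_degree"] = self.mean_degree
        group.attrs["rewiring_p"] = self.rewiring_p
        group.create_dataset("pre", data=self.pre)
        group.create_dataset("post", data=self.post)
        group.create_dataset("delay", data=self.delay)
        group.create_dataset("exc_mask", data=self.exc_mask)

    @classmethod
    def from_hdf5(cls, group) -> "NetworkSpec":
        return cls(
            N=int(group.attrs["N"]),
            mean_degree=int(group.attrs["mean_degree"]),
            rewiring_p=float(group.attrs["rewiring_p"]),
            pre=group["pre"][:],
            post=group["post"][:],
            delay=group["delay"][:],
            exc_mask=group["exc_mask"][:].astype(bool),
        )

    def to_edge_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "delay_ms": self.delay,
                "exc": self.edge_is_exc.astype(int),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CouplingSpec:
    """Inter-population projection parameters.

    ``frac_source_exc`` of the excitatory neurons of each population send
    long-range projections; targets are drawn from a random subset covering
    ``frac_target`` of the other population.  ``tau_inter`` is the mean
    inter-areal conduction delay in ms.  ``connectivity_ratio`` sets how much
    sparser the cross-network wiring is than the internal wiring (number of
    inter edges per direction = N * mean_degree / connectivity_ratio).
    """

    frac_source_exc: float = 0.9
    frac_target: float = 0.25
    tau_inter: float = 0.0
    delay_mode: str = "gamma"
    unidirectional: bool = False
    connectivity_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.frac_source_exc <= 1 and 0 < self.frac_target <= 1):
            raise ValueError("coupling fractions must lie in (0, 1]")
        if self.tau_inter < 0:
            raise ValueError("tau_inter must be non-negative")
        if self.delay_mode not in ("gamma", "constant"):
            raise ValueError("delay_mode must be 'gamma' or 'constant'")


@dataclass
class InterEdges:
    """Directed long-range excitatory edges between the two populations.

    ``pre_a2b`` indexes neurons in population A, ``post_a2b`` in population B
    (and symmetrically for ``b2a``; empty when coupling is unidirectional).
    """

    pre_a2b: np.ndarray
    post_a2b: np.ndarray
    delay_a2b: np.ndarray
    pre_b2a: np.ndarray
    post_b2a: np.ndarray
    delay_b2a: np.ndarray


def lattice_clustering(k: int) -> float:
    """Clustering coefficient of the unrewired ring lattice with even degree k."""
    return 3.0 * (k - 2) / (4.0 * (k - 1))


def build_small_world(N: int, mean_degree: int, rewiring_p: float, seed: int) -> NetworkSpec:
    """Watts–Strogatz skeleton duplicated into directed edges.

    The undirected graph has ``N`` nodes each wired to its ``mean_degree``
    nearest ring neighbours before rewiring each edge with probability
    ``rewiring_p``; every undirected edge becomes a reciprocal pair of
    directed synapses, so the average out-degree equals ``mean_degree``.
    """
    if not (N > mean_degree >= 2):
        raise ValueError("require N > mean_degree >= 2")
    if mean_degree % 2:
        raise ValueError("mean_degree must be even for the ring lattice")
    g = nx.watts_strogatz_graph(N, mean_degree, rewiring_p, seed=int(seed))
    und = np.array(g.edges(), dtype=np.int64)
    pre = np.concatenate([und[:, 0], und[:, 1]])
    post = np.concatenate([und[:, 1], und[:, 0]])
    return NetworkSpec(N=N, mean_degree=mean_degree, rewiring_p=rewiring_p, pre=pre, post=post)


def assign_cell_types(N: int, frac_exc: float, seed: int) -> np.ndarray:
    """Random excitatory/inhibitory labelling with exactly round(N*frac_exc)
    excitatory cells; deterministic for a fixed seed."""
    if not (0 < frac_exc < 1):
        raise ValueError("frac_exc must lie strictly between 0 and 1 (inhibition is required)")
    n_exc = int(round(N * frac_exc))
    rng = np.random.default_rng(seed)
    mask = np.zeros(N, dtype=bool)
    mask[rng.permutation(N)[:n_exc]] = True
    return mask


def sample_intra_delays(n_edges: int, seed: int, shape: float = 1.0, scale: float = 1.0) -> np.ndarray:
    """Gamma(shape=1, scale=1) = Exponential(1) conduction delays in ms."""
    if n_edges < 1:
        raise ValueError("need at least one edge")
    rng = np.random.default_rng(seed)
    d = rng.gamma(shape, scale, size=n_edges)
    # strictly positive: the gamma sampler can in principle return 0.0
    return np.maximum(d, 1e-9)


def build_population(
    N: int, mean_degree: int, rewiring_p: float, frac_exc: float, seed: int
) -> NetworkSpec:
    """Full population: small-world wiring + cell types + intra delays."""
    ss = np.random.SeedSequence(seed).spawn(3)
    spec = build_small_world(N, mean_degree, rewiring_p, seed=int(ss[0].generate_state(1)[0] % 2**31))
    spec.exc_mask = assign_cell_types(N, frac_exc, seed=int(ss[1].generate_state(1)[0]))
    spec.delay = sample_intra_delays(spec.n_edges, seed=int(ss[2].generate_state(1)[0]))
    spec.validate()
    return spec


def _sample_direction(
    src: NetworkSpec, dst: NetworkSpec, c: CouplingSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    exc_idx = np.flatnonzero(src.exc_mask)
    n_src = max(1, int(round(c.frac_source_exc * len(exc_idx))))
    sources = rng.permutation(exc_idx)[:n_src]
    n_tgt = max(1, int(round(c.frac_target * dst.N)))
    target_pool = rng.permutation(dst.N)[:n_tgt]
    n_edges = max(1, int(round(src.N * src.mean_degree / c.connectivity_ratio)))
    pre = rng.choice(sources, size=n_edges)
    post = rng.choice(target_pool, size=n_edges)
    if c.tau_inter == 0:
        if c.delay_mode == "gamma":
            logger.info("tau_inter=0 with gamma delays: falling back to zero delays")
        delay = np.zeros(n_edges)
    elif c.delay_mode == "constant":
        delay = np.full(n_edges, float(c.tau_inter))
    else:
        # scale 1, shape tau: mean tau, variance tau, CV 1/sqrt(tau)
        delay = np.maximum(rng.gamma(c.tau_inter, 1.0, size=n_edges), 1e-9)
    return pre, post, delay


def build_inter_coupling(
    spec_a: NetworkSpec, spec_b: NetworkSpec, c: CouplingSpec, seed: int
) -> InterEdges:
    """Long-range excitatory projections between the two populations.

    Sources are excitatory cells only; in unidirectional mode only A
    projects onto B.  Delays are drawn per edge: gamma(shape=tau, scale=1)
    in ``gamma`` mode, exactly ``tau`` in ``constant`` mode, and zero when
    ``tau_inter == 0``.
    """
    if spec_a.exc_mask is None or spec_b.exc_mask is None:
        raise ValueError("population specs must carry cell-type labels")
    rng = np.random.default_rng(seed)
    pre_ab, post_ab, d_ab = _sample_direction(spec_a, spec_b, c, rng)
    if c.unidirectional:
        empty_i = np.empty(0, dtype=np.int64)
        empty_f = np.empty(0, dtype=float)
        return InterEdges(pre_ab, post_ab, d_ab, empty_i, empty_i, empty_f)
    pre_ba, post_ba, d_ba = _sample_direction(spec_b, spec_a, c, rng)
    return InterEdges(pre_ab, post_ab, d_ab, pre_ba, post_ba, d_ba)
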