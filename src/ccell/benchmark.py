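"""Synthetic benchmark family: sparse linear signalling networks.

Each benchmark is a 300-species linear dynamical system
``x_{t+1} = A x_t + omega`` in which only a small set of *time-variant*
species interact over the studied timescale; every other species keeps an
identity row (its concentration is constant up to system noise).  The
family mirrors well-studied pathway sizes (JAK-STAT, GR, ERK, p38 and their
crosstalk) through exact species/link counts; the wiring itself is a seeded
random weakly-connected sparse digraph with the same counts, since the aim
is the statistical shape of the inference problem, not curated biology.

Conventions
-----------
``A[i, j]`` is the influence of species j on species i, so a link
(j -> i) exists iff ``A[i, j]`` is a nonzero off-diagonal entry.  Diagonal
entries are self-dynamics, not interactions: 1 for a time-invariant
species (its concentration persists), 0 for a time-variant one (its next
concentration is set by its regulators, as in a fast phosphorylation
cycle).  The interaction block is rescaled to spectral radius <= 0.95
when a draw exceeds it, so trajectories stay bounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .measurement_design import MeasurementDesign, generate_ldpc_design, simulate_measurements

__all__ = [
    "BENCHMARK_TABLE",
    "BenchmarkSpec",
    "BenchmarkNetwork",
    "ExperimentBundle",
    "build_benchmark",
    "simulate_dynamics",
    "run_experiment",
]

#: id -> (pathway components, number of time-variant species, number of links)
BENCHMARK_TABLE: dict[str, tuple[str, int, int]] = {
    "n-4": ("JAK-STAT", 4, 4),
    "n-11": ("ERK", 11, 20),
    "n-39": ("p38", 39, 61),
    "n-50": ("ERK and p38", 50, 83),
    "n-53": ("GR, ERK and p38", 53, 93),
    "n-58": ("GR, JAK-STAT, ERK and p38", 58, 101),
}

#: target spectral radius of the time-variant interaction block
_SPECTRAL_TARGET = 0.95
#: link weight magnitudes are drawn uniformly from this band (random sign)
_WEIGHT_RANGE = (0.2, 0.9)


@dataclass
class BenchmarkSpec:
    """Full description of one in-silico experiment.

    Defaults are the baseline study conditions: 300 species, 5 time points,
    initial concentrations N(100, 20^2) truncated at zero (each perturbation
    redraws the initial state, so perturbations are well separated), system
    and measurement noise std 0.01 in absolute concentration units (i.e.
    0.01% of the signal mean -- the "small" baseline; the noise-robustness
    sweep raises it to 1-10), and 150 pooled measurements of column
    weight 3.
    """

    id: str = "custom"
    n_species: int = 300
    n_time_variant: int = 0
    n_links: int = 0
    components: str = ""
    n_perturbations: int = 3
    n_time_points: int = 5
    init_mean: float = 100.0
    init_std: float = 20.0
    system_noise_std: float = 0.01
    measurement_noise_std: float = 0.01
    n_measurements: int = 150
    column_weight: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time_variant > self.n_species:
            raise ValueError("n_time_variant exceeds n_species")
        if self.n_time_variant and self.n_links < self.n_time_variant - 1:
            raise ValueError("too few links for a connected time-variant set")
        if self.n_time_points < 2:
            raise ValueError("need at least two time points")
        if not 1 <= self.n_perturbations:
            raise ValueError("need at least one perturbation")

    @classmethod
    def from_id(cls, benchmark_id: str, **overrides) -> "BenchmarkSpec":
        """Spec for one of the named benchmark networks (n-4 ... n-58)."""
        try:
            components, n_tv, n_links = BENCHMARK_TABLE[benchmark_id]
        except KeyError as exc:
            raise ValueError(
                f"unknown benchmark id {benchmark_id!r}; "
                f"known: {sorted(BENCHMARK_TABLE)}"
            ) from exc
        return cls(
            id=benchmark_id,
            n_time_variant=n_tv,
            n_links=n_links,
            components=components,
            **overrides,
        )


@dataclass
class BenchmarkNetwork:
    """Ground-truth transition matrix with its time-variant set and links."""

    transition: np.ndarray
    time_variant: np.ndarray
    links: list[tuple[int, int, float]]
    spec: BenchmarkSpec

    @property
    def n_species(self) -> int:
        return self.transition.shape[0]

    def adjacency(self) -> np.ndarray:
        """Boolean matrix of true links; adj[i, j] = link j -> i."""
        adj = np.zeros(self.transition.shape, dtype=bool)
        for source, target, _ in self.links:
            adj[target, source] = True
        return adj


@dataclass
class ExperimentBundle:
    """A complete regenerable in-silico experiment."""

    network: BenchmarkNetwork
    design: MeasurementDesign
    true_concentrations: np.ndarray  # (P, T, N)
    observations: np.ndarray  # (P, T, M)
    initial_concentrations: np.ndarray  # (P, N), known to inference


def _rng_streams(seed: int) -> list[np.random.SeedSequence]:
    """Independent child streams: network, dynamics, design, measurement."""
    return np.random.SeedSequence(seed).spawn(4)


#: maximum in-degree of a time-variant species; signalling cascades rarely
#: integrate more than a few upstream regulators, while out-degrees may hub
_MAX_IN_DEGREE = 3
#: fraction of non-skeleton links allowed to run against the cascade order
#: (feedback); the bulk of signal flow is feed-forward
_FEEDBACK_FRACTION = 0.2


def _sample_links(
    rng: np.random.Generator, n_nodes: int, n_links: int
) -> list[tuple[int, int]]:
    """Weakly connected cascade-like digraph with exactly n_links edges.

    Nodes are placed in a random cascade order; every node past the first
    receives one edge from an earlier node (connectivity), extra edges are
    mostly feed-forward with a minority of feedback, and in-degrees are
    capped so no species integrates more than a few upstream regulators.
    """
    cap = _MAX_IN_DEGREE
    max_links = min(n_nodes * (n_nodes - 1), n_nodes * cap)
    if n_links > max_links:
        raise ValueError(
            f"{n_links} links infeasible for {n_nodes} species "
            f"(maximum {max_links} with in-degree cap {cap})"
        )
    order = list(rng.permutation(n_nodes))
    rank = {node: k for k, node in enumerate(order)}
    edges: set[tuple[int, int]] = set()
    in_degree = np.zeros(n_nodes, dtype=int)
    for k in range(1, n_nodes):
        src = order[int(rng.integers(0, k))]
        dst = order[k]
        edges.add((src, dst))
        in_degree[dst] += 1
    while len(edges) < n_links:
        open_dst = np.flatnonzero(in_degree < cap)
        feedback = rng.random() < _FEEDBACK_FRACTION
        candidates = [
            (s, d)
            for d in open_dst
            for s in range(n_nodes)
            if s != d
            and (s, d) not in edges
            and (rank[s] > rank[d]) == feedback
        ]
        if not candidates:  # fall back to any orientation
            candidates = [
                (s, d)
                for d in open_dst
                for s in range(n_nodes)
                if s != d and (s, d) not in edges
            ]
        src, dst = candidates[int(rng.integers(0, len(candidates)))]
        edges.add((src, dst))
        in_degree[dst] += 1
    return sorted(edges)


def build_benchmark(spec: BenchmarkSpec) -> BenchmarkNetwork:
    """Ground-truth network with exactly the requested species/link counts.

    Time-invariant rows are identity rows; time-variant rows hold the
    sampled interaction weights (uniform magnitudes in +-[0.2, 0.9]) and a
    zero diagonal, with the interaction block rescaled to spectral radius
    <= 0.95 when the draw exceeds it.
    """
    rng = np.random.default_rng(_rng_streams(spec.seed)[0])
    n = spec.n_species
    transition = np.eye(n)
    if spec.n_time_variant == 0:
        if spec.n_links:
            raise ValueError("links require at least one time-variant species")
        return BenchmarkNetwork(transition, np.array([], dtype=int), [], spec)
    tv = np.sort(rng.choice(n, size=spec.n_time_variant, replace=False))
    local_edges = _sample_links(rng, spec.n_time_variant, spec.n_links)
    magnitudes = rng.uniform(*_WEIGHT_RANGE, size=len(local_edges))
    signs = rng.choice([-1.0, 1.0], size=len(local_edges))
    block = np.zeros((spec.n_time_variant, spec.n_time_variant))
    for (src, dst), w in zip(local_edges, magnitudes * signs):
        block[dst, src] = w
    radius = np.max(np.abs(np.linalg.eigvals(block))) if block.any() else 0.0
    if radius > _SPECTRAL_TARGET:
        block *= _SPECTRAL_TARGET / radius
    transition[tv, :] = 0.0
    transition[np.ix_(tv, tv)] = block
    links = [
        (int(tv[src]), int(tv[dst]), float(block[dst, src]))
        for src, dst in local_edges
    ]
    return BenchmarkNetwork(transition, tv, links, spec)


def simulate_dynamics(
    network: BenchmarkNetwork,
    n_perturbations: int,
    n_time_points: int,
    init_mean: float,
    init_std: float,
    system_noise_std: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Perturbation time series ``x_{t+1} = A x_t + N(0, s^2 I)``.

    Each perturbation draws an independent initial state per species from
    N(init_mean, init_std^2) truncated at zero.  Returns (P, T, N).
    """
    if n_time_points < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(seed)
    n = network.n_species
    x = np.empty((n_perturbations, n_time_points, n))
    x[:, 0, :] = np.clip(
        rng.normal(init_mean, init_std, size=(n_perturbations, n)), 0.0, None
    )
    a_t = network.transition.T
    for t in range(n_time_points - 1):
        noise = (
            rng.normal(0.0, system_noise_std, size=(n_perturbations, n))
            if system_noise_std > 0
            else 0.0
        )
        x[:, t + 1, :] = x[:, t, :] @ a_t + noise
    return x


def run_experiment(
    spec: BenchmarkSpec, design: Optional[MeasurementDesign] = None
) -> ExperimentBundle:
    """Build network and design, simulate dynamics and the pooled assay.

    Fully regenerable: identical spec (and seed) yields a bit-identical
    bundle.  A pre-built design may be supplied to share one pooling matrix
    across experiments.
    """
    streams = _rng_streams(spec.seed)
    network = build_benchmark(spec)
    x = simulate_dynamics(
        network,
        spec.n_perturbations,
        spec.n_time_points,
        spec.init_mean,
        spec.init_std,
        spec.system_noise_std,
        seed=streams[1],
    )
    if design is None:
        design_seed = int(streams[2].generate_state(1)[0] % (2**31))
        design = generate_ldpc_design(
            spec.n_measurements, spec.n_species, spec.column_weight, design_seed
        )
    rng_meas = np.random.default_rng(streams[3])
    p, t, _ = x.shape
    obs = np.empty((p, t, design.n_measurements))
    for ip in range(p):
        for it in range(t):
            obs[ip, it] = simulate_measurements(
                design, x[ip, it], spec.measurement_noise_std, rng=rng_meas
            )
    return ExperimentBundle(
        network=network,
        design=design,
        true_concentrations=x,
        observations=obs,
        initial_concentrations=x[:, 0, :].copy(),
    )
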