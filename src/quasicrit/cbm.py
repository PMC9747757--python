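"""Cortical branching model (CBM): a probabilistic cellular automaton.

The CBM is a minimal spiking model of cortex dynamics.  ``n_nodes`` excitatory
nodes each receive ``k_in`` directed in-edges from distinct random sources.
The in-edges of every node carry transmission probabilities drawn from an
exponential weighting function ranked by strength,

    p_n = exp(-B n) / sum_{m=1..k_in} exp(-B m),      n = 1..k_in,

so the inbound probabilities of each node sum to one; a bias B = 0 gives
homogeneous weights, larger B gives few strong and many weak connections
(used to model the age-related skewing of cortical connectivity).  The full
connection weight is P_ij = kappa * p_{n_ij}, where the branching parameter
kappa scales every edge and equals the largest eigenvalue of the weight
matrix.  A quiescent node activates when an active in-neighbor's edge
transmits (uniform draw <= P_ij) or spontaneously with probability ``p_s``
per step; after one active step a node is refractory for ``refractory``
steps.  With p_s = 0 the model has an absorbing inactive phase for kappa < 1
and a critical point at kappa = 1; with p_s > 0 the transition is replaced
by a quasicritical crossover whose susceptibility peak defines the Widom
line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .errors import ConstructionFailureError, InvalidArgumentError

__all__ = [
    "CBMConfig",
    "Network",
    "Raster",
    "weighting_probabilities",
    "build_network",
    "step",
    "initial_state",
    "simulate",
    "simulate_counts",
    "seeded_avalanche_sizes",
    "kappa_sweep",
    "SweepResult",
]

#: phase encoding shared with the compiled kernels
QUIESCENT = 0
ACTIVE = 1

#: steps discarded before collecting statistics (all-quiescent start transient)
DEFAULT_BURN_IN = 1000


@dataclass(frozen=True)
class CBMConfig:
    """Parameters of one CBM simulation.

    Defaults are the reference simulation conditions: 256 nodes, 5 incoming
    neighbors, spontaneous probability 1e-3 and a one-step refractory period.
    """

    n_nodes: int = 256
    k_in: int = 5
    kappa: float = 1.0
    p_s: float = 1e-3
    bias: float = 0.0
    refractory: int = 1
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.k_in < 1:
            raise InvalidArgumentError("n_nodes and k_in must be positive")
        if self.k_in >= self.n_nodes:
            raise InvalidArgumentError("k_in must be smaller than n_nodes")
        if not 0.0 <= self.p_s <= 1.0:
            raise InvalidArgumentError("p_s must lie in [0, 1]")
        if self.kappa < 0 or self.bias < 0:
            raise InvalidArgumentError("kappa and bias must be non-negative")
        if self.refractory < 0:
            raise InvalidArgumentError("refractory must be non-negative")
        if self.n_steps < 1:
            raise InvalidArgumentError("n_steps must be positive")

    def replace(self, **kwargs) -> "CBMConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Network:
    """Directed weighted connectivity of a CBM realisation.

    ``in_neighbors[j, m]`` is the source of the in-edge of node j with rank
    m + 1 (rank 1 = strongest), and ``in_weights[j, m]`` its full transmission
    probability P_ij = kappa * p_{m+1}.
    """

    in_neighbors: np.ndarray  # (n_nodes, k_in) int32
    in_weights: np.ndarray  # (n_nodes, k_in) float64, already kappa-scaled
    kappa: float
    bias: float
    # CSR-style out-edge arrays consumed by the compiled kernels
    out_ptr: np.ndarray = field(repr=False, default=None)
    out_tgt: np.ndarray = field(repr=False, default=None)
    out_w: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.in_neighbors.shape[0]

    @property
    def k_in(self) -> int:
        return self.in_neighbors.shape[1]

    def unscaled_in_weights(self) -> np.ndarray:
        """Inbound probabilities p_n before kappa scaling (rows sum to 1)."""
        if self.kappa == 0:
            return np.tile(
                weighting_probabilities(self.k_in, self.bias), (self.n_nodes, 1)
            )
        return self.in_weights / self.kappa


@dataclass
class Raster:
    """Binary node/channel x time-bin activity matrix."""

    data: np.ndarray  # (n_rows, n_bins) uint8
    bin_width: int = 1  # samples per bin
    sampling_rate: float | None = None  # Hz of the underlying samples, if any

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise InvalidArgumentError("raster data must be 2-D")
        if self.data.max(initial=0) > 1:
            raise InvalidArgumentError("raster entries must be binary")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        """Number of active rows per time bin."""
        return self.data.sum(axis=0).astype(np.int64)


def weighting_probabilities(k_in: int, bias: float) -> np.ndarray:
    """Exponential rank-weighting p_n = e^{-B n} / sum_m e^{-B m}, n = 1..k_in.

    Strictly decreasing in rank for bias > 0 and homogeneous (all 1/k_in)
    for bias = 0; always sums to one.
    """
    if k_in < 1:
        raise InvalidArgumentError("k_in must be >= 1")
    if bias < 0:
        raise InvalidArgumentError("bias must be non-negative")
    n = np.arange(1, k_in + 1, dtype=float)
    # subtract the smallest exponent for numerical safety at large bias
    w = np.exp(-bias * (n - 1.0))
    return w / w.sum()


def build_network(config: CBMConfig, max_attempts: int = 1000) -> Network:
    """Wire a random CBM network satisfying the connectivity invariant.

    Every node receives exactly ``k_in`` in-edges from distinct sources other
    than itself; inbound rank m+1 carries probability p_{m+1} from
    :func:`weighting_probabilities` (sources are assigned to ranks at
    random).  The wiring is resampled until the underlying undirected graph
    is a single component.
    """
    n, k = config.n_nodes, config.k_in
    rng = np.random.default_rng(config.seed)
    p_rank = weighting_probabilities(k, config.bias)
    for _ in range(max_attempts):
        in_neighbors = np.empty((n, k), dtype=np.int32)
        for j in range(n):
            sources = rng.choice(n - 1, size=k, replace=False)
            sources[sources >= j] += 1  # skip self
            in_neighbors[j] = sources
        if _is_connected(in_neighbors, n):
            break
    else:
        raise ConstructionFailureError(
            f"no connected wiring found in {max_attempts} attempts"
        )
    in_weights = np.tile(config.kappa * p_rank, (n, 1))
    out_ptr, out_tgt, out_w = _out_edges(in_neighbors, in_weights, n)
    return Network(
        in_neighbors=in_neighbors,
        in_weights=in_weights,
        kappa=config.kappa,
        bias=config.bias,
        out_ptr=out_ptr,
        out_tgt=out_tgt,
        out_w=out_w,
    )


def _is_connected(in_neighbors: np.ndarray, n: int) -> bool:
    k = in_neighbors.shape[1]
    rows = in_neighbors.ravel()
    cols = np.repeat(np.arange(n), k)
    adj = csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def _out_edges(in_neighbors, in_weights, n):
    """Convert the in-edge table to CSR out-edge arrays sorted by source."""
    src = in_neighbors.ravel()
    tgt = np.repeat(np.arange(n, dtype=np.int32), in_neighbors.shape[1])
    w = in_weights.ravel()
    order = np.argsort(src, kind="stable")
    src, tgt, w = src[order], tgt[order], w[order]
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr, src + 1, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, tgt.astype(np.int32), w.astype(np.float64)


# ---------------------------------------------------------------------------
# dynamics


def initial_state(n_nodes: int) -> np.ndarray:
    """All-quiescent phase vector (0 quiescent, 1 active, k>=2 refractory)."""
    return np.zeros(n_nodes, dtype=np.int8)


def step(
    phase: np.ndarray,
    network: Network,
    p_s: float,
    rng: np.random.Generator,
    refractory: int = 1,
) -> np.ndarray:
    """Pure-python reference update; returns the phase vector at t+1.

    Semantics match the compiled kernels: a node active at t is refractory
    for ``refractory`` steps and then quiescent; a node quiescent after that
    decay activates if any in-edge from a node active at t transmits
    (draw <= P_ij, edges evaluated in ascending source order) or by a
    spontaneous draw <= p_s.
    """
    phase = np.asarray(phase, dtype=np.int8)
    n = phase.shape[0]
    active_prev = np.flatnonzero(phase == ACTIVE)
    out = phase.copy()
    # decay
    out[phase == ACTIVE] = refractory + 1 if refractory > 0 else 0
    out[phase == 2] = 0
    mask = phase > 2
    out[mask] = phase[mask] - 1
    # driven transmission, ascending source-node order
    for i in active_prev:
        for e in range(network.out_ptr[i], network.out_ptr[i + 1]):
            j = network.out_tgt[e]
            if out[j] == QUIESCENT and rng.random() <= network.out_w[e]:
                out[j] = ACTIVE
    # spontaneous activation
    if p_s > 0:
        for j in range(n):
            if out[j] == QUIESCENT and rng.random() <= p_s:
                out[j] = ACTIVE
    return out


def simulate(
    config: CBMConfig,
    network: Network | None = None,
    record_from: int = 0,
) -> Raster:
    """Run the CBM and return the full binary node x time raster.

    The network is built from ``config`` unless supplied.  ``record_from``
    drops an initial transient (in steps) from the returned raster.
    """
    if network is None:
        network = build_network(config)
    phase = initial_state(config.n_nodes)
    raster = _kernels.run_raster(
        network.out_ptr,
        network.out_tgt,
        network.out_w,
        config.n_nodes,
        config.p_s,
        config.refractory,
        config.n_steps,
        _kernel_seed(config.seed),
        phase,
    )
    if record_from > 0:
        raster = raster[:, record_from:]
    return Raster(data=raster, bin_width=1)


def simulate_counts(
    config: CBMConfig,
    network: Network | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    target_avalanches: int | None = None,
    max_steps: int | None = None,
    chunk: int = 250_000,
) -> np.ndarray:
    """Run the CBM recording only the per-step active-node count.

    This is the memory-light path used for long runs.  If
    ``target_avalanches`` is given, the simulation proceeds in chunks until
    at least that many complete avalanches (maximal runs of non-zero counts
    bounded by zeros) have occurred or ``max_steps`` (default
    ``config.n_steps``) is reached, whichever comes first.  The burn-in is
    simulated but excluded from the returned series.
    """
    if network is None:
        network = build_network(config)
    max_steps = config.n_steps if max_steps is None else max_steps
    phase = initial_state(config.n_nodes)
    seed0 = _kernel_seed(config.seed)
    segment = 0  # each kernel call advances the seed so chunks differ
    if burn_in > 0:
        _kernels.run_counts(
            network.out_ptr, network.out_tgt, network.out_w,
            config.n_nodes, config.p_s, config.refractory,
            burn_in, seed0, phase,
        )
        segment = 1
    if target_avalanches is None:
        return _kernels.run_counts(
            network.out_ptr, network.out_tgt, network.out_w,
            config.n_nodes, config.p_s, config.refractory,
            max_steps, seed0 + segment, phase,
        )
    pieces = []
    n_av = 0
    total = 0
    while n_av < target_avalanches and total < max_steps:
        n = min(chunk, max_steps - total)
        counts = _kernels.run_counts(
            network.out_ptr, network.out_tgt, network.out_w,
            config.n_nodes, config.p_s, config.refractory,
            n, seed0 + segment, phase,
        )
        segment += 1
        pieces.append(counts)
        total += n
        nz = counts > 0
        n_av += int(np.sum(nz[1:] & ~nz[:-1]))
    return np.concatenate(pieces)


def seeded_avalanche_sizes(
    config: CBMConfig,
    n_avalanches: int,
    network: Network | None = None,
    max_steps: int = 1_000_000,
) -> np.ndarray:
    """Total progeny of avalanches seeded from single random nodes (p_s = 0).

    With kappa < 1 this realises a Galton-Watson branching process whose
    mean offspring number is kappa, so the mean total size tends to
    1 / (1 - kappa) when refractory collisions are rare.
    """
    if network is None:
        network = build_network(config)
    return _kernels.seeded_avalanche_sizes(
        network.out_ptr,
        network.out_tgt,
        network.out_w,
        config.n_nodes,
        config.refractory,
        n_avalanches,
        max_steps,
        _kernel_seed(config.seed),
    )


def _kernel_seed(seed: int) -> int:
    # numba's legacy RNG wants a 32-bit unsigned seed; keep headroom for
    # per-chunk offsets
    return int(seed) % (2**31 - 1000)


# ---------------------------------------------------------------------------
# susceptibility sweep


@dataclass
class SweepResult:
    """Susceptibility profile over a kappa grid."""

    kappa: np.ndarray
    chi_mean: np.ndarray
    chi_sd: np.ndarray

    @property
    def kappa_star(self) -> float:
        """Grid location of the susceptibility peak (raw argmax)."""
        return float(self.kappa[int(np.argmax(self.chi_mean))])

    @property
    def kappa_star_quadratic(self) -> float:
        """Vertex of a quadratic fit to chi(kappa), clipped to the grid.

        The quasicritical susceptibility peak is broad relative to
        run-to-run noise, so the parabola vertex is a steadier peak-location
        estimate than the raw argmax.  Falls back on the argmax if the fit
        is not concave.
        """
        if self.kappa.size < 3:
            return self.kappa_star
        coef = np.polyfit(self.kappa, self.chi_mean, 2)
        if coef[0] >= 0:
            return self.kappa_star
        vertex = -coef[1] / (2.0 * coef[0])
        return float(np.clip(vertex, self.kappa[0], self.kappa[-1]))

    def rows(self):
        return list(zip(self.kappa, self.chi_mean, self.chi_sd))


def kappa_sweep(
    config: CBMConfig,
    kappa_grid: Sequence[float],
    reps: int = 3,
    n_steps: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
) -> SweepResult:
    """Susceptibility chi as a function of the branching parameter kappa.

    For each kappa on the grid, ``reps`` independent simulations (fresh
    network wiring and dynamics per rep) of ``n_steps`` steps (default
    ``config.n_steps``) are run and chi = N * var(rho_1) computed after
    burn-in.  Returns the per-kappa mean and SD of chi; the peak location
    estimates the Widom-line point for the configured p_s and bias.
    """
    from .activity import susceptibility_from_counts

    grid = np.asarray(list(kappa_grid), dtype=float)
    if grid.size == 0:
        raise InvalidArgumentError("kappa_grid must be non-empty")
    if reps < 1:
        raise InvalidArgumentError("reps must be >= 1")
    n_steps = config.n_steps if n_steps is None else n_steps
    chi_mean = np.empty(grid.size)
    chi_sd = np.empty(grid.size)
    for gi, kappa in enumerate(grid):
        chis = np.empty(reps)
        for r in range(reps):
            cfg = config.replace(
                kappa=float(kappa),
                seed=config.seed + 104_729 * r + 15_485_863 * gi,
                n_steps=n_steps,
            )
            counts = simulate_counts(cfg, burn_in=burn_in)
            chis[r] = susceptibility_from_counts(counts, cfg.n_nodes)
        chi_mean[gi] = chis.mean()
        chi_sd[gi] = chis.std(ddof=1) if reps > 1 else 0.0
    return SweepResult(kappa=grid, chi_mean=chi_mean, chi_sd=chi_sd)
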