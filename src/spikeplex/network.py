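"""Construction of structural networks: lattice, small-world rewiring, recurrence control.

The structural layer is a directed graph over neurons placed on a 2-D grid.
Construction proceeds in four stages:

1. a regular lattice with an undirected edge between every pair of neurons at
   Euclidean distance <= ``radius`` (no periodic boundaries);
2. Watts-Strogatz rewiring of undirected edges with probability ``p_rw``;
3. recurrence reduction: an exact proportion ``p_r`` of undirected edges is
   made unidirectional by deleting one direction, chosen by ``p_d``;
4. assignment of excitatory/inhibitory types and synaptic weights.

Adjacency convention: ``adjacency[i, j] == 1`` means a directed edge from
neuron ``j`` to neuron ``i`` (source along columns, target along rows).
An *undirected* (recurrent) edge is a pair of reciprocal directed edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StructuralNetwork",
    "BuildParams",
    "build_regular_lattice",
    "rewire_small_world",
    "reduce_recurrence",
    "assign_types_and_weights",
    "build_structural_network",
]


@dataclass
class StructuralNetwork:
    """A directed structural (synaptic) network.

    Attributes
    ----------
    adjacency:
        ``(n, n)`` binary matrix; ``adjacency[i, j] == 1`` encodes an edge
        ``j -> i``. Zero diagonal.
    positions:
        ``(n, 2)`` integer grid coordinates (row, col) per neuron.
    is_inhibitory:
        ``(n,)`` boolean flags; ``True`` marks an inhibitory neuron.
    weights:
        ``(n, n)`` synaptic amplitudes in mV aligned with ``adjacency``
        (``weights[i, j]`` is the amplitude of the ``j -> i`` synapse,
        zero where no edge). Excitatory-source weights are positive,
        inhibitory-source weights negative.
    rng_seed:
        Seed recorded at build time (``None`` for intermediate stages).
    """

    adjacency: np.ndarray
    positions: np.ndarray
    is_inhibitory: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-edges are not allowed")
        if self.is_inhibitory is None:
            self.is_inhibitory = np.zeros(n, dtype=bool)
        if self.weights is None:
            self.weights = np.zeros((n, n), dtype=float)

    @property
    def n_neurons(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return int(self.adjacency.sum())

    def undirected_edges(self) -> list[tuple[int, int]]:
        """Recurrent pairs as ``(u, v)`` with ``u < v`` (both directions present)."""
        mutual = (self.adjacency & self.adjacency.T).astype(bool)
        iu = np.triu_indices(self.n_neurons, k=1)
        mask = mutual[iu]
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    def n_undirected_edges(self) -> int:
        """Number of *edge units*: recurrent pairs plus unidirectional edges."""
        a = self.adjacency.astype(bool)
        mutual = int((a & a.T).sum()) // 2
        uni = int(a.sum()) - 2 * mutual
        return mutual + uni


@dataclass
class BuildParams:
    """Parameters of the structural-network generator.

    ``radius`` is the Euclidean neighbour cutoff on the grid (default
    ``sqrt(2)``: the 8-neighbourhood). ``p_rw`` is the Watts-Strogatz
    rewiring probability, ``p_r`` the proportion of undirected edges made
    unidirectional, and ``p_d`` the probability that the canonical
    (lower-index -> higher-index) direction is the one deleted.
    Weights: excitatory amplitudes drawn from N(``weight_mean``,
    ``weight_sd``) mV, inhibitory amplitudes fixed at ``v_inh`` mV.
    """

    rows: int = 10
    cols: int = 10
    radius: float = math.sqrt(2)
    p_rw: float = 0.4
    p_r: float = 0.4
    p_d: float = 0.5
    inhibitory_fraction: float = 0.2
    weight_mean: float = 3.1
    weight_sd: float = 0.1
    v_inh: float = -1.5

    def __post_init__(self) -> None:
        for name in ("p_rw", "p_r", "p_d", "inhibitory_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _exact_round(x: float) -> int:
    """Round-half-up for non-negative x (avoids banker's rounding)."""
    return int(math.floor(x + 0.5))


def build_regular_lattice(rows: int, cols: int, radius: float = math.sqrt(2)) -> StructuralNetwork:
    """Fully recurrent lattice: undirected edges between all pairs at distance <= radius.

    Neurons are placed on an integer ``rows x cols`` grid without periodic
    boundaries. A 10x10 grid with ``radius = sqrt(2)`` yields 342 undirected
    edges (interior neurons have eight neighbours, boundary five, corners
    three).
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid dimensions must be at least 2x2")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = rows * cols
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=int)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    # small tolerance so radius = sqrt(2) includes exact diagonal neighbours
    adj = (d2 <= radius * radius + 1e-9).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return StructuralNetwork(adjacency=adj, positions=pos)


def rewire_small_world(
    net: StructuralNetwork, p_rw: float, rng: np.random.Generator
) -> StructuralNetwork:
    """Watts-Strogatz rewiring of a fully recurrent network.

    Each undirected edge is independently rewired with probability ``p_rw``:
    one endpoint (chosen uniformly) is kept and the other is replaced by a
    uniformly drawn vertex, redrawing on self-loops and duplicate edges.
    The undirected edge count is preserved; both directions move together.
    """
    if not 0.0 <= p_rw <= 1.0:
        raise ValueError("p_rw must be in [0, 1]")
    a = net.adjacency.astype(bool)
    if not np.array_equal(a, a.T):
        raise ValueError("rewiring expects a fully recurrent network")
    n = net.n_neurons
    edges = {frozenset(e) for e in net.undirected_edges()}
    new_edges = set(edges)
    for u, v in sorted((min(e), max(e)) for e in edges):
        if rng.random() >= p_rw:
            continue
        keep = u if rng.random() < 0.5 else v
        new_edges.discard(frozenset((u, v)))
        while True:
            w = int(rng.integers(n))
            if w != keep and frozenset((keep, w)) not in new_edges:
                break
        new_edges.add(frozenset((keep, w)))
    adj = np.zeros((n, n), dtype=np.uint8)
    for e in new_edges:
        u, v = tuple(e)
        adj[u, v] = adj[v, u] = 1
    return StructuralNetwork(adjacency=adj, positions=net.positions.copy())


def reduce_recurrence(
    net: StructuralNetwork, p_r: float, p_d: float, rng: np.random.Generator
) -> StructuralNetwork:
    """Make an exact proportion ``p_r`` of undirected edges unidirectional.

    Exactly ``round(p_r * E)`` undirected edges are selected without
    replacement; for each, one direction is deleted -- the canonical
    lower-index -> higher-index direction with probability ``p_d``, the
    reverse otherwise. With ``p_r = 1`` and ``p_d`` in ``{0, 1}`` all
    surviving edges point the same way with respect to the vertex order,
    so the digraph is acyclic.
    """
    if not 0.0 <= p_r <= 1.0 or not 0.0 <= p_d <= 1.0:
        raise ValueError("p_r and p_d must be in [0, 1]")
    pairs = net.undirected_edges()
    e_count = len(pairs)
    m = _exact_round(p_r * e_count)
    adj = net.adjacency.copy()
    if m > 0:
        chosen = rng.choice(e_count, size=m, replace=False)
        for idx in chosen:
            u, v = pairs[int(idx)]  # u < v; canonical direction is u -> v
            if rng.random() < p_d:
                adj[v, u] = 0  # delete canonical u -> v
            else:
                adj[u, v] = 0  # delete reverse v -> u
    return StructuralNetwork(adjacency=adj, positions=net.positions.copy())


def assign_types_and_weights(
    net: StructuralNetwork,
    inhibitory_fraction: float,
    rng: np.random.Generator,
    weight_mean: float = 3.1,
    weight_sd: float = 0.1,
    v_inh: float = -1.5,
) -> StructuralNetwork:
    """Flag inhibitory neurons and draw synaptic amplitudes.

    ``round(inhibitory_fraction * n)`` neurons are flagged inhibitory,
    placed uniformly at random. Every directed edge whose source is
    excitatory receives an independent Gaussian(``weight_mean``,
    ``weight_sd``) amplitude; edges from inhibitory sources receive the
    fixed amplitude ``v_inh``.
    """
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError("inhibitory_fraction must be in [0, 1]")
    n = net.n_neurons
    n_inh = _exact_round(inhibitory_fraction * n)
    inh = np.zeros(n, dtype=bool)
    inh[rng.choice(n, size=n_inh, replace=False)] = True
    weights = np.zeros((n, n), dtype=float)
    targets, sources = np.nonzero(net.adjacency)
    exc_edge = ~inh[sources]
    weights[targets[exc_edge], sources[exc_edge]] = rng.normal(
        weight_mean, weight_sd, size=int(exc_edge.sum())
    )
    weights[targets[~exc_edge], sources[~exc_edge]] = v_inh
    return StructuralNetwork(
        adjacency=net.adjacency.copy(),
        positions=net.positions.copy(),
        is_inhibitory=inh,
        weights=weights,
    )


def build_structural_network(
    params: BuildParams, rng: np.random.Generator | int | None = None
) -> StructuralNetwork:
    """Run all four construction stages with the given parameters."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    net = build_regular_lattice(params.rows, params.cols, params.radius)
    net = rewire_small_world(net, params.p_rw, rng)
    net = reduce_recurrence(net, params.p_r, params.p_d, rng)
    net = assign_types_and_weights(
        net,
        params.inhibitory_fraction,
        rng,
        weight_mean=params.weight_mean,
        weight_sd=params.weight_sd,
        v_inh=params.v_inh,
    )
    return replace(net, rng_seed=seed if seed is None else int(seed))
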