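"""Randomised null ensembles and transformation Z-scores.

Two null models quantify how nonrandomly the functional layer follows the
structural layer:

* **Structure randomisation** (null model one): the structural layer is
  relabelled by a uniform vertex permutation and further randomised by
  double-edge swaps that preserve the in-, out- and recurrent-degree
  sequences. Recurrent (mutual) pairs are swapped as undirected units and
  unidirectional edges as source/sink-preserving ordered pairs; an attempt
  that mixes the two kinds, touches fewer than four distinct vertices, or
  would create a duplicate or new mutual edge is discarded. Each sample is
  paired with the *fixed* functional layer.

* **Discrepancy randomisation** (null model two): a surrogate functional
  layer is built by copying the structural layer, deleting as many
  uniformly chosen structural edges as there are false negatives and
  adding as many uniformly chosen structural non-edges as there are false
  positives. Each sample is paired with the *fixed* structural layer.

For every transformation class the ensemble mean ``mu`` and population
standard deviation ``sigma`` over ``N`` samples give the Z-score
``Z = (observed - mu) / sigma``; cells with ``sigma == 0`` are flagged
undefined unless the observed count equals ``mu`` exactly (then ``Z = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multiplex import MultiplexNetwork, dyadic_census, triadic_census

__all__ = [
    "NullEnsemble",
    "ZScoreTable",
    "randomize_structure",
    "randomize_discrepancies",
    "structure_null_ensemble",
    "discrepancy_null_ensemble",
    "zscores",
]


@dataclass
class NullEnsemble:
    """Per-transformation count samples from one null model.

    ``counts`` has the sample axis first (``(N, 10)`` dyadic or
    ``(N, 16, 16)`` triadic); ``mu`` and ``sigma`` are the per-cell mean
    and population SD over the ``N`` samples.
    """

    kind: str  # "structure" | "discrepancy"
    counts: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def from_counts(cls, kind: str, counts: np.ndarray) -> "NullEnsemble":
        counts = np.asarray(counts)
        if counts.shape[0] < 2:
            raise ValueError("an ensemble needs at least two samples")
        return cls(
            kind=kind,
            counts=counts,
            mu=counts.mean(axis=0),
            sigma=counts.std(axis=0),
        )


@dataclass
class ZScoreTable:
    """Z-scores with a defined-flag mask (undefined cells are NaN)."""

    z: np.ndarray
    defined: np.ndarray
    observed: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


def _degree_arrays(adj: np.ndarray):
    a = adj.astype(bool)
    mutual = a & a.T
    uni = a & ~a.T
    return mutual, uni


def randomize_structure(
    structural,
    rng: np.random.Generator,
    n_iterations: int = 100,
    permute: bool = True,
) -> np.ndarray:
    """One degree-preserving randomisation of a structural adjacency matrix.

    A uniform vertex permutation (optional, on by default) is followed by
    ``n_iterations`` double-edge-swap *attempts*; invalid attempts are
    discarded without retry. The in-, out- and recurrent-degree sequences
    of the result match the input's up to the permutation.
    """
    adj = np.asarray(getattr(structural, "adjacency", structural), dtype=np.uint8).copy()
    n = adj.shape[0]
    if permute:
        p = rng.permutation(n)
        adj = adj[np.ix_(p, p)]
    mutual, uni = _degree_arrays(adj)
    iu = np.triu_indices(n, k=1)
    rec_pairs = [
        [int(a), int(b)] for a, b in zip(iu[0][mutual[iu]], iu[1][mutual[iu]])
    ]
    # ordered (source, target): uni[t, s] means edge s -> t
    uni_t, uni_s = np.nonzero(uni)
    uni_edges = [[int(s), int(t)] for s, t in zip(uni_s, uni_t)]
    n_rec = len(rec_pairs)
    n_uni = len(uni_edges)
    total = n_rec + n_uni
    if total < 2:
        return adj

    def any_edge(a: int, b: int) -> bool:
        # pair-level occupancy, orientation-agnostic
        return bool(adj[a, b] or adj[b, a])

    for _ in range(n_iterations):
        x = int(rng.integers(total))
        y = int(rng.integers(total))
        if x == y:
            continue
        if x < n_rec and y < n_rec:
            pair1, pair2 = rec_pairs[x], rec_pairs[y]
            # unbiased orientation of each undirected unit
            a, b = (pair1 if rng.random() < 0.5 else pair1[::-1])
            c, d = (pair2 if rng.random() < 0.5 else pair2[::-1])
            if len({a, b, c, d}) < 4:
                continue
            # proposed units {c, b} and {a, d} must be fresh in both directions
            if any_edge(c, b) or any_edge(a, d):
                continue
            for u, v in ((a, b), (c, d)):
                adj[u, v] = adj[v, u] = 0
            for u, v in ((c, b), (a, d)):
                adj[u, v] = adj[v, u] = 1
            rec_pairs[x] = [c, b]
            rec_pairs[y] = [a, d]
        elif x >= n_rec and y >= n_rec:
            (a, b) = uni_edges[x - n_rec]
            (c, d) = uni_edges[y - n_rec]
            if len({a, b, c, d}) < 4:
                continue
            # swap sources: (a, b), (c, d) -> (c, b), (a, d); reject if either
            # slot is occupied in any direction (would duplicate or create a
            # mutual pair, breaking the recurrent-degree sequence)
            if any_edge(c, b) or any_edge(a, d):
                continue
            adj[b, a] = 0
            adj[d, c] = 0
            adj[b, c] = 1
            adj[d, a] = 1
            uni_edges[x - n_rec] = [c, b]
            uni_edges[y - n_rec] = [a, d]
        # mixed kinds: attempt discarded
    return adj


def randomize_discrepancies(
    structural, n_fp: int, n_fn: int, rng: np.random.Generator
) -> np.ndarray:
    """Surrogate functional layer with randomly placed FPs and FNs.

    Copies the structural adjacency, deletes ``n_fn`` uniformly chosen
    directed edges and adds ``n_fp`` uniformly chosen absent ordered pairs
    (off-diagonal, never on an existing structural edge).
    """
    adj = np.asarray(getattr(structural, "adjacency", structural), dtype=np.uint8).copy()
    n = adj.shape[0]
    tgt, src = np.nonzero(adj)
    n_edges = len(tgt)
    off_diag = n * (n - 1)
    if n_fn > n_edges:
        raise ValueError(f"cannot delete {n_fn} edges from a {n_edges}-edge layer")
    if n_fp > off_diag - n_edges:
        raise ValueError(f"cannot add {n_fp} edges: only {off_diag - n_edges} free slots")
    if n_fn > 0:
        drop = rng.choice(n_edges, size=n_fn, replace=False)
        adj[tgt[drop], src[drop]] = 0
    if n_fp > 0:
        free = np.asarray(
            np.nonzero((np.asarray(getattr(structural, "adjacency", structural)) == 0)
                       & ~np.eye(n, dtype=bool))
        ).T
        pick = rng.choice(len(free), size=n_fp, replace=False)
        adj[free[pick, 0], free[pick, 1]] = 1
    return adj


def _census_counts(s_adj: np.ndarray, f_adj: np.ndarray, which: str) -> np.ndarray:
    m = MultiplexNetwork(structural=s_adj, functional=f_adj)
    return dyadic_census(m) if which == "dyadic" else triadic_census(m)


def structure_null_ensemble(
    structural,
    functional,
    n_samples: int,
    rng: np.random.Generator,
    n_iterations: int = 100,
    which: str = "dyadic",
    permute: bool = True,
) -> NullEnsemble:
    """Null model one: census counts over ``n_samples`` structure
    randomisations, each paired with the fixed functional layer."""
    s = np.asarray(getattr(structural, "adjacency", structural), dtype=np.uint8)
    f = np.asarray(getattr(functional, "adjacency", functional), dtype=np.uint8)
    counts = [
        _census_counts(
            randomize_structure(s, rng, n_iterations=n_iterations, permute=permute), f, which
        )
        for _ in range(n_samples)
    ]
    return NullEnsemble.from_counts("structure", np.stack(counts))


def discrepancy_null_ensemble(
    structural,
    n_fp: int,
    n_fn: int,
    n_samples: int,
    rng: np.random.Generator,
    which: str = "triadic",
) -> NullEnsemble:
    """Null model two: census counts over ``n_samples`` FP/FN
    randomisations, each paired with the fixed structural layer."""
    s = np.asarray(getattr(structural, "adjacency", structural), dtype=np.uint8)
    counts = [
        _census_counts(s, randomize_discrepancies(s, n_fp, n_fn, rng), which)
        for _ in range(n_samples)
    ]
    return NullEnsemble.from_counts("discrepancy", np.stack(counts))


def zscores(observed_counts: np.ndarray, ensemble: NullEnsemble) -> ZScoreTable:
    """Per-transformation Z-scores against an ensemble.

    ``sigma == 0`` cells are undefined (NaN) unless the observed count
    matches the ensemble mean, in which case ``Z = 0``.
    """
    observed = np.asarray(observed_counts, dtype=float)
    if observed.shape != ensemble.mu.shape:
        raise ValueError("observed counts and ensemble statistics differ in shape")
    sigma = ensemble.sigma
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - ensemble.mu) / sigma
    degenerate = sigma == 0
    z = np.where(degenerate & (observed == ensemble.mu), 0.0, z)
    z = np.where(degenerate & (observed != ensemble.mu), np.nan, z)
    return ZScoreTable(
        z=z,
        defined=np.isfinite(z),
        observed=observed,
        mu=ensemble.mu.copy(),
        sigma=sigma.copy(),
    )
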