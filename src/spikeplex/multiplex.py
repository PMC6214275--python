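"""Two-layer multiplex pairing of structural and functional networks and the
dyadic / triadic transformation census.

The multiplex network ``M = {S, F}`` shares one vertex set across a
structural layer ``S`` and a functional layer ``F``; its supra-adjacency is
the ``2n x 2n`` block matrix with the layer adjacencies on the diagonal and
identity off-diagonal blocks (interlayer edges join each vertex to its own
copy).

Subgraph classification (neuron types are deliberately ignored):

* dyads: 1 = empty, 2 = single directed edge, 3 = recurrent (mutual);
* triads: the 16 isomorphism classes of 3-vertex digraphs, numbered by the
  canonical representatives on vertices (x, y, z):

  ==  ============================  ==  ============================
   1  (empty)                        9  x>y, y>z, x>z (feed-forward)
   2  x>y                           10  x>y, y>z, z>x (cycle)
   3  x<>y                          11  x<>y, x<>z
   4  x>y, x>z (out-hub)            12  x<>y, z>x, z>y
   5  y>x, z>x (in-star)            13  x<>y, x>z, y>z
   6  x>y, y>z (chain)              14  x<>y, x>z, z>y
   7  x<>y, z>x                     15  x<>y, x>z, y<>z
   8  x<>y, x>z                     16  (all six edges)
  ==  ============================  ==  ============================

  The 64 labelled 3-vertex digraphs partition into these classes with
  sizes (1, 6, 3, 3, 3, 6, 6, 6, 6, 2, 3, 3, 3, 6, 6, 1).

A *transformation* is the pair (structural class, functional class) on the
same vertices. For dyads, reducing the 16 labelled state pairs by the
simultaneous vertex swap leaves 10 classes: the preservations 1->1, 2->2,
3->3, the direction reversal 2->2*, and six conversions. For triads all
16 x 16 = 256 ordered class pairs are counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "MultiplexNetwork",
    "DiscrepancySet",
    "DYAD_TRANSFORMATIONS",
    "build_multiplex",
    "classify_dyad",
    "classify_triad",
    "dyadic_census",
    "triadic_census",
    "edge_discrepancies",
    "TRIAD_CLASS_SIZES",
]

#: the ten dyadic transformation classes, in reporting order
DYAD_TRANSFORMATIONS: tuple[str, ...] = (
    "1->1",
    "1->2",
    "1->3",
    "2->1",
    "2->2",
    "2->2*",
    "2->3",
    "3->1",
    "3->2",
    "3->3",
)

#: labelled-digraph counts of the 16 triad classes (over the 64 graphs)
TRIAD_CLASS_SIZES: tuple[int, ...] = (1, 6, 3, 3, 3, 6, 6, 6, 6, 2, 3, 3, 3, 6, 6, 1)

# ordered vertex pairs backing the 6-bit triad edge code, bit b = pair _PAIRS[b]
_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))

# canonical representatives (edge lists, (a, b) meaning a -> b) for classes 1..16
_TRIAD_REPRESENTATIVES: tuple[tuple[tuple[int, int], ...], ...] = (
    (),
    ((0, 1),),
    ((0, 1), (1, 0)),
    ((0, 1), (0, 2)),
    ((1, 0), (2, 0)),
    ((0, 1), (1, 2)),
    ((0, 1), (1, 0), (2, 0)),
    ((0, 1), (1, 0), (0, 2)),
    ((0, 1), (1, 2), (0, 2)),
    ((0, 1), (1, 2), (2, 0)),
    ((0, 1), (1, 0), (0, 2), (2, 0)),
    ((0, 1), (1, 0), (2, 0), (2, 1)),
    ((0, 1), (1, 0), (0, 2), (1, 2)),
    ((0, 1), (1, 0), (0, 2), (2, 1)),
    ((0, 1), (1, 0), (0, 2), (1, 2), (2, 1)),
    ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)),
)


def _edges_to_code(edges) -> int:
    code = 0
    for a, b in edges:
        code |= 1 << _PAIRS.index((a, b))
    return code


def _permute_code(code: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for bit, (a, b) in enumerate(_PAIRS):
        if code >> bit & 1:
            out |= 1 << _PAIRS.index((perm[a], perm[b]))
    return out


def _canonical_code(code: int) -> int:
    return min(_permute_code(code, p) for p in itertools.permutations((0, 1, 2)))


def _build_triad_table() -> np.ndarray:
    canon_to_class: dict[int, int] = {}
    for label, edges in enumerate(_TRIAD_REPRESENTATIVES, start=1):
        canon_to_class[_canonical_code(_edges_to_code(edges))] = label
    table = np.zeros(64, dtype=np.int64)
    for code in range(64):
        table[code] = canon_to_class[_canonical_code(code)]
    return table


#: lookup from 6-bit triad edge code to class label 1..16
TRIAD_TABLE: np.ndarray = _build_triad_table()

# dyadic transformation lookup: state = a>b flag + 2 * b>a flag per layer
# (0 empty, 1 forward-only, 2 reverse-only, 3 mutual); combo = 4*s + f
_DYAD_STATE_CLASS = {0: 1, 1: 2, 2: 2, 3: 3}


def _build_dyad_transformation_table() -> np.ndarray:
    table = np.zeros(16, dtype=np.int64)
    for s in range(4):
        for f in range(4):
            if s in (0, 3):
                name = f"{_DYAD_STATE_CLASS[s]}->{_DYAD_STATE_CLASS[f]}"
            else:
                # canonicalise so the structural single edge points "forward";
                # swapping the vertices flips both layers' 1<->2 states
                fs = f
                if s == 2:
                    fs = {0: 0, 1: 2, 2: 1, 3: 3}[f]
                name = {0: "2->1", 1: "2->2", 2: "2->2*", 3: "2->3"}[fs]
            table[4 * s + f] = DYAD_TRANSFORMATIONS.index(name)
    return table


_DYAD_TRANSFORMATION_TABLE: np.ndarray = _build_dyad_transformation_table()


@dataclass
class MultiplexNetwork:
    """Structural and functional adjacency over one vertex set.

    Both layers follow the ``adjacency[i, j] = edge j -> i`` convention.
    """

    structural: np.ndarray
    functional: np.ndarray

    def __post_init__(self) -> None:
        self.structural = np.asarray(self.structural, dtype=np.uint8)
        self.functional = np.asarray(self.functional, dtype=np.uint8)
        if self.structural.shape != self.functional.shape:
            raise ValueError("layers must share one vertex set")
        if self.structural.ndim != 2 or self.structural.shape[0] != self.structural.shape[1]:
            raise ValueError("layer adjacencies must be square")

    @property
    def n_neurons(self) -> int:
        return self.structural.shape[0]

    @property
    def supra(self) -> np.ndarray:
        """``2n x 2n`` supra-adjacency: structural vertices 0..n-1, functional
        copies n..2n-1, identity interlayer blocks."""
        n = self.n_neurons
        eye = np.eye(n, dtype=np.uint8)
        return np.block([[self.structural, eye], [eye, self.functional]])


@dataclass
class DiscrepancySet:
    """False positives / negatives as ordered ``(source, target)`` pairs."""

    false_positives: list[tuple[int, int]]
    false_negatives: list[tuple[int, int]]

    @property
    def n_fp(self) -> int:
        return len(self.false_positives)

    @property
    def n_fn(self) -> int:
        return len(self.false_negatives)


def build_multiplex(structural, functional) -> MultiplexNetwork:
    """Pair a structural and a functional layer (sizes must match)."""
    s = getattr(structural, "adjacency", structural)
    f = getattr(functional, "adjacency", functional)
    return MultiplexNetwork(structural=s, functional=f)


def classify_dyad(a_pair) -> int:
    """Dyad class of a 2x2 adjacency pattern: 1 empty, 2 single, 3 mutual."""
    a = np.asarray(a_pair)
    n_edges = int(a[0, 1] != 0) + int(a[1, 0] != 0)
    return n_edges + 1


def classify_triad(a_triple) -> int:
    """Triad class (1..16) of a 3x3 directed adjacency pattern.

    The pattern follows the package-wide ``a[i, j] = edge j -> i``
    convention (sources along columns). Classification is by
    canonical-form lookup: the 6-bit edge code is minimised over the 6
    vertex permutations and mapped through the representative table.
    """
    a = np.asarray(a_triple)
    code = 0
    for bit, (x, y) in enumerate(_PAIRS):
        if a[y, x]:  # edge x -> y under the adjacency[i, j] = j -> i convention
            code |= 1 << bit
    return int(TRIAD_TABLE[code])


def dyadic_census(m: MultiplexNetwork) -> np.ndarray:
    """Counts of the 10 dyadic transformation classes over all unordered pairs.

    Order follows :data:`DYAD_TRANSFORMATIONS`; counts sum to ``C(n, 2)``.
    """
    s, f = m.structural, m.functional
    n = m.n_neurons
    iu, ju = np.triu_indices(n, k=1)  # pair (p, q) with p < q
    # edge p -> q lives at adjacency[q, p]
    s_state = s[ju, iu].astype(np.int64) + 2 * s[iu, ju].astype(np.int64)
    f_state = f[ju, iu].astype(np.int64) + 2 * f[iu, ju].astype(np.int64)
    combos = _DYAD_TRANSFORMATION_TABLE[4 * s_state + f_state]
    return np.bincount(combos, minlength=10)


@njit(cache=True)
def _triadic_census_kernel(s, f, table, out):
    n = s.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            sij = 1 if s[j, i] else 0
            sji = 2 if s[i, j] else 0
            fij = 1 if f[j, i] else 0
            fji = 2 if f[i, j] else 0
            for k in range(j + 1, n):
                cs = sij | sji
                if s[k, i]:
                    cs |= 4
                if s[i, k]:
                    cs |= 8
                if s[k, j]:
                    cs |= 16
                if s[j, k]:
                    cs |= 32
                cf = fij | fji
                if f[k, i]:
                    cf |= 4
                if f[i, k]:
                    cf |= 8
                if f[k, j]:
                    cf |= 16
                if f[j, k]:
                    cf |= 32
                out[table[cs] - 1, table[cf] - 1] += 1


def triadic_census(m: MultiplexNetwork) -> np.ndarray:
    """16 x 16 matrix of (structural class, functional class) triple counts.

    Cell ``[a-1, b-1]`` counts unordered vertex triples whose structural
    triad is class ``a`` and functional triad class ``b``; the 256 cells
    sum to ``C(n, 3)``.
    """
    out = np.zeros((16, 16), dtype=np.int64)
    _triadic_census_kernel(
        np.ascontiguousarray(m.structural),
        np.ascontiguousarray(m.functional),
        TRIAD_TABLE,
        out,
    )
    return out


def edge_discrepancies(m: MultiplexNetwork) -> DiscrepancySet:
    """False positives (functional-only edges) and false negatives
    (structural-only edges) as ordered ``(source, target)`` pairs."""
    s = m.structural.astype(bool)
    f = m.functional.astype(bool)
    fp_t, fp_s = np.nonzero(f & ~s)
    fn_t, fn_s = np.nonzero(s & ~f)
    return DiscrepancySet(
        false_positives=list(zip(fp_s.tolist(), fp_t.tolist())),
        false_negatives=list(zip(fn_s.tolist(), fn_t.tolist())),
    )
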