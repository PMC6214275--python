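"""Multiplex assembly, dyad/triad classification and the transformation census."""

import itertools

import networkx as nx
import numpy as np
import pytest

import spikeplex as sp
from spikeplex.multiplex import (
    DYAD_TRANSFORMATIONS,
    TRIAD_CLASS_SIZES,
    TRIAD_TABLE,
    _PAIRS,
)


def code_to_adjacency(code):
    """6-bit edge code -> 3x3 pattern in the adjacency[i, j] = j -> i convention."""
    a = np.zeros((3, 3), dtype=np.uint8)
    for bit, (x, y) in enumerate(_PAIRS):
        if code >> bit & 1:
            a[y, x] = 1
    return a


def nx_triad_label(code):
    """Independent oracle: classify one labelled 3-vertex digraph with
    networkx's triadic census (MAN notation)."""
    g = nx.DiGraph()
    g.add_nodes_from([0, 1, 2])
    for bit, (x, y) in enumerate(_PAIRS):
        if code >> bit & 1:
            g.add_edge(x, y)
    census = nx.triadic_census(g)
    (label,) = [k for k, v in census.items() if v == 1]
    return label


class TestMultiplexAssembly:
    def test_supra_block_structure(self):
        s = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=np.uint8)
        f = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=np.uint8)
        m = sp.build_multiplex(s, f)
        supra = m.supra
        assert supra.shape == (6, 6)
        np.testing.assert_array_equal(supra[:3, :3], s)
        np.testing.assert_array_equal(supra[3:, 3:], f)
        np.testing.assert_array_equal(supra[:3, 3:], np.eye(3, dtype=np.uint8))
        np.testing.assert_array_equal(supra[3:, :3], np.eye(3, dtype=np.uint8))

    def test_identical_layers(self):
        s = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        m = sp.build_multiplex(s, s)
        np.testing.assert_array_equal(m.supra[:2, :2], m.supra[2:, 2:])

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.build_multiplex(np.zeros((3, 3)), np.zeros((4, 4)))


class TestDyadClassification:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ([[0, 0], [0, 0]], 1),
            ([[0, 1], [0, 0]], 2),
            ([[0, 0], [1, 0]], 2),
            ([[0, 1], [1, 0]], 3),
        ],
    )
    def test_three_classes(self, pattern, expected):
        assert sp.classify_dyad(np.array(pattern)) == expected


class TestTriadClassification:
    def test_all_64_labelled_digraphs_partition_into_16_classes(self):
        labels = {sp.classify_triad(code_to_adjacency(c)) for c in range(64)}
        assert labels == set(range(1, 17))

    def test_class_sizes_match_oracle(self):
        sizes = np.bincount(TRIAD_TABLE, minlength=17)[1:]
        np.testing.assert_array_equal(sizes, TRIAD_CLASS_SIZES)

    def test_agrees_with_networkx_census(self):
        """Map each package class to a networkx MAN label via the class
        representatives, then check all 64 labelled digraphs agree."""
        man_of_class = {}
        for code in range(64):
            cls = int(TRIAD_TABLE[code])
            man = nx_triad_label(code)
            if cls in man_of_class:
                assert man_of_class[cls] == man, f"class {cls} split across MAN labels"
            else:
                man_of_class[cls] = man
        # the 16 classes map onto 16 distinct MAN labels (a bijection)
        assert len(set(man_of_class.values())) == 16

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = (rng.random((3, 3)) < 0.5).astype(np.uint8)
            np.fill_diagonal(a, 0)
            base = sp.classify_triad(a)
            for p in itertools.permutations(range(3)):
                pi = np.argsort(p)
                assert sp.classify_triad(a[np.ix_(pi, pi)]) == base

    def test_extremes(self):
        assert sp.classify_triad(np.zeros((3, 3), dtype=np.uint8)) == 1
        full = np.ones((3, 3), dtype=np.uint8)
        np.fill_diagonal(full, 0)
        assert sp.classify_triad(full) == 16

    def test_named_representatives(self):
        # out-hub x->y, x->z is class 4; in-star class 5; chain class 6
        hub = np.zeros((3, 3), dtype=np.uint8)
        hub[1, 0] = hub[2, 0] = 1
        assert sp.classify_triad(hub) == 4
        star = hub.T.copy()
        assert sp.classify_triad(star) == 5
        chain = np.zeros((3, 3), dtype=np.uint8)
        chain[1, 0] = chain[2, 1] = 1
        assert sp.classify_triad(chain) == 6


def random_multiplex(n, rng, p_s=0.2, p_f=0.2):
    s = (rng.random((n, n)) < p_s).astype(np.uint8)
    f = (rng.random((n, n)) < p_f).astype(np.uint8)
    np.fill_diagonal(s, 0)
    np.fill_diagonal(f, 0)
    return sp.build_multiplex(s, f)


class TestDyadicCensus:
    def test_ten_distinct_classes_under_simultaneous_swap(self):
        """Brute force over the 16 labelled (structural, functional) dyad
        state pairs: reduction by the simultaneous vertex swap leaves exactly
        10 orbits."""
        states = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (edge a->b, edge b->a)
        orbits = set()
        for s in states:
            for f in states:
                swapped = ((s[1], s[0]), (f[1], f[0]))
                orbits.add(min(((s, f), swapped)))
        assert len(orbits) == 10

    def test_preservation_only_when_layers_equal(self):
        rng = np.random.default_rng(1)
        s = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        np.fill_diagonal(s, 0)
        counts = sp.dyadic_census(sp.build_multiplex(s, s))
        nonzero = {DYAD_TRANSFORMATIONS[i] for i in np.nonzero(counts)[0]}
        assert nonzero <= {"1->1", "2->2", "3->3"}

    def test_counts_sum_to_pairs(self):
        rng = np.random.default_rng(2)
        m = random_multiplex(100, rng)
        assert sp.dyadic_census(m).sum() == 100 * 99 // 2

    def test_direction_reversal_detected(self):
        s = np.zeros((2, 2), dtype=np.uint8)
        s[1, 0] = 1  # structural edge 0 -> 1
        f = np.zeros((2, 2), dtype=np.uint8)
        f[0, 1] = 1  # functional edge 1 -> 0
        counts = sp.dyadic_census(sp.build_multiplex(s, f))
        assert counts[DYAD_TRANSFORMATIONS.index("2->2*")] == 1
        f2 = np.zeros((2, 2), dtype=np.uint8)
        f2[1, 0] = 1
        counts2 = sp.dyadic_census(sp.build_multiplex(s, f2))
        assert counts2[DYAD_TRANSFORMATIONS.index("2->2")] == 1


class TestTriadicCensus:
    def test_table_shape_and_conservation(self):
        rng = np.random.default_rng(3)
        m = random_multiplex(100, rng)
        table = sp.triadic_census(m)
        assert table.shape == (16, 16)
        assert table.sum() == 100 * 99 * 98 // 6

    def test_identical_layers_concentrate_on_diagonal(self):
        rng = np.random.default_rng(4)
        s = (rng.random((15, 15)) < 0.25).astype(np.uint8)
        np.fill_diagonal(s, 0)
        table = sp.triadic_census(sp.build_multiplex(s, s))
        assert table.sum() == np.trace(table)

    def test_structural_marginal_matches_networkx(self):
        """Summing the census over functional classes reproduces networkx's
        triadic census of the structural layer alone."""
        rng = np.random.default_rng(5)
        m = random_multiplex(20, rng)
        marginal = sp.triadic_census(m).sum(axis=1)
        g = nx.DiGraph()
        g.add_nodes_from(range(20))
        tgt, src = np.nonzero(m.structural)
        g.add_edges_from(zip(src.tolist(), tgt.tolist()))
        nx_census = nx.triadic_census(g)
        man_of_class = {int(TRIAD_TABLE[c]): nx_triad_label(c) for c in range(64)}
        for cls in range(1, 17):
            assert marginal[cls - 1] == nx_census[man_of_class[cls]]

    def test_census_invariant_under_simultaneous_relabelling(self):
        rng = np.random.default_rng(6)
        m = random_multiplex(15, rng)
        p = rng.permutation(15)
        m2 = sp.build_multiplex(
            m.structural[np.ix_(p, p)], m.functional[np.ix_(p, p)]
        )
        np.testing.assert_array_equal(sp.triadic_census(m), sp.triadic_census(m2))

    def test_adding_one_fp_edge_moves_exactly_n_minus_2_triples(self):
        """Adding one functional edge re-classifies exactly the n-2 triples
        (and the single pair) containing its endpoints."""
        rng = np.random.default_rng(7)
        n = 20
        m = random_multiplex(n, rng)
        f2 = m.functional.copy()
        empty = np.argwhere((f2 == 0) & ~np.eye(n, dtype=bool))
        i, j = empty[0]
        f2[i, j] = 1
        m2 = sp.build_multiplex(m.structural, f2)

        def per_triple_classes(mux):
            out = {}
            for a, b, c in itertools.combinations(range(n), 3):
                idx = np.ix_((a, b, c), (a, b, c))
                out[(a, b, c)] = (
                    sp.classify_triad(mux.structural[idx]),
                    sp.classify_triad(mux.functional[idx]),
                )
            return out

        before = per_triple_classes(m)
        after = per_triple_classes(m2)
        changed = [k for k in before if before[k] != after[k]]
        assert len(changed) == n - 2
        dy_delta = np.abs(sp.dyadic_census(m2) - sp.dyadic_census(m)).sum()
        assert dy_delta == 2  # one pair moves class

    def test_pair_marginals_consistent_with_dyadic_census(self):
        """Each unordered pair lies in n-2 triples: recomputing dyad-state
        counts from triple enumeration matches (n-2) x the dyadic census."""
        rng = np.random.default_rng(17)
        n = 20
        m = random_multiplex(n, rng)
        from_triples = np.zeros(10, dtype=int)
        for a, b, c in itertools.combinations(range(n), 3):
            for p, q in ((a, b), (a, c), (b, c)):
                idx = np.ix_((p, q), (p, q))
                sub = sp.build_multiplex(m.structural[idx], m.functional[idx])
                from_triples += sp.dyadic_census(sub)
        np.testing.assert_array_equal(from_triples, (n - 2) * sp.dyadic_census(m))


class TestDiscrepancies:
    def test_identical_layers_no_discrepancies(self):
        rng = np.random.default_rng(8)
        s = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        np.fill_diagonal(s, 0)
        d = sp.edge_discrepancies(sp.build_multiplex(s, s))
        assert d.n_fp == 0 and d.n_fn == 0

    def test_direct_set_difference(self):
        s = np.zeros((3, 3), dtype=np.uint8)
        s[1, 0] = 1  # structural 0 -> 1
        f = np.zeros((3, 3), dtype=np.uint8)
        f[1, 0] = 1  # functional 0 -> 1 (true positive)
        f[2, 1] = 1  # functional 1 -> 2 (false positive)
        d = sp.edge_discrepancies(sp.build_multiplex(s, f))
        assert d.false_positives == [(1, 2)]
        assert d.false_negatives == []

    def test_partition_of_functional_edges(self):
        rng = np.random.default_rng(9)
        m = random_multiplex(25, rng)
        d = sp.edge_discrepancies(m)
        tp = int((m.structural.astype(bool) & m.functional.astype(bool)).sum())
        assert d.n_fp + tp == int(m.functional.sum())
        assert d.n_fn + tp == int(m.structural.sum())
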