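"""Subgraph-class enumeration, canonicalization and identification."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import motifsync as ms
from motifsync.catalog import _NAMED_STRUCTURES


def _nx_isomorphism_class_count(k: int) -> int:
    """Independent oracle: count weakly-connected k-node digraph classes by
    pairwise networkx isomorphism tests within degree-sequence buckets."""
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    buckets = {}
    for mask in range(1 << len(pairs)):
        arcs = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
        g = nx.DiGraph()
        g.add_nodes_from(range(k))
        g.add_edges_from(arcs)
        if not nx.is_weakly_connected(g):
            continue
        key = (g.number_of_edges(),
               tuple(sorted((g.in_degree(v), g.out_degree(v)) for v in g)))
        reps = buckets.setdefault(key, [])
        if not any(nx.is_isomorphic(g, r) for r in reps):
            reps.append(g)
    return sum(len(v) for v in buckets.values())


@pytest.mark.parametrize("k,expected", [(2, 2), (3, 13), (4, 199)])
def test_class_count_matches_isomorphism_oracle(k, expected):
    cat = ms.enumerate_classes(k)
    assert len(cat) == expected
    assert _nx_isomorphism_class_count(k) == expected
    # deterministic order: by edge count, then canonical code
    keys = [(c.edge_count, c.canonical_code) for c in cat.classes]
    assert keys == sorted(keys)


def test_unsupported_sizes_rejected():
    with pytest.raises(ms.UnsupportedSizeError):
        ms.enumerate_classes(5)
    with pytest.raises(ms.UnsupportedSizeError):
        ms.enumerate_classes(1)


def test_canonical_form_invariant_under_relabeling():
    rng = np.random.default_rng(11)
    for _ in range(200):
        k = int(rng.integers(3, 5))
        pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
        while True:
            keep = rng.random(len(pairs)) < 0.5
            arcs = [p for p, kp in zip(pairs, keep) if kp]
            g = ms.DirectedGraph(k, arcs)
            if g.is_weakly_connected():
                break
        code = ms.canonical_form(g)
        perm = rng.permutation(k)
        assert ms.canonical_form(g.relabel(list(perm))) == code


@settings(derandomize=True, deadline=None, max_examples=150)
@given(data=st.data(), k=st.sampled_from([3, 4]))
def test_canonical_form_permutation_property(data, k):
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    arcs = data.draw(st.sets(st.sampled_from(pairs)))
    g = ms.DirectedGraph(k, arcs)
    perm = data.draw(st.permutations(range(k)))
    assert ms.canonical_form(g.relabel(list(perm))) == ms.canonical_form(g)


def test_canonical_form_separates_non_isomorphic():
    ffl = ms.DirectedGraph(3, [(0, 1), (0, 2), (1, 2)])
    cycle = ms.DirectedGraph(3, [(0, 1), (1, 2), (2, 0)])
    assert ms.canonical_form(ffl) != ms.canonical_form(cycle)
    cascade = ms.DirectedGraph(3, [(0, 1), (1, 2)])
    relabeled = ms.DirectedGraph(3, [(2, 1), (1, 0)])
    assert ms.canonical_form(cascade) == ms.canonical_form(relabeled)


def test_canonical_form_size_cap():
    big = ms.DirectedGraph(9, [(i, i + 1) for i in range(8)])
    with pytest.raises(ms.UnsupportedSizeError):
        ms.canonical_form(big)


def test_classify_named_classes(cat3):
    ffl = ms.DirectedGraph(3, [(0, 1), (0, 2), (1, 2)])
    assert cat3.classes[ms.classify(ffl, cat3)].name == "feedforward loop"
    cat2 = ms.enumerate_classes(2)
    dyad = ms.DirectedGraph(2, [(0, 1), (1, 0)])
    assert cat2.classes[ms.classify(dyad, cat2)].name == "mutual dyad"
    disconnected = ms.DirectedGraph(3, [(0, 1)])
    with pytest.raises(ms.NotConnectedError):
        ms.classify(disconnected, cat3)


def test_classify_invariant_under_permutation(cat3, cat4):
    rng = np.random.default_rng(5)
    for _ in range(300):
        k = int(rng.integers(3, 5))
        cat = cat3 if k == 3 else cat4
        cls = cat.classes[int(rng.integers(len(cat.classes)))]
        g = cls.representative()
        perm = rng.permutation(k)
        assert ms.classify(g.relabel(list(perm)), cat) == ms.classify(g, cat)


def test_all_named_structures_have_distinct_classes(cat3):
    codes = set()
    for name, (k, arcs) in _NAMED_STRUCTURES.items():
        if k != 3:
            continue
        codes.add(ms.canonical_form(ms.DirectedGraph(3, arcs)))
    assert len(codes) == 13  # the 13 named 3-node structures cover all classes


def test_density_classes_partition(cat3, cat4):
    d3 = ms.density_classes(cat3)
    assert {m: len(v) for m, v in d3.items()} == {2: 3, 3: 4, 4: 4, 5: 1, 6: 1}
    assert sum(len(v) for v in d3.values()) == 13
    d4 = ms.density_classes(cat4)
    assert sum(len(v) for v in d4.values()) == 199
    assert set(d4) == set(range(3, 13))  # 4-node classes span 3..12 arcs
    for m in (4, 5, 6):                  # groups used for density-controlled tests
        assert len(d4[m]) > 1


def test_assign_paper_ids_rank_and_ties(cat3):
    scores = np.linspace(1.0, 0.2, 13)
    labeled = ms.assign_paper_ids(cat3, scores)
    ids = [c.paper_id for c in labeled.classes]
    assert ids == list(range(1, 14))       # catalog order equals score order here
    # ties broken by ascending edge count, then canonical code
    tied = ms.assign_paper_ids(cat3, np.ones(13))
    order = sorted(range(13), key=lambda i: tied.classes[i].paper_id)
    keys = [(tied.classes[i].edge_count, tied.classes[i].canonical_code)
            for i in order]
    assert keys == sorted(keys)
    with pytest.raises(ValueError):
        ms.assign_paper_ids(cat3, np.ones(12))


def test_graph_validation():
    with pytest.raises(ValueError):
        ms.DirectedGraph(3, [(0, 0)])       # self-loop
    with pytest.raises(ValueError):
        ms.DirectedGraph(2, [(0, 2)])       # out of range
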