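"""Induced-subgraph census: per-class occurrence counts in a network.

The frequency of a subgraph class in a network is the number of k-node subsets
whose *induced* subgraph is weakly connected and belongs to that class; each
subset counts once (the standard motif-census convention, with no
symmetry-factor corrections).

Two independent routes are provided: :func:`count_subgraphs` enumerates
connected node subsets by neighborhood expansion (ESU) and classifies each
induced subgraph through a precomputed arc-bitmask table, while
:func:`census_oracle` iterates over every ``C(n, k)`` subset and classifies by
brute-force canonicalization.  The oracle exists for cross-checking and is
practical only for small networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .catalog import (Catalog, DirectedGraph, canonical_form,
                      _weakly_connected)

_ORACLE_MAX_NODES = 15


@dataclass
class CensusVector:
    """Per-class induced-subgraph counts for one network."""

    network_name: str
    size_k: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _ordered_pairs(k: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


_TABLE_CACHE: Dict[tuple, np.ndarray] = {}


def _mask_table(catalog: Catalog) -> np.ndarray:
    """Map every arc bitmask on k labeled nodes to its class index (-1 if the
    digraph is not weakly connected).  Cached per catalog content."""
    key = (catalog.size_k, tuple(c.canonical_code for c in catalog.classes))
    table = _TABLE_CACHE.get(key)
    if table is not None:
        return table
    k = catalog.size_k
    pairs = _ordered_pairs(k)
    table = np.full(1 << len(pairs), -1, dtype=np.int16)
    for mask in range(table.size):
        arcs = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
        if not _weakly_connected(k, arcs):
            continue
        code = canonical_form(DirectedGraph(k, arcs))
        table[mask] = catalog.lookup[code]
    _TABLE_CACHE[key] = table
    return table


def _undirected_neighbors(graph: DirectedGraph) -> List[Set[int]]:
    neigh: List[Set[int]] = [set() for _ in range(graph.node_count)]
    for s, t in graph.arcs:
        neigh[s].add(t)
        neigh[t].add(s)
    return neigh


def connected_subsets(graph: DirectedGraph, k: int):
    """Yield every weakly-connected k-node subset exactly once (sorted tuples).

    Neighborhood-expansion enumeration (ESU): grow each subset only with nodes
    larger than the root that are exclusive neighbors of the current subset,
    which makes every connected subset appear through a unique expansion path.
    """
    neigh = _undirected_neighbors(graph)

    def extend(sub: List[int], ext: Set[int], closed: Set[int], root: int):
        if len(sub) == k:
            yield tuple(sorted(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_closed = closed | neigh[w]
            new_ext = ext | {u for u in neigh[w]
                             if u > root and u not in closed}
            sub.append(w)
            yield from extend(sub, new_ext, new_closed, root)
            sub.pop()

    for v in range(graph.node_count):
        ext0 = {u for u in neigh[v] if u > v}
        yield from extend([v], ext0, {v} | neigh[v], v)


def count_subgraphs(graph: DirectedGraph, catalog: Catalog) -> CensusVector:
    """Count induced occurrences of every catalog class in the network."""
    k = catalog.size_k
    table = _mask_table(catalog)
    pairs = _ordered_pairs(k)
    arcset = graph.arcs
    counts = np.zeros(len(catalog.classes), dtype=np.int64)
    for nodes in connected_subsets(graph, k):
        mask = 0
        for b, (i, j) in enumerate(pairs):
            if (nodes[i], nodes[j]) in arcset:
                mask |= 1 << b
        idx = table[mask]
        # ESU yields only connected subsets, so idx is always a valid class
        counts[idx] += 1
    return CensusVector("", k, counts)


def census_oracle(graph: DirectedGraph, catalog: Catalog) -> CensusVector:
    """Brute-force census over all C(n, k) subsets (test oracle, n <= 15)."""
    if graph.node_count > _ORACLE_MAX_NODES:
        raise ValueError(
            f"census_oracle is limited to {_ORACLE_MAX_NODES} nodes")
    k = catalog.size_k
    counts = np.zeros(len(catalog.classes), dtype=np.int64)
    for nodes in combinations(range(graph.node_count), k):
        node_pos = {v: i for i, v in enumerate(nodes)}
        arcs = [(node_pos[s], node_pos[t]) for s, t in graph.arcs
                if s in node_pos and t in node_pos]
        if not _weakly_connected(k, arcs):
            continue
        code = canonical_form(DirectedGraph(k, arcs))
        counts[catalog.lookup[code]] += 1
    return CensusVector("", k, counts)


def frequency_ranking(census: CensusVector,
                      catalog: Optional[Catalog] = None) -> List[int]:
    """Class indices sorted by descending count.

    Ties are broken by ascending conventional ID when the catalog carries
    IDs, otherwise by catalog position.
    """
    def tie_key(i: int) -> int:
        if catalog is not None and catalog.classes[i].paper_id is not None:
            return catalog.classes[i].paper_id
        return i

    return sorted(range(len(census.counts)),
                  key=lambda i: (-census.counts[i], tie_key(i)))
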