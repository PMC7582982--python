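"""Isomorphism classes of small weakly-connected directed graphs.

Directed subgraphs on two to four nodes are reduced to isomorphism classes
("subgraph classes"): topologically identical arrangements of arcs count as one
class.  There are 2 such classes on two nodes, 13 on three nodes and 199 on
four nodes.  Canonicalization is brute force over node permutations, which is
exact and fast at these sizes.

Classes carry a deterministic catalog order (by arc count, then canonical
code).  The 1-based IDs used when reporting results are a separate labeling
assigned by descending synchronizability (SM) score; see
:func:`assign_paper_ids`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("motifsync")

Arc = Tuple[int, int]

#: supported subgraph sizes for class enumeration
SUPPORTED_SIZES = (2, 3, 4)

_MAX_CANON_NODES = 8


class UnsupportedSizeError(ValueError):
    """Subgraph size outside the supported range."""


class NotConnectedError(ValueError):
    """Graph is not weakly connected where connectivity is required."""


@dataclass(frozen=True)
class DirectedGraph:
    """A simple directed graph: no self-loops, no duplicate arcs.

    Parameters
    ----------
    node_count
        Number of nodes; node indices run from 0 to ``node_count - 1``.
    arcs
        Set of ordered (source, target) pairs.
    """

    node_count: int
    arcs: frozenset[Arc]

    def __init__(self, node_count: int, arcs: Iterable[Arc]):
        arcs = frozenset((int(s), int(t)) for s, t in arcs)
        if node_count < 1:
            raise ValueError("node_count must be positive")
        for s, t in arcs:
            if s == t:
                raise ValueError(f"self-loop on node {s} not allowed")
            if not (0 <= s < node_count and 0 <= t < node_count):
                raise ValueError(f"arc ({s}, {t}) outside [0, {node_count})")
        object.__setattr__(self, "node_count", int(node_count))
        object.__setattr__(self, "arcs", arcs)

    @property
    def arc_count(self) -> int:
        return len(self.arcs)

    def in_neighbors(self, node: int) -> frozenset[int]:
        return frozenset(s for s, t in self.arcs if t == node)

    def out_neighbors(self, node: int) -> frozenset[int]:
        return frozenset(t for s, t in self.arcs if s == node)

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean matrix A with A[s, t] = True iff arc s -> t exists."""
        a = np.zeros((self.node_count, self.node_count), dtype=bool)
        for s, t in self.arcs:
            a[s, t] = True
        return a

    def relabel(self, mapping: Sequence[int]) -> "DirectedGraph":
        """Return the graph with node i renamed to ``mapping[i]``."""
        return DirectedGraph(self.node_count,
                             ((mapping[s], mapping[t]) for s, t in self.arcs))

    def is_weakly_connected(self) -> bool:
        return _weakly_connected(self.node_count, self.arcs)


def _weakly_connected(n: int, arcs: Iterable[Arc]) -> bool:
    if n == 1:
        return True
    neigh: List[set] = [set() for _ in range(n)]
    for s, t in arcs:
        neigh[s].add(t)
        neigh[t].add(s)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in neigh[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


def canonical_form(graph: DirectedGraph) -> Tuple[Arc, ...]:
    """Canonical code of a directed graph under node relabeling.

    The code is the lexicographically smallest sorted arc tuple over all
    ``node_count!`` relabelings, so isomorphic graphs (and only those) share a
    code.  Brute force is the contract; inputs are capped at 8 nodes.
    """
    n = graph.node_count
    if n > _MAX_CANON_NODES:
        raise UnsupportedSizeError(
            f"canonical_form is brute-force and limited to {_MAX_CANON_NODES} "
            f"nodes, got {n}")
    arcs = graph.arcs
    best: Optional[Tuple[Arc, ...]] = None
    for perm in permutations(range(n)):
        code = tuple(sorted((perm[s], perm[t]) for s, t in arcs))
        if best is None or code < best:
            best = code
    assert best is not None
    return best


def code_str(code: Tuple[Arc, ...]) -> str:
    """Compact text form of a canonical code, e.g. ``"0>1,0>2,1>2"``."""
    return ",".join(f"{s}>{t}" for s, t in code)


# -- named three-node classes ------------------------------------------------
#
# Anchors used throughout: the feedforward loop {A->B, A->C, B->C}, the
# three-node feedback loop (directed 3-cycle), the cascade (two-link chain),
# mutual-dyad variants, the semi-clique (clique minus one arc) and the clique.
_NAMED_STRUCTURES: Dict[str, Tuple[int, Tuple[Arc, ...]]] = {
    "arc": (2, ((0, 1),)),
    "mutual dyad": (2, ((0, 1), (1, 0))),
    "in-star": (3, ((0, 2), (1, 2))),
    "out-star": (3, ((0, 1), (0, 2))),
    "cascade": (3, ((0, 1), (1, 2))),
    "feedforward loop": (3, ((0, 1), (0, 2), (1, 2))),
    "feedback loop": (3, ((0, 1), (1, 2), (2, 0))),
    "mutual-in": (3, ((0, 1), (1, 0), (2, 0))),
    "mutual-out": (3, ((0, 1), (1, 0), (0, 2))),
    "regulated mutual": (3, ((0, 1), (1, 0), (2, 0), (2, 1))),
    "regulating mutual": (3, ((0, 1), (1, 0), (0, 2), (1, 2))),
    "mutual cascade": (3, ((0, 1), (1, 0), (1, 2), (2, 0))),
    "double mutual": (3, ((0, 1), (1, 0), (1, 2), (2, 1))),
    "semi-clique": (3, ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0))),
    "clique": (3, ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))),
}


@dataclass
class SubgraphClass:
    """One isomorphism class of a weakly-connected k-node directed graph."""

    size_k: int
    canonical_code: Tuple[Arc, ...]
    edge_count: int
    name: Optional[str] = None
    paper_id: Optional[int] = None

    def representative(self) -> DirectedGraph:
        """A concrete graph of this class (the canonical representative)."""
        return DirectedGraph(self.size_k, self.canonical_code)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = self.name or code_str(self.canonical_code)
        return f"SubgraphClass(k={self.size_k}, m={self.edge_count}, {label!r})"


@dataclass
class Catalog:
    """All weakly-connected k-node subgraph classes, in deterministic order."""

    size_k: int
    classes: List[SubgraphClass]
    lookup: Dict[Tuple[Arc, ...], int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.lookup:
            self.lookup = {c.canonical_code: i for i, c in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.classes)

    def index_of_name(self, name: str) -> int:
        for i, c in enumerate(self.classes):
            if c.name == name:
                return i
        raise KeyError(name)


def enumerate_classes(size_k: int) -> Catalog:
    """Enumerate every weakly-connected directed subgraph class on k nodes.

    Iterates all ``2^(k(k-1))`` arc subsets, keeps the weakly connected ones,
    and buckets them by canonical form.  Classes are ordered by (edge count,
    canonical code).  Yields 2 classes for k=2, 13 for k=3 and 199 for k=4.
    """
    if size_k not in SUPPORTED_SIZES:
        raise UnsupportedSizeError(
            f"size_k must be one of {SUPPORTED_SIZES}, got {size_k}")
    pairs = [(i, j) for i in range(size_k) for j in range(size_k) if i != j]
    seen: Dict[Tuple[Arc, ...], int] = {}
    for mask in range(1 << len(pairs)):
        arcs = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
        if not _weakly_connected(size_k, arcs):
            continue
        code = canonical_form(DirectedGraph(size_k, arcs))
        seen.setdefault(code, len(arcs))
    ordered = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
    classes = [SubgraphClass(size_k, code, m) for code, m in ordered]
    by_code = {c.canonical_code: c for c in classes}
    for name, (k, arcs) in _NAMED_STRUCTURES.items():
        if k != size_k:
            continue
        code = canonical_form(DirectedGraph(k, arcs))
        by_code[code].name = name
    logger.debug("enumerated %d classes for k=%d", len(classes), size_k)
    return Catalog(size_k, classes)


def classify(graph: DirectedGraph, catalog: Catalog) -> int:
    """Index of the catalog class the graph belongs to.

    The graph must be weakly connected and have exactly ``catalog.size_k``
    nodes.
    """
    if graph.node_count != catalog.size_k:
        raise ValueError(
            f"graph has {graph.node_count} nodes, catalog is for "
            f"k={catalog.size_k}")
    if not graph.is_weakly_connected():
        raise NotConnectedError("graph is not weakly connected")
    return catalog.lookup[canonical_form(graph)]


def density_classes(catalog: Catalog) -> Dict[int, List[int]]:
    """Partition class indices by arc count (the "density classes")."""
    out: Dict[int, List[int]] = {}
    for i, c in enumerate(catalog.classes):
        out.setdefault(c.edge_count, []).append(i)
    return dict(sorted(out.items()))


def assign_paper_ids(catalog: Catalog, sm_scores: Sequence[float]) -> Catalog:
    """Label classes 1..N by descending SM score.

    The conventional subgraph numbering orders classes from the most to the
    least synchronizable, so ID 1 is the class with the largest SM score.
    Ties are broken by ascending edge count, then canonical code, for
    reproducible IDs under reruns.
    """
    scores = np.asarray(sm_scores, dtype=float)
    if scores.shape != (len(catalog.classes),):
        raise ValueError(
            f"expected {len(catalog.classes)} scores, got {scores.shape}")
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i], catalog.classes[i].edge_count,
                       catalog.classes[i].canonical_code))
    classes = [SubgraphClass(c.size_k, c.canonical_code, c.edge_count, c.name,
                             None) for c in catalog.classes]
    for rank, i in enumerate(order, start=1):
        classes[i].paper_id = rank
    return Catalog(catalog.size_k, classes)
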