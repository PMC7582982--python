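"""Self-contained synthetic networks for testing and demonstrations.

Provides seed-deterministic Erdős–Rényi G(n, m) draws, planted-motif overlays
(known minimum class counts by construction), and a handful of tiny named
networks: the four reference three-node subgraphs used in the dynamics
illustrations (feedforward loop, mutual-in, mutual cascade, clique) plus the
cascade, the three-node feedback loop, the semi-clique and a 10-node toy
network shipped as a matching DSM / edge-list file pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .catalog import DirectedGraph, SubgraphClass, _NAMED_STRUCTURES
from .netio import NetworkRecord, write_dsm, write_edgelist


class CapacityError(ValueError):
    """Requested arcs or placements exceed what the graph can hold."""


def er_graph(node_count: int, arc_count: int,
             rng: np.random.Generator) -> DirectedGraph:
    """Uniform simple digraph with exactly ``arc_count`` arcs, no self-loops.

    Ordered pairs are drawn uniformly without replacement, so mutual arcs are
    allowed but duplicates are not.
    """
    capacity = node_count * (node_count - 1)
    if not 0 <= arc_count <= capacity:
        raise CapacityError(
            f"arc_count must be in [0, {capacity}] for {node_count} nodes, "
            f"got {arc_count}")
    chosen = rng.choice(capacity, size=arc_count, replace=False)
    arcs = []
    for idx in chosen:
        s, r = divmod(int(idx), node_count - 1)
        t = r if r < s else r + 1
        arcs.append((s, t))
    return DirectedGraph(node_count, arcs)


def _labels(n: int) -> List[str]:
    return [f"v{i}" for i in range(n)]


def gen_er(node_count: int, arc_count: int, seed: int,
           name: Optional[str] = None) -> NetworkRecord:
    """Seeded Erdős–Rényi G(n, m) network record."""
    rng = np.random.default_rng(seed)
    graph = er_graph(node_count, arc_count, rng)
    return NetworkRecord(name or f"er_{node_count}_{arc_count}_{seed}",
                         _labels(node_count), graph)


def plant_motifs(base: NetworkRecord, cls: SubgraphClass, copies: int,
                 seed: int) -> NetworkRecord:
    """Overlay ``copies`` instances of a subgraph class on disjoint node sets.

    Node sets are chosen by a seeded permutation of the base nodes, so the
    resulting census count of the planted class is at least ``copies`` (exact
    when the base graph is empty).  ``copies = 0`` returns an identical copy.
    """
    k = cls.size_k
    n = base.graph.node_count
    if copies * k > n:
        raise CapacityError(
            f"{copies} disjoint placements of a {k}-node class need "
            f"{copies * k} nodes, base has {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    arcs = set(base.graph.arcs)
    for c in range(copies):
        nodes = perm[c * k:(c + 1) * k]
        arcs.update((int(nodes[s]), int(nodes[t]))
                    for s, t in cls.canonical_code)
    return NetworkRecord(f"{base.name}+{copies}x{cls.name or 'motif'}",
                         list(base.node_labels), DirectedGraph(n, arcs))


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic network."""

    kind: str                      # "er", "planted" or "named"
    name: str = ""
    node_count: int = 0
    arc_count: int = 0
    planted_name: str = ""
    copies: int = 0
    seed: int = 0


_NAMED_FIXTURES = ("ffl", "mutual_in", "mutual_cascade", "clique3",
                   "cascade", "cycle3", "semi_clique", "toy10")

_NAME_TO_STRUCTURE = {
    "ffl": "feedforward loop",
    "mutual_in": "mutual-in",
    "mutual_cascade": "mutual cascade",
    "clique3": "clique",
    "cascade": "cascade",
    "cycle3": "feedback loop",
    "semi_clique": "semi-clique",
}


def named_fixture(name: str) -> NetworkRecord:
    """One named tiny network (see :data:`_NAMED_FIXTURES`)."""
    if name == "toy10":
        # fixed 10-node toy network used for the DSM / edge-list file pair
        rng = np.random.default_rng(2020)
        return NetworkRecord("toy10", _labels(10), er_graph(10, 18, rng))
    structure = _NAME_TO_STRUCTURE.get(name)
    if structure is None:
        raise KeyError(f"unknown fixture {name!r}; known: {_NAMED_FIXTURES}")
    k, arcs = _NAMED_STRUCTURES[structure]
    labels = ["A", "B", "C", "D"][:k]
    return NetworkRecord(name, labels, DirectedGraph(k, arcs))


def named_fixtures() -> List[NetworkRecord]:
    """All named tiny networks."""
    return [named_fixture(n) for n in _NAMED_FIXTURES]


def generate(spec: FixtureSpec) -> NetworkRecord:
    """Build a network from a :class:`FixtureSpec`."""
    if spec.kind == "er":
        return gen_er(spec.node_count, spec.arc_count, spec.seed,
                      name=spec.name or None)
    if spec.kind == "named":
        return named_fixture(spec.name)
    if spec.kind == "planted":
        from .catalog import canonical_form, enumerate_classes
        structure = _NAME_TO_STRUCTURE.get(spec.planted_name,
                                           spec.planted_name)
        k, arcs = _NAMED_STRUCTURES[structure]
        cat = enumerate_classes(k)
        cls = cat.classes[cat.lookup[canonical_form(DirectedGraph(k, arcs))]]
        base = gen_er(spec.node_count, spec.arc_count, spec.seed,
                      name=spec.name or None)
        return plant_motifs(base, cls, spec.copies, spec.seed + 1)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def write_fixture_bundle(outdir) -> Dict[str, List[str]]:
    """Write every named fixture as edge-list TSV and DSM CSV files.

    Returns a map from fixture name to the written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, List[str]] = {}
    for record in named_fixtures():
        edge_path = outdir / f"{record.name}.edges.tsv"
        dsm_path = outdir / f"{record.name}.dsm.csv"
        write_edgelist(record, edge_path)
        write_dsm(record, dsm_path)
        written[record.name] = [str(edge_path), str(dsm_path)]
    return written
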