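"""Shared fixtures and independent oracles.

The exact oracle evaluates the open/closed dynamics on tiny graphs by matrix
iteration of the full 2^n-state Markov chain, and integrates the resulting
synchronization probability over the (beta, delta) unit square by
Gauss-Legendre quadrature.  It shares no code with the Monte-Carlo kernel.
"""

from __future__ import annotations

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

import motifsync as ms


@pytest.fixture(scope="session")
def cat3() -> ms.Catalog:
    return ms.enumerate_classes(3)


@pytest.fixture(scope="session")
def cat4() -> ms.Catalog:
    return ms.enumerate_classes(4)


def exact_sync_probability(graph: ms.DirectedGraph, beta: float, delta: float,
                           iterations: int) -> float:
    """Probability of reaching all-closed within T single-node updates,
    starting all-open, by exact Markov-chain iteration (n <= ~12 nodes)."""
    n = graph.node_count
    infl = ms.influence_matrix(graph)
    nstates = 1 << n
    transition = np.zeros((nstates, nstates))
    for s in range(nstates):       # bit j set <=> node j open
        for node in range(n):
            k = sum(1 for j in range(n) if infl[node, j] and (s >> j & 1))
            escape = (1.0 - beta) ** k
            if s >> node & 1:
                p_close = escape * delta
                transition[s, s & ~(1 << node)] += p_close / n
                transition[s, s] += (1.0 - p_close) / n
            else:
                p_open = 1.0 - escape
                transition[s, s | (1 << node)] += p_open / n
                transition[s, s] += (1.0 - p_open) / n
    v = np.zeros(nstates)
    v[nstates - 1] = 1.0           # all-open start
    for _ in range(iterations):
        v = v @ transition
    return float(v[0])             # all-closed is absorbing


def exact_sm(graph: ms.DirectedGraph, iterations: int = 120,
             quadrature_order: int = 24) -> float:
    """SM score as the exact integral of the synchronization probability over
    (beta, delta) ~ Uniform(0,1)^2 (Gauss-Legendre quadrature)."""
    x, w = leggauss(quadrature_order)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    return float(sum(
        w[i] * w[j] * exact_sync_probability(graph, x[i], x[j], iterations)
        for i in range(quadrature_order) for j in range(quadrature_order)))


@pytest.fixture(scope="session")
def exact_sm3(cat3) -> np.ndarray:
    """Exact SM score per 3-node class (catalog order), T = 120."""
    return np.array([exact_sm(c.representative()) for c in cat3.classes])


def named_graph(name: str) -> ms.DirectedGraph:
    return ms.named_fixture(name).graph
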