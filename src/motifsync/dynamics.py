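"""Stochastic open/closed dynamics of collective problem-solving on a digraph.

Each node of a directed network is a subproblem that is either *open*
(unresolved) or *closed* (resolved).  At each time step a single node is
picked uniformly at random and updated:

* a **closed** node reopens with probability ``1 - (1 - beta)^k`` where ``k``
  is its number of open in-neighbors — each open upstream subproblem
  independently forces a reopening with probability ``beta``;
* an **open** node closes with probability ``(1 - beta)^k * delta`` — it must
  escape the influence of every open in-neighbor (each with probability
  ``1 - beta``) and then resolve itself in a self-directed way (probability
  ``delta``).

The all-closed configuration ("full synchronization") is absorbing: once every
node is closed, no node has an open in-neighbor, so nothing can reopen.

Two parameters govern the process: the reopening probability ``beta`` and the
self-directed probability ``delta``, assumed homogeneous across nodes.  Time
is counted in single-node updates ("iterations"); one sweep of an n-node
network is n iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .catalog import DirectedGraph

OPEN = 0
CLOSED = 1

_INITIAL_POLICIES = ("open", "closed", "random")


@dataclass(frozen=True)
class ModelParams:
    """Dynamics parameters: reopening probability and self-directed probability."""

    beta: float
    delta: float

    def __post_init__(self):
        for name in ("beta", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Monte-Carlo protocol sizes and the initial-state policy.

    ``iterations_T`` counts single-node updates.  The default initial state is
    all-open: the study simulates solving the whole problem from scratch.
    """

    iterations_T: int = 120
    realizations_R: int = 100
    initial_state: str = "open"
    seed: int = 0
    undirected_influence: bool = False

    def __post_init__(self):
        if self.iterations_T < 1 or self.realizations_R < 1:
            raise ValueError("iterations_T and realizations_R must be >= 1")
        if self.initial_state not in _INITIAL_POLICIES:
            raise ValueError(f"initial_state must be one of {_INITIAL_POLICIES}")


@dataclass
class Trajectory:
    """Per-step fraction of closed nodes of one realization."""

    fractions: np.ndarray          # fraction closed after step t; index 0 = start
    synchronized: bool
    first_sync_step: Optional[int]  # step index of first full synchronization

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)


def influence_matrix(graph: DirectedGraph,
                     undirected: bool = False) -> np.ndarray:
    """Boolean matrix M with M[i, j] = True iff node j influences node i.

    By default the influence set of a node is its in-neighborhood — open
    upstream subproblems push new information downstream along arcs.  The
    undirected variant treats any arc as an influence channel.
    """
    a = graph.adjacency_matrix()
    return (a | a.T) if undirected else a.T


def _initial_open(policy: str, n: int, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """(size, n) boolean array; True = open."""
    if policy == "open":
        return np.ones((size, n), dtype=bool)
    if policy == "closed":
        return np.zeros((size, n), dtype=bool)
    return rng.random((size, n)) < 0.5


def step(state: np.ndarray, graph: DirectedGraph, params: ModelParams,
         rng: np.random.Generator,
         undirected_influence: bool = False) -> np.ndarray:
    """One single-node update; returns the new state vector.

    ``state`` holds ``OPEN``/``CLOSED`` per node.  One node is chosen
    uniformly; all other nodes are unchanged.
    """
    state = np.asarray(state)
    n = graph.node_count
    if state.shape != (n,):
        raise ValueError(f"state must have shape ({n},)")
    node = int(rng.integers(n))
    infl = graph.in_neighbors(node)
    if undirected_influence:
        infl = infl | graph.out_neighbors(node)
    k_open = sum(1 for j in infl if state[j] == OPEN)
    escape = (1.0 - params.beta) ** k_open
    u = rng.random()
    new = state.copy()
    if state[node] == CLOSED:
        if u < 1.0 - escape:
            new[node] = OPEN
    else:
        if u < escape * params.delta:
            new[node] = CLOSED
    return new


def run(graph: DirectedGraph, params: ModelParams,
        config: SimulationConfig,
        rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Simulate one realization for up to T single-node updates.

    Stops early once all nodes are closed (the absorbing configuration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = graph.node_count
    open_ = _initial_open(config.initial_state, n, 1, rng)[0]
    infl = influence_matrix(graph, config.undirected_influence)
    fractions: List[float] = [1.0 - open_.mean()]
    first_sync: Optional[int] = None if open_.any() else 0
    t = 0
    while t < config.iterations_T and first_sync is None:
        t += 1
        node = int(rng.integers(n))
        k_open = int(np.count_nonzero(open_ & infl[node]))
        escape = (1.0 - params.beta) ** k_open
        u = rng.random()
        if open_[node]:
            if u < escape * params.delta:
                open_[node] = False
        else:
            if u < 1.0 - escape:
                open_[node] = True
        fractions.append(1.0 - open_.mean())
        if not open_.any():
            first_sync = t
    return Trajectory(np.array(fractions), first_sync is not None, first_sync)


def simulate_batch(graph: DirectedGraph, beta: np.ndarray, delta: np.ndarray,
                   iterations_T: int, rng: np.random.Generator,
                   initial_state: str = "open",
                   undirected_influence: bool = False) -> np.ndarray:
    """Vectorized kernel: N independent realizations, element i using
    ``(beta[i], delta[i])``.  Returns a boolean array — True where the
    realization reached full synchronization within T single-node updates.

    Because the all-closed state is absorbing, synchronization within T steps
    is equivalent to being all-closed after T steps, so only the final state
    is inspected.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if beta.shape != delta.shape or beta.ndim != 1:
        raise ValueError("beta and delta must be equal-length 1-D arrays")
    n = graph.node_count
    N = beta.shape[0]
    infl = influence_matrix(graph, undirected_influence)
    open_ = _initial_open(initial_state, n, N, rng)
    rows = np.arange(N)
    for _ in range(iterations_T):
        if not open_.any():
            break
        node = rng.integers(0, n, size=N)
        u = rng.random(N)
        k_open = np.count_nonzero(open_ & infl[node], axis=1)
        escape = (1.0 - beta) ** k_open
        cur = open_[rows, node]
        # open -> closed with escape*delta ; closed -> open with 1-escape
        new = np.where(cur, ~(u < escape * delta), u < 1.0 - escape)
        open_[rows, node] = new
    return ~open_.any(axis=1)


def sync_probability(graph: DirectedGraph, params: ModelParams,
                     realizations_R: int, iterations_T: int,
                     seed: int = 0, initial_state: str = "open",
                     undirected_influence: bool = False) -> float:
    """Fraction of R independent realizations that fully synchronize within T
    single-node updates.  Reproducible given the seed."""
    rng = np.random.default_rng(seed)
    beta = np.full(realizations_R, params.beta)
    delta = np.full(realizations_R, params.delta)
    synced = simulate_batch(graph, beta, delta, iterations_T, rng,
                            initial_state, undirected_influence)
    return float(synced.mean())
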