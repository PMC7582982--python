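"""Null-model significance of subgraph counts: Z-scores, significance
profiles, and relative-difference (RD) scores.

The null model is the uniform Erdős–Rényi digraph G(n, m): each randomized
network keeps the node and arc counts of the real network but is otherwise
devoid of structure.  For class i with real count ``N_real_i`` and null
ensemble mean/standard deviation ``mean_i`` / ``std_i``:

* ``Z_i = (N_real_i - mean_i) / std_i`` — undefined (flagged) when
  ``std_i = 0``;
* the significance profile ``SP`` is the Z vector scaled to unit Euclidean
  norm over its defined entries;
* ``RD_i = (N_real_i - mean_i) / (N_real_i + mean_i)`` — a bounded relative
  difference in [-1, 1], undefined when both terms are zero — with an
  analogously normalized RD profile.

Cross-network comparisons exclude whole networks that carry any undefined
entry (the rare dense classes of sparse networks), matching the usual
treatment of undefined Z/RD entries in profile correlation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import Catalog, enumerate_classes
from .census import CensusVector, count_subgraphs
from .synth import er_graph
from .stats import spearman

logger = logging.getLogger("motifsync")


class InsufficientDataError(ValueError):
    """Fewer than two usable networks for a pairwise comparison."""


@dataclass
class EnsembleSummary:
    """Per-class count statistics over a null ensemble."""

    means: np.ndarray
    stds: np.ndarray
    ensemble_size: int
    null_model: str
    seed: int
    raw_counts: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)


@dataclass
class SignificanceProfile:
    """Z-scores and their unit-norm profile; NaN where undefined."""

    z: np.ndarray
    sp: np.ndarray
    undefined: np.ndarray   # boolean flags

    @property
    def any_undefined(self) -> bool:
        return bool(self.undefined.any())


@dataclass
class RDProfile:
    """RD-scores in [-1, 1] and their unit-norm profile; NaN where undefined."""

    rd: np.ndarray
    normalized: np.ndarray
    undefined: np.ndarray

    @property
    def any_undefined(self) -> bool:
        return bool(self.undefined.any())


def er_ensemble(node_count: int, arc_count: int, ensemble_size: int,
                catalog: Catalog, seed: int = 0,
                keep_raw: bool = True) -> EnsembleSummary:
    """Census statistics over ``ensemble_size`` G(n, m) random digraphs.

    Each network draws ``arc_count`` distinct ordered pairs uniformly (no
    self-loops; mutual arcs allowed).  The per-class standard deviation is the
    population standard deviation over the ensemble.
    """
    rng = np.random.default_rng(seed)
    counts = np.empty((ensemble_size, len(catalog.classes)), dtype=np.int64)
    for e in range(ensemble_size):
        g = er_graph(node_count, arc_count, rng)
        counts[e] = count_subgraphs(g, catalog).counts
    summary = EnsembleSummary(
        means=counts.mean(axis=0),
        stds=counts.std(axis=0, ddof=0),
        ensemble_size=ensemble_size,
        null_model=f"ER G({node_count}, {arc_count})",
        seed=seed,
        raw_counts=counts if keep_raw else None)
    return summary


def _normalize(values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    out = np.full(values.shape, np.nan)
    norm = float(np.sqrt(np.nansum(values[defined] ** 2)))
    if norm > 0:
        out[defined] = values[defined] / norm
    else:
        out[defined] = 0.0
    return out


def z_scores(real: CensusVector, ensemble: EnsembleSummary
             ) -> SignificanceProfile:
    """Z-score and unit-norm significance profile per class.

    Classes with zero ensemble standard deviation are flagged undefined and
    excluded from the normalization.
    """
    if real.counts.shape != ensemble.means.shape:
        raise ValueError("census and ensemble cover different catalogs")
    undefined = ensemble.stds == 0.0
    z = np.full(real.counts.shape, np.nan)
    ok = ~undefined
    z[ok] = (real.counts[ok] - ensemble.means[ok]) / ensemble.stds[ok]
    return SignificanceProfile(z, _normalize(z, ok), undefined)


def rd_scores(real: CensusVector, ensemble: EnsembleSummary) -> RDProfile:
    """Relative-difference score and unit-norm RD profile per class.

    ``RD = (real - mean) / (real + mean)``; a class absent from both the real
    network and the null ensemble (0/0) is flagged undefined.
    """
    if real.counts.shape != ensemble.means.shape:
        raise ValueError("census and ensemble cover different catalogs")
    total = real.counts + ensemble.means
    undefined = total == 0.0
    rd = np.full(real.counts.shape, np.nan)
    ok = ~undefined
    rd[ok] = (real.counts[ok] - ensemble.means[ok]) / total[ok]
    return RDProfile(rd, _normalize(rd, ok), undefined)


def profile_matrix(records: Sequence, size_k: int, score_kind: str = "z",
                   ensemble_size: int = 500, seed: int = 0,
                   catalog: Optional[Catalog] = None,
                   pairwise_exclusion: bool = False,
                   share_ensemble: bool = False
                   ) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Normalized profiles per network and their pairwise Spearman matrix.

    Each network gets its own null ensemble (child seed streams spawned from
    ``seed``); with ``share_ensemble=True`` all networks use the same ensemble
    seed, so identical networks get identical profiles.  By default a network
    with any undefined entry is dropped from the pairwise matrix entirely;
    with ``pairwise_exclusion=True`` undefined entries are instead dropped
    pair by pair.
    """
    if score_kind not in ("z", "rd"):
        raise ValueError("score_kind must be 'z' or 'rd'")
    if len(records) < 2:
        raise InsufficientDataError("need at least two networks")
    if catalog is None:
        catalog = enumerate_classes(size_k)
    children = np.random.SeedSequence(seed).spawn(len(records))
    if share_ensemble:
        children = [children[0]] * len(records)
    profiles: Dict[str, np.ndarray] = {}
    flags: Dict[str, bool] = {}
    for record, child in zip(records, children):
        census = count_subgraphs(record.graph, catalog)
        census.network_name = record.name
        ens = er_ensemble(record.graph.node_count, record.graph.arc_count,
                          ensemble_size, catalog,
                          seed=int(child.generate_state(1)[0] % 2**31),
                          keep_raw=False)
        if score_kind == "z":
            prof = z_scores(census, ens)
            profiles[record.name] = prof.sp
        else:
            prof = rd_scores(census, ens)
            profiles[record.name] = prof.normalized
        flags[record.name] = prof.any_undefined
        if prof.any_undefined:
            logger.warning("%s: undefined %s entries; excluded from the "
                           "pairwise matrix", record.name, score_kind.upper())
    if pairwise_exclusion:
        usable = list(profiles)
    else:
        usable = [n for n in profiles if not flags[n]]
    if len(usable) < 2:
        raise InsufficientDataError(
            "fewer than two networks with fully defined profiles")
    mat = pd.DataFrame(np.eye(len(usable)), index=usable, columns=usable)
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            pa, pb = profiles[a], profiles[b]
            ok = ~(np.isnan(pa) | np.isnan(pb))
            rho = spearman(pa[ok], pb[ok]).rho
            mat.loc[a, b] = mat.loc[b, a] = rho
    return profiles, mat
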