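"""Nonparametric statistics linking synchronizability to subgraph abundance.

Spearman rank correlation (Pearson correlation of average ranks, two-tailed p
via the t approximation) and the tie-corrected Kruskal–Wallis H test are
implemented directly on ranks; only the t and chi-squared distribution
functions come from scipy.  Box-plot five-number summaries follow the usual
rule: whiskers reach the most extreme values within 1.5 IQR of the box, and
anything beyond is an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .catalog import Catalog
from .census import CensusVector
from .scoring import SMScoreVector


class DegenerateDataError(ValueError):
    """Input has no variation (or wrong shape) for the requested statistic."""


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FiveNumberSummary:
    q1: float
    median: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple


def average_ranks(values) -> np.ndarray:
    """1-based ranks; tied values share the average of their rank range."""
    a = np.asarray(values, dtype=float)
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.shape[0])
    sa = a[order]
    i = 0
    while i < a.shape[0]:
        j = i
        while j < a.shape[0] and sa[j] == sa[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0   # average of ranks i+1 .. j
        i = j
    return ranks


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-tailed t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("x and y must be equal-length vectors")
    n = x.shape[0]
    if n < 3:
        raise DegenerateDataError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input has no rank correlation")
    rx = average_ranks(x)
    ry = average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, n, p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with a chi-squared p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise DegenerateDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical")
    n_total = pooled.size
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (
        n_total ** 3 - n_total)
    h /= correction
    df = len(groups) - 1
    return KWResult(float(h), df, float(_sps.chi2.sf(h, df)))


def five_number_summary(values) -> FiveNumberSummary:
    """Box-plot summary: quartiles (linear interpolation), whiskers, outliers."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    iqr = q3 - q1
    hi = q3 + 1.5 * iqr
    lo = q1 - 1.5 * iqr
    inside = a[(a >= lo) & (a <= hi)]
    upper = float(min(a.max(), hi)) if inside.size == 0 else float(inside.max())
    lower = float(max(a.min(), lo)) if inside.size == 0 else float(inside.min())
    outliers = tuple(sorted(float(v) for v in a[(a < lo) | (a > hi)]))
    return FiveNumberSummary(float(q1), float(med), float(q3), float(iqr),
                             lower, upper, outliers)


@dataclass
class StatReport:
    """Bundle of SM-vs-abundance statistics across networks."""

    spearman_sm_frequency: Dict[str, SpearmanResult]
    kw_frequency_by_sm_class: Dict[str, Optional[KWResult]]
    frequency_box_summaries: Dict[str, Dict[int, FiveNumberSummary]]
    kw_profile_by_density: Dict[str, Dict[str, Dict[int, Optional[KWResult]]]]


def _kw_or_none(groups) -> Optional[KWResult]:
    try:
        return kruskal_wallis(groups)
    except DegenerateDataError:
        return None


def sm_vs_frequency_report(sm: SMScoreVector,
                           censuses: Sequence[CensusVector],
                           sm_classes: np.ndarray,
                           density_classes: Dict[int, List[int]],
                           profiles: Optional[Dict[str, Dict[str, np.ndarray]]]
                           = None) -> StatReport:
    """Per-network statistics tying SM scores to subgraph abundance.

    For each network: Spearman correlation between SM score and class
    frequency; a Kruskal–Wallis test of frequency across the four SM classes
    (with per-class box summaries); and — when per-network Z or RD profiles
    are supplied as ``profiles[kind][network]`` — Kruskal–Wallis tests of the
    profile values across SM classes within each density class.  Tests that
    are degenerate for a given grouping (e.g. a density class covered by a
    single SM class) are reported as ``None``.
    """
    n_classes = len(sm.scores)
    sm_classes = np.asarray(sm_classes)
    spearman_out: Dict[str, SpearmanResult] = {}
    kw_out: Dict[str, Optional[KWResult]] = {}
    boxes: Dict[str, Dict[int, FiveNumberSummary]] = {}
    kw_density: Dict[str, Dict[str, Dict[int, Optional[KWResult]]]] = {}
    for census in censuses:
        if census.counts.shape[0] != n_classes:
            raise ValueError(
                f"census for {census.network_name!r} covers "
                f"{census.counts.shape[0]} classes, SM vector {n_classes}")
        name = census.network_name
        spearman_out[name] = spearman(sm.scores, census.counts)
        groups = {c: census.counts[sm_classes == c]
                  for c in sorted(set(sm_classes.tolist()))}
        kw_out[name] = _kw_or_none([g for g in groups.values() if g.size])
        boxes[name] = {c: five_number_summary(g)
                       for c, g in groups.items() if g.size}
    if profiles:
        for kind, per_network in profiles.items():
            kw_density[kind] = {}
            for name, values in per_network.items():
                values = np.asarray(values, dtype=float)
                per_density: Dict[int, Optional[KWResult]] = {}
                for m, idxs in density_classes.items():
                    idxs = [i for i in idxs if not np.isnan(values[i])]
                    labels = sm_classes[idxs]
                    grp = [values[[i for i in idxs if sm_classes[i] == c]]
                           for c in sorted(set(labels.tolist()))]
                    grp = [g for g in grp if g.size]
                    per_density[m] = _kw_or_none(grp) if len(grp) >= 2 else None
                kw_density[kind][name] = per_density
    return StatReport(spearman_out, kw_out, boxes, kw_density)
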