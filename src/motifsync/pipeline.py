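"""End-to-end study orchestration.

A study takes one or more directed networks and, for each subgraph size,
computes SM scores for every subgraph class, the per-network census, Z/RD
significance profiles against ER null ensembles, cross-network profile
correlation matrices, and the SM-vs-abundance statistical report.  All
numeric tables are written as TSV with 10-significant-digit formatting; a
manifest records the package version, seeds and parameters so any run can be
replayed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .catalog import assign_paper_ids, density_classes, enumerate_classes
from .census import count_subgraphs, frequency_ranking
from .netio import (NetworkRecord, ROW_DEPENDS_ON_COLUMN, read_dsm,
                    read_edgelist)
from .scoring import SMConfig, sm_quartile_classes, sm_scores
from .significance import er_ensemble, rd_scores, z_scores
from .stats import sm_vs_frequency_report, spearman

logger = logging.getLogger("motifsync")

_FMT = "%.10g"


def fmt(x) -> str:
    """Fixed 10-significant-digit number formatting for diffable TSVs."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return _FMT % x


def write_tsv(path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                fmt(c) if isinstance(c, (int, float, np.floating, np.integer))
                and not isinstance(c, bool) else str(c)
                for c in row) + "\n")


@dataclass
class NetworkInput:
    """One input network: a path plus its on-disk format."""

    path: str
    format: str = "edgelist"            # "edgelist" or "dsm"
    name: Optional[str] = None
    dsm_orientation: str = ROW_DEPENDS_ON_COLUMN
    delimiter: Optional[str] = None

    def load(self) -> NetworkRecord:
        if not Path(self.path).exists():
            raise FileNotFoundError(self.path)
        if self.format == "edgelist":
            return read_edgelist(self.path, delimiter=self.delimiter,
                                 name=self.name)
        if self.format == "dsm":
            return read_dsm(self.path, orientation=self.dsm_orientation,
                            name=self.name)
        raise ValueError(f"unknown format {self.format!r}")


@dataclass
class StudyConfig:
    """Full configuration of an end-to-end study."""

    networks: List[NetworkInput]
    sizes: List[int] = field(default_factory=lambda: [3])
    sm: SMConfig = field(default_factory=SMConfig)
    ensemble_size: int = 500
    seed: int = 0
    outdir: str = "study_out"


def load_config(path) -> StudyConfig:
    """Read a study configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    networks = [NetworkInput(**n) for n in raw.get("networks", [])]
    sm_raw = raw.get("sm", {})
    sm = SMConfig(
        param_samples_S=int(sm_raw.get("param_samples_S", 10_000)),
        realizations_R=int(sm_raw.get("realizations_R", 100)),
        iterations_T=int(sm_raw.get("iterations_T", 120)),
        seed=int(sm_raw.get("seed", raw.get("seed", 0))))
    return StudyConfig(networks=networks,
                       sizes=[int(s) for s in raw.get("sizes", [3])],
                       sm=sm,
                       ensemble_size=int(raw.get("ensemble_size", 500)),
                       seed=int(raw.get("seed", 0)),
                       outdir=str(raw.get("outdir", "study_out")))


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % 2**31)


def run_study(config: StudyConfig) -> Dict:
    """Run the full analysis and write the result bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    if not config.networks:
        raise ValueError("a study needs at least one input network")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [n.load() for n in config.networks]
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "sm": asdict(config.sm),
        "ensemble_size": config.ensemble_size,
        "sizes": list(config.sizes),
        "networks": [{"name": r.name, "nodes": r.graph.node_count,
                      "arcs": r.graph.arc_count} for r in records],
        "outputs": [],
    }

    def emit(relpath: str):
        manifest["outputs"].append(relpath)
        return outdir / relpath

    root_seq = np.random.SeedSequence(config.seed)
    for size_k, size_seq in zip(config.sizes, root_seq.spawn(len(config.sizes))):
        tag = f"k{size_k}"
        cat = enumerate_classes(size_k)
        sm_seq, ens_seq = size_seq.spawn(2)
        smcfg = SMConfig(config.sm.param_samples_S, config.sm.realizations_R,
                         config.sm.iterations_T, _child_seed(sm_seq))
        logger.info("[%s] SM scoring %d classes (S=%d, R=%d, T=%d)", tag,
                    len(cat), smcfg.param_samples_S, smcfg.realizations_R,
                    smcfg.iterations_T)
        smvec = sm_scores(cat, smcfg)
        cat = assign_paper_ids(cat, smvec.scores)
        sm_cls = sm_quartile_classes(smvec)
        dens = density_classes(cat)

        write_tsv(emit(f"catalog_{tag}.tsv"),
                  ["paper_id", "canonical_code", "edge_count", "name",
                   "sm_score", "sm_se", "sm_class"],
                  sorted(([c.paper_id, ",".join(f"{s}>{t}" for s, t in
                                                c.canonical_code),
                           c.edge_count, c.name or "", smvec.scores[i],
                           smvec.standard_errors[i], int(sm_cls[i])]
                          for i, c in enumerate(cat.classes)),
                         key=lambda r: r[0]))

        censuses = []
        profiles: Dict[str, Dict[str, np.ndarray]] = {"z": {}, "rd": {}}
        flags: Dict[str, bool] = {}
        for rec, net_seq in zip(records, ens_seq.spawn(len(records))):
            census = count_subgraphs(rec.graph, cat)
            census.network_name = rec.name
            censuses.append(census)
            ens = er_ensemble(rec.graph.node_count, rec.graph.arc_count,
                              config.ensemble_size, cat,
                              seed=_child_seed(net_seq), keep_raw=False)
            zprof = z_scores(census, ens)
            rdprof = rd_scores(census, ens)
            profiles["z"][rec.name] = zprof.z
            profiles["rd"][rec.name] = rdprof.rd
            flags[rec.name] = zprof.any_undefined or rdprof.any_undefined
            ranking = frequency_ranking(census, cat)
            rank_of = {idx: pos + 1 for pos, idx in enumerate(ranking)}
            write_tsv(
                emit(f"significance_{tag}_{rec.name}.tsv"),
                ["paper_id", "count", "freq_rank", "mean_rand", "std_rand",
                 "z", "sp", "rd", "rd_norm", "undefined"],
                sorted(([cat.classes[i].paper_id, int(census.counts[i]),
                         rank_of[i], ens.means[i], ens.stds[i], zprof.z[i],
                         zprof.sp[i], rdprof.rd[i], rdprof.normalized[i],
                         int(zprof.undefined[i] or rdprof.undefined[i])]
                        for i in range(len(cat.classes))),
                       key=lambda r: r[0]))

        # cross-network profile correlations (whole-network exclusion)
        usable = [r.name for r in records if not flags[r.name]]
        if len(usable) >= 2:
            for kind, norm_key in (("z", "z"), ("rd", "rd")):
                rows = []
                for a in usable:
                    row = [a]
                    for b in usable:
                        if a == b:
                            row.append(1.0)
                        else:
                            row.append(spearman(profiles[kind][a],
                                                profiles[kind][b]).rho)
                    rows.append(row)
                write_tsv(emit(f"profile_corr_{kind}_{tag}.tsv"),
                          ["network"] + usable, rows)

        report = sm_vs_frequency_report(smvec, censuses, sm_cls, dens,
                                        profiles=profiles)
        rep_json = {
            "spearman_sm_frequency": {
                n: {"rho": r.rho, "n": r.n, "p": r.p_value}
                for n, r in report.spearman_sm_frequency.items()},
            "kw_frequency_by_sm_class": {
                n: (None if r is None else
                    {"H": r.H, "df": r.df, "p": r.p_value})
                for n, r in report.kw_frequency_by_sm_class.items()},
            "kw_profile_by_density": {
                kind: {n: {str(m): (None if r is None else
                                    {"H": r.H, "df": r.df, "p": r.p_value})
                           for m, r in per.items()}
                       for n, per in nets.items()}
                for kind, nets in report.kw_profile_by_density.items()},
            "frequency_box_summaries": {
                n: {str(c): asdict(s) for c, s in per.items()}
                for n, per in report.frequency_box_summaries.items()},
        }
        with open(emit(f"report_{tag}.json"), "w") as fh:
            json.dump(rep_json, fh, indent=1, sort_keys=True)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
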