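"""Reading and writing directed networks.

Two plain-text formats are supported: two-column edge lists (TSV/CSV, one arc
per line, source then target) and square binary Dependency Structure Matrices
(DSM, CSV with optional label header).  A DSM records information dependencies
among tasks; under the common row-depends-on-column convention a nonzero entry
at (row i, column j) means task i depends on task j, i.e. information flows
along the arc j -> i.  Some published DSMs use the transposed convention, so
the orientation is a parameter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

from .catalog import DirectedGraph

logger = logging.getLogger("motifsync")

ROW_DEPENDS_ON_COLUMN = "row-depends-on-column"
COLUMN_DEPENDS_ON_ROW = "column-depends-on-row"


class EdgeListParseError(ValueError):
    """Malformed edge-list line (carries the 1-based line number)."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class DSMShapeError(ValueError):
    """DSM matrix is not square."""


@dataclass
class NetworkRecord:
    """A named directed network with stable node labels."""

    name: str
    node_labels: List[str]
    graph: DirectedGraph

    def __post_init__(self):
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if len(self.node_labels) != self.graph.node_count:
            raise ValueError("label count does not match node count")


def _build_record(name: str, labeled_arcs: Sequence[tuple],
                  labels: Optional[Sequence[str]] = None) -> NetworkRecord:
    """Assemble a record from (source_label, target_label) pairs.

    Nodes are the union of endpoints in first-appearance order unless an
    explicit label list is given.  Self-loops are dropped and duplicate arcs
    collapsed, each with a logged warning.
    """
    if labels is None:
        order: List[str] = []
        seen = set()
        for s, t in labeled_arcs:
            for lab in (s, t):
                if lab not in seen:
                    seen.add(lab)
                    order.append(lab)
        labels = order
    index = {lab: i for i, lab in enumerate(labels)}
    arcs = set()
    dropped_loops = 0
    dupes = 0
    for s, t in labeled_arcs:
        if s == t:
            dropped_loops += 1
            continue
        a = (index[s], index[t])
        if a in arcs:
            dupes += 1
        arcs.add(a)
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", name, dropped_loops)
    if dupes:
        logger.warning("%s: collapsed %d duplicate arc(s)", name, dupes)
    return NetworkRecord(name, list(labels),
                         DirectedGraph(len(labels), arcs))


def read_edgelist(path, delimiter: Optional[str] = None,
                  name: Optional[str] = None) -> NetworkRecord:
    """Read a two-column edge list (source, target; one arc per line).

    Lines starting with ``#`` and blank lines are ignored.  With
    ``delimiter=None`` the line is split on any whitespace; pass ``","`` for
    CSV input.
    """
    path = Path(path)
    labeled_arcs = []
    isolated: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#node "):
                isolated.append(line[len("#node "):].strip())
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise EdgeListParseError(
                    path, lineno,
                    f"expected 2 columns, got {len(parts)}: {line!r}")
            labeled_arcs.append((parts[0], parts[1]))
    if not labeled_arcs:
        if not isolated:
            raise EdgeListParseError(path, 0, "no arcs or nodes in file")
        return NetworkRecord(name or path.stem, isolated,
                             DirectedGraph(len(isolated), []))
    record = _build_record(name or path.stem, labeled_arcs)
    if isolated:
        # "#node X" comments preserve isolated nodes across round trips
        labels = record.node_labels + [x for x in isolated
                                       if x not in set(record.node_labels)]
        record = NetworkRecord(record.name, labels,
                               DirectedGraph(len(labels), record.graph.arcs))
    return record


def _try_float(cell: str) -> Optional[float]:
    try:
        return float(cell)
    except ValueError:
        return None


def read_dsm(path, orientation: str = ROW_DEPENDS_ON_COLUMN,
             name: Optional[str] = None) -> NetworkRecord:
    """Read a square binary DSM (CSV); any nonzero off-diagonal cell is a link.

    An optional header row and/or leading label column is auto-detected (cells
    that do not parse as numbers).  Diagonal entries are ignored with a
    warning.  Under ``row-depends-on-column``, a nonzero entry at (row i,
    column j) yields the arc j -> i; the other orientation flips it.
    """
    if orientation not in (ROW_DEPENDS_ON_COLUMN, COLUMN_DEPENDS_ON_ROW):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and any(c.strip() for c in r)]
    if not rows:
        raise DSMShapeError(f"{path}: empty file")
    # header row present iff any non-leading cell of the first row is
    # non-numeric
    has_header = any(_try_float(c) is None for c in rows[0][1:])
    header = [c.strip() for c in rows[0]] if has_header else None
    body = rows[1:] if has_header else rows
    has_label_col = any(_try_float(r[0]) is None for r in body)
    labels: Optional[List[str]]
    if has_label_col:
        labels = [r[0].strip() for r in body]
    elif header is not None:
        # header may carry a corner cell above the label column
        labels = header[1:] if len(header) == len(body) + 1 else header
        labels = [c for c in labels]
    else:
        labels = None
    matrix = []
    for r in body:
        cells = r[1:] if has_label_col else r
        row = []
        for c in cells:
            v = _try_float(c.strip() or "0")
            if v is None:
                raise ValueError(f"{path}: non-numeric cell {c!r}")
            row.append(v)
        matrix.append(row)
    n = len(matrix)
    if any(len(r) != n for r in matrix):
        raise DSMShapeError(
            f"{path}: matrix is not square "
            f"({n} rows, widths {sorted({len(r) for r in matrix})})")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise DSMShapeError(f"{path}: {len(labels)} labels for {n} rows")
    diag = sum(1 for i in range(n) if matrix[i][i] != 0)
    if diag:
        logger.warning("%s: ignored %d nonzero diagonal entr(ies)", path, diag)
    arcs = []
    for i in range(n):
        for j in range(n):
            if i == j or matrix[i][j] == 0:
                continue
            if orientation == ROW_DEPENDS_ON_COLUMN:
                arcs.append((labels[j], labels[i]))  # information flows j -> i
            else:
                arcs.append((labels[i], labels[j]))
    return _build_record(name or path.stem, arcs, labels=labels)


def write_edgelist(record: NetworkRecord, path, delimiter: str = "\t") -> None:
    """Write the network as a two-column edge list (sorted, diffable)."""
    path = Path(path)
    labels = record.node_labels
    lines = sorted((labels[s], labels[t]) for s, t in record.graph.arcs)
    with open(path, "w") as fh:
        fh.write(f"# {record.name}: {record.graph.node_count} nodes, "
                 f"{record.graph.arc_count} arcs\n")
        # isolated nodes are kept as degenerate self-referential comments so
        # that labels survive a round trip of an empty-arc network
        used = {lab for pair in lines for lab in pair}
        for lab in labels:
            if lab not in used:
                fh.write(f"#node {lab}\n")
        for s, t in lines:
            fh.write(f"{s}{delimiter}{t}\n")


def write_dsm(record: NetworkRecord, path,
              orientation: str = ROW_DEPENDS_ON_COLUMN) -> None:
    """Write the network as a labeled binary DSM (CSV)."""
    n = record.graph.node_count
    labels = record.node_labels
    m = [[0] * n for _ in range(n)]
    for s, t in record.graph.arcs:
        if orientation == ROW_DEPENDS_ON_COLUMN:
            m[t][s] = 1  # row t depends on column s
        else:
            m[s][t] = 1
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(labels))
        for i in range(n):
            w.writerow([labels[i]] + m[i])
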