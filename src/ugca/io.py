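"""Plain-text readers and writers: time-series panels and adjacency matrices.

All formats round-trip through this module's own readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .causality import AdjacencyNetwork, CausalDecision
from .var_core import TimeSeriesPanel

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_adjacency",
    "write_adjacency",
    "write_edge_list",
]


def read_timeseries(
    path: str | Path, delimiter: str = ",", header: bool = True
) -> TimeSeriesPanel:
    """Read a delimited numeric file: columns are nodes, rows are time points.

    With ``header=True`` the first row supplies node labels; otherwise
    nodes are labelled ``x1 .. xm``.  Ragged rows, non-numeric cells and
    missing values raise errors naming the offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from None
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[
            [not np.issubdtype(d, np.number) for d in frame.dtypes]
        ].tolist()
        raise ValueError(f"{path}: non-numeric cells in column(s) {bad}")
    if np.isnan(values).any():
        rows = np.unique(np.where(np.isnan(values))[0]) + 1 + int(header)
        raise ValueError(f"{path}: missing/NaN values at data row(s) {rows.tolist()}")
    labels = tuple(str(c) for c in frame.columns) if header else ()
    return TimeSeriesPanel(values, labels)


def write_timeseries(
    panel: TimeSeriesPanel, path: str | Path, delimiter: str = ","
) -> None:
    frame = pd.DataFrame(panel.values, columns=list(panel.node_labels))
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def write_adjacency(net: AdjacencyNetwork, path: str | Path) -> None:
    """Whitespace-delimited 0/1 matrix with a header row of node labels."""
    with open(path, "w") as fh:
        fh.write(" ".join(net.node_labels) + "\n")
        for row in net.edges.astype(int):
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_adjacency(path: str | Path) -> AdjacencyNetwork:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    labels = tuple(lines[0].split())
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split()
        if len(cells) != len(labels):
            raise ValueError(f"{path}: row {i} has {len(cells)} entries, "
                             f"expected {len(labels)}")
        try:
            rows.append([int(c) for c in cells])
        except ValueError:
            raise ValueError(f"{path}: non-integer cell at row {i}") from None
    mat = np.asarray(rows)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    return AdjacencyNetwork(mat.astype(bool), labels)


def write_edge_list(
    decisions: Sequence[CausalDecision],
    labels: Sequence[str],
    path: str | Path,
) -> None:
    """TSV of source, target, raw statistic and verdict for post-hoc thresholding."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tstatistic\tedge\n")
        for d in decisions:
            fh.write(
                f"{labels[d.source]}\t{labels[d.target]}\t{d.statistic:.12g}\t"
                f"{int(d.edge)}\n"
            )
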