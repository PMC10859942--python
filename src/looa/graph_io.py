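"""Read and write the two-column interaction CSV and build clean graphs.

The input dialect is a plain RFC-4180 CSV whose header must contain the
columns ``Source`` and ``Target`` (matched case-insensitively); every row is
one protein-protein interaction.  Crosslink-derived interactions carry no
direction, so the graph is a simple undirected :class:`networkx.Graph`:
self-loops are dropped and reciprocal/duplicate rows are collapsed, with
counts logged.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from looa.errors import EmptyGraphError, FormatError, InputError, OutputError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("Source", "Target")


@dataclass(frozen=True)
class EdgeRecord:
    """One interaction row: an ordered (as-read) pair of protein identifiers."""

    source: str
    target: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("EdgeRecord endpoints must be non-empty strings")


def read_edge_list(path: str | os.PathLike, case_sensitive_ids: bool = True) -> list[EdgeRecord]:
    """Parse a Source/Target CSV into :class:`EdgeRecord` rows, in file order.

    Header matching is case-insensitive and extra columns are ignored (with a
    warning); identifiers are whitespace-trimmed.  With
    ``case_sensitive_ids=False`` identifiers are uppercased so that e.g.
    ``Tau`` and ``TAU`` collapse to one protein.

    Raises
    ------
    InputError
        If the file does not exist or cannot be read.
    FormatError
        If a required column is missing or a row has an empty cell.
    """
    try:
        handle = open(path, "r", encoding="utf-8-sig", newline="")
    except OSError as exc:
        raise InputError(f"cannot read edge list {path!r}: {exc}") from exc

    with handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path!r} is empty: no header row") from None

        lower = [h.strip().lower() for h in header]
        indices: dict[str, int] = {}
        for name in REQUIRED_COLUMNS:
            try:
                indices[name] = lower.index(name.lower())
            except ValueError:
                raise FormatError(f"missing required column: {name}") from None
        extra = [h for i, h in enumerate(header) if i not in indices.values()]
        if extra:
            logger.warning("ignoring %d extra column(s): %s", len(extra), ", ".join(extra))

        records: list[EdgeRecord] = []
        for row_number, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue  # tolerate blank lines
            cells = []
            for name in REQUIRED_COLUMNS:
                idx = indices[name]
                value = row[idx].strip() if idx < len(row) else ""
                if not value:
                    raise FormatError(f"empty {name} cell in row {row_number}")
                cells.append(value if case_sensitive_ids else value.upper())
            records.append(EdgeRecord(cells[0], cells[1]))
    return records


def graph_from_edges(records: Sequence[EdgeRecord] | Iterable[EdgeRecord]) -> nx.Graph:
    """Build a simple undirected graph, dropping self-loops and duplicates.

    Direction is discarded: ``(A, B)`` and ``(B, A)`` are the same
    interaction.  Dropped self-loop and duplicate counts are logged.

    Raises
    ------
    EmptyGraphError
        If no records are given or every record is a self-loop.
    """
    graph = nx.Graph()
    self_loops = 0
    duplicates = 0
    for record in records:
        if record.source == record.target:
            self_loops += 1
            continue
        if graph.has_edge(record.source, record.target):
            duplicates += 1
            continue
        graph.add_edge(record.source, record.target)
    if self_loops:
        logger.info("dropped %d self-loop record(s)", self_loops)
    if duplicates:
        logger.info("collapsed %d duplicate record(s)", duplicates)
    if graph.number_of_edges() == 0:
        raise EmptyGraphError("no usable interactions: every record was empty or a self-loop")
    return graph


def load_graph(path: str | os.PathLike, case_sensitive_ids: bool = True) -> nx.Graph:
    """Convenience wrapper: :func:`read_edge_list` then :func:`graph_from_edges`."""
    return graph_from_edges(read_edge_list(path, case_sensitive_ids=case_sensitive_ids))


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write a graph back to the Source/Target dialect, canonically ordered.

    Endpoints are sorted within each row and rows sorted lexicographically, so
    the output is a deterministic function of the graph and round-trips
    through :func:`load_graph` to an identical graph.
    """
    rows = sorted(tuple(sorted(edge)) for edge in graph.edges())
    try:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(REQUIRED_COLUMNS)
            writer.writerows(rows)
    except OSError as exc:
        raise OutputError(f"cannot write edge list {path!r}: {exc}") from exc
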