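"""Readers and writers for interaction networks, complex catalogs and matrices.

File formats are deliberately minimal and line-oriented:

* **Edge list** — one interaction per line, ``node_a node_b [weight]``,
  whitespace- or tab-separated.  Lines starting with ``#`` are comments.
  A first line whose third column does not parse as a number is treated as
  a header and skipped with a warning.
* **Complex catalog** — one complex per line, whitespace/tab-separated
  protein identifiers (the flat format used by curated catalogs such as
  CORUM exports).
* **Matrix** — TSV with a header row of column labels and a leading column
  of row labels, full precision.

Node labels are opaque, case-sensitive strings.  Matrices produced anywhere
in the package are indexed by the network's node order, which is the order
of first appearance in the edge-list file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "ComplexCover",
    "read_edgelist",
    "read_complexes",
    "restrict_cover",
    "write_cover",
    "write_matrix",
    "read_matrix",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class Network:
    """An undirected interaction network.

    Parameters
    ----------
    nodes : list of str
        Node labels in a fixed order; every matrix in the package is
        indexed by this order.
    adjacency : ndarray of shape (n, n)
        Symmetric non-negative matrix of edge weights, zero diagonal.
        For unweighted networks every edge has weight 1.
    weighted : bool
        Whether edge weights carry information beyond presence/absence.
    """

    nodes: list[str]
    adjacency: np.ndarray
    weighted: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} nodes"
            )
        if len(set(self.nodes)) != n:
            raise ValueError("node labels must be unique")
        self.validate()
        self._index = {lab: i for i, lab in enumerate(self.nodes)}

    def validate(self) -> None:
        a = self.adjacency
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValueError("adjacency must be non-negative")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not self.weighted:
            nz = a[a != 0]
            if nz.size and not np.all(nz == 1.0):
                raise ValueError("unweighted network has edge weights != 1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency)) // 2

    def index_of(self, label: str) -> int:
        return self._index[label]

    def degrees(self) -> np.ndarray:
        """Weighted degree of every node (row sums of the adjacency)."""
        return self.adjacency.sum(axis=1)


@dataclass
class ComplexCover:
    """A collection of node sets — predicted or reference complexes.

    Sets may overlap and need not cover every node of a network.
    """

    complexes: list[set[str]]
    name: str = ""

    def __post_init__(self) -> None:
        self.complexes = [set(c) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty sets")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def members(self) -> set[str]:
        """Union of all member labels."""
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]


def _split(line: str) -> list[str]:
    return line.strip().split()


def read_edgelist(path: str | Path, weighted: bool = False) -> Network:
    """Read an undirected network from a whitespace/tab edge list.

    Duplicate edges (including the same edge in both orientations) are
    collapsed keeping the **maximum** weight; self-loops are dropped with a
    warning.  Node order is first appearance in the file.
    """
    path = Path(path)
    nodes: list[str] = []
    index: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = _split(line)
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            if first_data_line and len(cols) >= 3:
                try:
                    float(cols[2])
                except ValueError:
                    logger.warning("%s:%d: skipping header line %r", path, lineno, line)
                    first_data_line = False
                    continue
            first_data_line = False
            u, v = cols[0], cols[1]
            if weighted and len(cols) >= 3:
                try:
                    w = float(cols[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: cannot parse weight {cols[2]!r}"
                    ) from exc
                if w < 0:
                    raise FormatError(f"{path}:{lineno}: negative weight {w}")
            else:
                w = 1.0
            for lab in (u, v):
                if lab not in index:
                    index[lab] = len(nodes)
                    nodes.append(lab)
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                continue
            i, j = index[u], index[v]
            key = (min(i, j), max(i, j))
            edges[key] = max(edges.get(key, 0.0), w)

    n = len(nodes)
    a = np.zeros((n, n))
    for (i, j), w in edges.items():
        a[i, j] = a[j, i] = w
    return Network(nodes=nodes, adjacency=a, weighted=weighted)


def read_complexes(path: str | Path, name: str | None = None) -> ComplexCover:
    """Read a flat complex catalog: one complex per line, IDs separated by
    whitespace or tabs.  Within-line duplicate IDs are dropped with a warning.
    """
    path = Path(path)
    complexes: list[set[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids = _split(line)
            s = set(ids)
            if len(s) < len(ids):
                logger.warning("%s:%d: duplicate IDs within complex deduplicated", path, lineno)
            complexes.append(s)
    if not complexes:
        raise FormatError(f"{path}: no complexes found")
    return ComplexCover(complexes=complexes, name=name or path.name)


def restrict_cover(cover: ComplexCover, net: Network, min_size: int = 3) -> ComplexCover:
    """Intersect every complex with the network's node set and drop those
    left with fewer than ``min_size`` members.

    Reference catalogs routinely contain proteins absent from a given
    network; evaluation is only meaningful over the shared universe, and
    complexes reduced below ``min_size`` distinct members are removed.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(net.nodes)
    kept = [c & universe for c in cover.complexes]
    kept = [c for c in kept if len(c) >= min_size]
    return ComplexCover(complexes=kept, name=cover.name)


def write_cover(cover: ComplexCover, path: str | Path) -> None:
    """Write a cover in the flat catalog format (round-trips with
    :func:`read_complexes`). Members are written in sorted order."""
    path = Path(path)
    with path.open("w") as fh:
        for c in cover.complexes:
            fh.write("\t".join(sorted(c)) + "\n")


def write_matrix(
    matrix: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    path: str | Path,
) -> None:
    """Write a labeled matrix as TSV at full precision."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ValueError("label lengths do not match matrix shape")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["id", *map(str, col_labels)]) + "\n")
        for lab, row in zip(row_labels, matrix):
            fh.write("\t".join([str(lab), *(repr(float(x)) for x in row)]) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix written by :func:`write_matrix`.

    Returns ``(matrix, row_labels, col_labels)``.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_labels = header[1:]
        row_labels: list[str] = []
        rows: list[list[float]] = []
        for raw in fh:
            cols = raw.rstrip("\n").split("\t")
            row_labels.append(cols[0])
            rows.append([float(x) for x in cols[1:]])
    return np.array(rows, dtype=float), row_labels, col_labels
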