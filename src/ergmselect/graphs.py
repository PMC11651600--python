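"""Binary undirected graphs and exact motif counting.

The in-memory representation is deliberately small: a node count, a set of
canonical (i < j) index pairs, and the external labels in index order.
Everything downstream (sufficient statistics, change statistics, MCMC state)
is derived from this.

Counting conventions
--------------------
``count_kstars`` and ``count_triangles`` return the standard unordered
statistics used in ERGM likelihoods: ``sum_v C(deg v, k)`` and the number of
closed unordered triples.  Some published tabulations instead count ordered
2-paths and ordered triangles, which is exactly twice each of these;
``motif_summary`` exposes that via ``convention="ordered"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import IO, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "Dyad",
    "MotifCounts",
    "GraphParseError",
    "GraphValidationError",
    "read_edgelist",
    "write_edgelist",
    "read_pajek",
    "read_node_attributes",
    "degrees",
    "count_kstars",
    "count_triangles",
    "shared_partner_distributions",
    "motif_summary",
]


class GraphParseError(ValueError):
    """A line of an edge-list or Pajek file could not be parsed."""


class GraphValidationError(ValueError):
    """Input violates a structural constraint (self-loop, unknown label...)."""


@dataclass(frozen=True)
class Dyad:
    """An unordered node pair in canonical ``i < j`` form."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise GraphValidationError(f"dyad endpoints must differ, got ({self.i}, {self.j})")
        if self.i > self.j:
            raise GraphValidationError(f"dyad must be canonical i < j, got ({self.i}, {self.j})")


@dataclass(frozen=True)
class MotifCounts:
    edges: int
    two_stars: int
    triangles: int

    def as_dict(self) -> dict[str, int]:
        return {"edges": self.edges, "two_stars": self.two_stars, "triangles": self.triangles}


@dataclass
class Graph:
    """A simple undirected graph with optional isolates.

    Parameters
    ----------
    n_nodes:
        Total node count; may exceed the number of labelled endpoints.
    edges:
        Set of ``(i, j)`` index pairs with ``i < j``.
    node_labels:
        External labels in internal-index order.  Defaults to ``0..n-1``.
    """

    n_nodes: int
    edges: set[tuple[int, int]] = field(default_factory=set)
    node_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise GraphValidationError("n_nodes must be nonnegative")
        if not self.node_labels:
            self.node_labels = list(range(self.n_nodes))
        if len(self.node_labels) != self.n_nodes:
            raise GraphValidationError(
                f"{len(self.node_labels)} labels for {self.n_nodes} nodes"
            )
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise GraphValidationError(f"self-loop on node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise GraphValidationError(f"edge ({i}, {j}) outside [0, {self.n_nodes})")
            canon.add((i, j) if i < j else (j, i))
        self.edges = canon
        self._adj: list[set[int]] | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_dyads(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def adjacency_sets(self) -> list[set[int]]:
        if self._adj is None:
            adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
            for i, j in self.edges:
                adj[i].add(j)
                adj[j].add(i)
            self._adj = adj
        return self._adj

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.uint8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    def has_edge(self, i: int, j: int) -> bool:
        return ((i, j) if i < j else (j, i)) in self.edges

    def with_edge(self, i: int, j: int, present: bool) -> "Graph":
        """Copy of the graph with dyad (i, j) set to ``present``."""
        e = (i, j) if i < j else (j, i)
        new = set(self.edges)
        (new.add if present else new.discard)(e)
        return Graph(self.n_nodes, new, list(self.node_labels))

    def dyads(self) -> Iterable[tuple[int, int]]:
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                yield i, j

    def copy(self) -> "Graph":
        return Graph(self.n_nodes, set(self.edges), list(self.node_labels))

    @classmethod
    def from_numpy(cls, a: np.ndarray, node_labels: Sequence | None = None) -> "Graph":
        n = a.shape[0]
        ii, jj = np.nonzero(np.triu(a, 1))
        edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
        return cls(n, edges, list(node_labels) if node_labels is not None else [])

    @classmethod
    def from_label_pairs(
        cls, pairs: Iterable[tuple], declared_nodes: Sequence | None = None
    ) -> "Graph":
        index: dict = {}
        if declared_nodes is not None:
            for lab in declared_nodes:
                if lab in index:
                    raise GraphValidationError(f"duplicate declared node {lab!r}")
                index[lab] = len(index)
        edges: set[tuple[int, int]] = set()
        n_dup = 0
        for a, b in pairs:
            for lab in (a, b):
                if lab not in index:
                    if declared_nodes is not None:
                        raise GraphValidationError(f"endpoint {lab!r} not in declared node list")
                    index[lab] = len(index)
            if a == b:
                raise GraphValidationError(f"self-loop on node {a!r}")
            i, j = index[a], index[b]
            e = (i, j) if i < j else (j, i)
            if e in edges:
                n_dup += 1
            edges.add(e)
        if n_dup:
            logger.warning("collapsed %d duplicate undirected edge(s)", n_dup)
        labels = list(index.keys())
        return cls(len(labels), edges, labels)


# -- I/O -----------------------------------------------------------------


def _open(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def read_edgelist(source, declared_nodes: Sequence | None = None) -> Graph:
    """Read a plain-text edge list: two tokens per line, ``#`` comments.

    Tokens may be separated by whitespace or commas.  ``declared_nodes``
    fixes the label order and admits isolates; without it, labels are indexed
    in order of first appearance.
    """
    fh, should_close = _open(source)
    pairs: list[tuple[str, str]] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise GraphParseError(
                    f"line {lineno}: expected two tokens, got {len(tokens)}: {raw.strip()!r}"
                )
            pairs.append((tokens[0], tokens[1]))
    finally:
        if should_close:
            fh.close()
    return Graph.from_label_pairs(pairs, declared_nodes)


def write_edgelist(g: Graph, target) -> None:
    """Write one ``label label`` line per edge, sorted by index pair."""
    fh, should_close = (target, False) if hasattr(target, "write") else (
        open(target, "w", encoding="utf-8"),
        True,
    )
    try:
        for i, j in sorted(g.edges):
            fh.write(f"{g.node_labels[i]} {g.node_labels[j]}\n")
    finally:
        if should_close:
            fh.close()


def read_node_list(source) -> list[str]:
    """One node label per line; '#' comments allowed."""
    fh, should_close = _open(source)
    try:
        labels = []
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                labels.append(line)
        return labels
    finally:
        if should_close:
            fh.close()


def read_pajek(source) -> Graph:
    """Minimal Pajek ``.net`` reader (``*Vertices`` / ``*Edges``, 1-based)."""
    fh, should_close = _open(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()
    n = 0
    labels: dict[int, str] = {}
    edges: list[tuple[str, str]] = []
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2:
                raise GraphParseError(f"line {lineno}: malformed *Vertices header")
            n = int(parts[1])
            section = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            section = "edges"
            continue
        if section == "vertices":
            parts = line.split(None, 1)
            idx = int(parts[0])
            lab = parts[1].strip().strip('"') if len(parts) > 1 else str(idx)
            labels[idx] = lab
        elif section == "edges":
            parts = line.split()
            if len(parts) < 2:
                raise GraphParseError(f"line {lineno}: malformed edge line {raw!r}")
            a, b = int(parts[0]), int(parts[1])
            for v in (a, b):
                if not (1 <= v <= n):
                    raise GraphValidationError(f"line {lineno}: vertex {v} outside 1..{n}")
            edges.append((str(a), str(b)))
        else:
            raise GraphParseError(f"line {lineno}: content before any *Vertices section")
    declared = [labels.get(i, str(i)) for i in range(1, n + 1)]
    # edge endpoints are 1-based indices; map through declared labels
    pairs = [(declared[int(a) - 1], declared[int(b) - 1]) for a, b in edges]
    return Graph.from_label_pairs(pairs, declared)


def read_node_attributes(source) -> "pd.DataFrame":
    """Delimited table: first column node label, remaining columns numeric."""
    import pandas as pd

    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.astype(float)


# -- motif counting ------------------------------------------------------


def degrees(g: Graph) -> np.ndarray:
    d = np.zeros(g.n_nodes, dtype=np.int64)
    for i, j in g.edges:
        d[i] += 1
        d[j] += 1
    return d


def count_kstars(g: Graph, k: int) -> int:
    """Number of k-stars, ``sum_v C(deg v, k)``.  k = 1 gives 2|E|."""
    if k < 1:
        raise ValueError(f"k-star order must be >= 1, got {k}")
    return int(sum(comb(int(d), k) for d in degrees(g)))


def count_triangles(g: Graph) -> int:
    """Number of closed unordered triples (= trace(A^3) / 6)."""
    adj = g.adjacency_sets()
    t = 0
    for i, j in g.edges:
        t += len(adj[i] & adj[j])
    return t // 3


def shared_partner_distributions(g: Graph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dyad-, edge- and nonedge-wise shared-partner spectra.

    Returns integer vectors ``(dsp, esp, nsp)`` indexed by the shared-partner
    count ``k = 0 .. max(n-2, 0)``; ``dsp = esp + nsp`` elementwise and the
    dsp spectrum sums to ``C(n, 2)``.
    """
    n = g.n_nodes
    size = max(n - 1, 1)
    dsp = np.zeros(size, dtype=np.int64)
    esp = np.zeros(size, dtype=np.int64)
    nsp = np.zeros(size, dtype=np.int64)
    adj = g.adjacency_sets()
    for i in range(n):
        for j in range(i + 1, n):
            k = len(adj[i] & adj[j])
            dsp[k] += 1
            if j in adj[i]:
                esp[k] += 1
            else:
                nsp[k] += 1
    return dsp, esp, nsp


def motif_summary(g: Graph, convention: str = "unordered") -> MotifCounts:
    """Edge, 2-star and triangle counts.

    ``convention="unordered"`` uses the statistic definitions above;
    ``"ordered"`` counts ordered 2-paths and ordered triangles (twice each),
    the convention of some published network summary tables.
    """
    if convention not in ("unordered", "ordered"):
        raise ValueError(f"unknown convention {convention!r}")
    mult = 1 if convention == "unordered" else 2
    return MotifCounts(
        edges=g.n_edges,
        two_stars=mult * count_kstars(g, 2),
        triangles=mult * count_triangles(g),
    )
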