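"""Catalog of ERGM sufficient statistics and their change statistics.

Fifteen term kinds are supported: the edge (intercept) term, the thirteen
endogenous statistics commonly used for binary undirected networks — k-star,
dyad/edge/nonedge-wise shared partners at a fixed order, triangle, isolates,
sociality, degree cross product, degree popularity, and the geometrically
weighted gwesp/gwnsp/gwdsp/gwdegree summaries — plus two basic exogenous
covariate terms (nodecov, absdiff).

Each term exposes the full statistic ``s(y)`` and the dyadic change statistic
``s(y_ij=1) - s(y_ij=0)``, computed locally from the dyad's neighbourhood
rather than by recounting the whole graph.  Toggle consistency between the
two is the central correctness property of the package and is enforced by
randomized tests against full-recount differences.

Conventions for terms whose formula is not fixed by their name follow the
reference ERGM software: degree cross product is the mean over edges of the
endpoint-degree product (0 on an empty graph) and degree popularity is
``sum_v deg(v)^{3/2}``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np

from .graphs import Dyad, Graph, count_kstars, count_triangles, degrees, shared_partner_distributions

__all__ = [
    "TermSpec",
    "TermConfigError",
    "KINDS",
    "BOUNDED_FAMILIES",
    "UNBOUNDED_ENDOGENOUS",
    "term_statistic",
    "change_statistic",
    "term_dimension",
    "parse_term",
    "format_term",
]

KINDS = (
    "edges",
    "kstar",
    "dsp",
    "esp",
    "nsp",
    "triangle",
    "isolates",
    "sociality",
    "degree_cross_product",
    "degree_popularity",
    "gwesp",
    "gwnsp",
    "gwdsp",
    "gwdegree",
    "nodecov",
    "absdiff",
)

#: families that need a data-driven upper bound on their order parameter
BOUNDED_FAMILIES = ("kstar", "dsp", "esp", "nsp")

#: the nine endogenous terms that take no order bound
UNBOUNDED_ENDOGENOUS = (
    "triangle",
    "isolates",
    "sociality",
    "degree_cross_product",
    "degree_popularity",
    "gwesp",
    "gwnsp",
    "gwdsp",
    "gwdegree",
)

_GW_KINDS = ("gwesp", "gwnsp", "gwdsp", "gwdegree")
_COV_KINDS = ("nodecov", "absdiff")


class TermConfigError(ValueError):
    """A TermSpec is missing or carries an inapplicable parameter."""


@dataclass(frozen=True)
class TermSpec:
    """One statistic: a kind plus its order / decay / covariate parameter."""

    kind: str
    order_k: Optional[int] = None
    decay: Optional[float] = None
    covariate: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TermConfigError(f"unknown term kind {self.kind!r}")
        if self.kind in BOUNDED_FAMILIES:
            if self.order_k is None or self.order_k < 1:
                raise TermConfigError(f"{self.kind} requires a positive order_k")
        elif self.order_k is not None:
            raise TermConfigError(f"{self.kind} takes no order_k")
        if self.kind in _GW_KINDS:
            if self.decay is None or self.decay < 0:
                raise TermConfigError(f"{self.kind} requires a nonnegative decay")
        elif self.decay is not None:
            raise TermConfigError(f"{self.kind} takes no decay")
        if self.kind in _COV_KINDS:
            if not self.covariate:
                raise TermConfigError(f"{self.kind} requires a covariate name")
        elif self.covariate is not None:
            raise TermConfigError(f"{self.kind} takes no covariate")

    @property
    def name(self) -> str:
        return format_term(self)

    def dimension(self, n_nodes: int) -> int:
        return term_dimension(self, n_nodes)


def term_dimension(t: TermSpec, n_nodes: int) -> int:
    """Sociality is an (n-1)-vector (node 0 is the reference); all else scalar."""
    if t.kind == "sociality":
        return max(n_nodes - 1, 0)
    return 1


# -- term mini-language ---------------------------------------------------

_TERM_RE = re.compile(r"^\s*([a-z_]+)\s*(?:\(\s*([^)]*?)\s*\))?\s*$")


def parse_term(text: str) -> TermSpec:
    """Parse ``"kstar(2)"``, ``"gwesp(0.5)"``, ``"nodecov(wealth)"``, ``"triangle"``."""
    m = _TERM_RE.match(text)
    if not m:
        raise TermConfigError(f"cannot parse term {text!r}")
    kind, arg = m.group(1), m.group(2)
    if kind not in KINDS:
        raise TermConfigError(f"unknown term kind {kind!r} in {text!r}")
    if kind in BOUNDED_FAMILIES:
        if arg in (None, ""):
            raise TermConfigError(f"{kind} requires an order, e.g. {kind}(2)")
        try:
            order = int(arg)
        except ValueError as exc:
            raise TermConfigError(f"bad order {arg!r} for {kind}") from exc
        return TermSpec(kind, order_k=order)
    if kind in _GW_KINDS:
        return TermSpec(kind, decay=float(arg) if arg not in (None, "") else 0.5)
    if kind in _COV_KINDS:
        if not arg:
            raise TermConfigError(f"{kind} requires a covariate name")
        return TermSpec(kind, covariate=arg)
    if arg not in (None, ""):
        raise TermConfigError(f"{kind} takes no argument")
    return TermSpec(kind)


def format_term(t: TermSpec) -> str:
    if t.kind in BOUNDED_FAMILIES:
        return f"{t.kind}({t.order_k})"
    if t.kind in _GW_KINDS:
        return f"{t.kind}({t.decay:g})"
    if t.kind in _COV_KINDS:
        return f"{t.kind}({t.covariate})"
    return t.kind


# -- helpers --------------------------------------------------------------


def _gw_weight(k: int, decay: float) -> float:
    """Weight of a spectrum cell at count k: e^tau * (1 - (1 - e^-tau)^k)."""
    if k <= 0:
        return 0.0
    return float(np.exp(decay) * (1.0 - (1.0 - np.exp(-decay)) ** k))


def _covariate_vector(t: TermSpec, g: Graph, attrs) -> np.ndarray:
    if attrs is None:
        raise TermConfigError(f"term {t.name} requires a node-attribute table")
    if t.covariate not in attrs.columns:
        raise TermConfigError(f"covariate {t.covariate!r} not in attribute table")
    col = attrs[t.covariate]
    try:
        return np.asarray([col[str(lab)] for lab in g.node_labels], dtype=float)
    except KeyError as exc:
        raise TermConfigError(f"attribute table missing node {exc.args[0]!r}") from exc


# -- full statistics ------------------------------------------------------


def term_statistic(t: TermSpec, g: Graph, attrs=None) -> np.ndarray:
    """Evaluate the full statistic s(y); returns a vector of the term's dimension."""
    kind = t.kind
    if kind == "edges":
        return np.array([g.n_edges], dtype=float)
    if kind == "kstar":
        return np.array([count_kstars(g, t.order_k)], dtype=float)
    if kind in ("dsp", "esp", "nsp"):
        dsp, esp, nsp = shared_partner_distributions(g)
        spec = {"dsp": dsp, "esp": esp, "nsp": nsp}[kind]
        k = t.order_k
        val = int(spec[k]) if k < len(spec) else 0
        return np.array([val], dtype=float)
    if kind == "triangle":
        return np.array([count_triangles(g)], dtype=float)
    if kind == "isolates":
        return np.array([int(np.sum(degrees(g) == 0))], dtype=float)
    if kind == "sociality":
        return degrees(g)[1:].astype(float)
    if kind == "degree_cross_product":
        if g.n_edges == 0:
            return np.array([0.0])
        d = degrees(g)
        s = sum(int(d[i]) * int(d[j]) for i, j in g.edges)
        return np.array([s / g.n_edges], dtype=float)
    if kind == "degree_popularity":
        d = degrees(g).astype(float)
        return np.array([float(np.sum(d**1.5))])
    if kind in ("gwesp", "gwnsp", "gwdsp"):
        dsp, esp, nsp = shared_partner_distributions(g)
        spec = {"gwdsp": dsp, "gwesp": esp, "gwnsp": nsp}[kind]
        val = sum(_gw_weight(k, t.decay) * int(spec[k]) for k in range(1, len(spec)))
        return np.array([val], dtype=float)
    if kind == "gwdegree":
        d = degrees(g)
        val = sum(_gw_weight(int(dv), t.decay) for dv in d)
        return np.array([val], dtype=float)
    if kind == "nodecov":
        x = _covariate_vector(t, g, attrs)
        return np.array([sum(x[i] + x[j] for i, j in g.edges)], dtype=float)
    if kind == "absdiff":
        x = _covariate_vector(t, g, attrs)
        return np.array([sum(abs(x[i] - x[j]) for i, j in g.edges)], dtype=float)
    raise TermConfigError(f"unhandled kind {kind!r}")  # pragma: no cover


# -- change statistics ----------------------------------------------------


def change_statistic(t: TermSpec, g: Graph, d: Dyad, attrs=None) -> np.ndarray:
    """Change statistic ``s(y_ij = 1) - s(y_ij = 0)`` for dyad ``d``.

    The value does not depend on the current state of the dyad in ``g``;
    computation always proceeds on the base graph with the dyad absent.
    """
    if not (0 <= d.i < g.n_nodes and 0 <= d.j < g.n_nodes):
        raise ValueError(f"dyad ({d.i}, {d.j}) outside graph with {g.n_nodes} nodes")
    base = g.with_edge(d.i, d.j, False) if g.has_edge(d.i, d.j) else g
    return _change_up(t, base, d.i, d.j, attrs)


def _change_up(t: TermSpec, g: Graph, i: int, j: int, attrs) -> np.ndarray:
    """Change from adding edge (i, j) to a graph where it is absent."""
    kind = t.kind
    adj = g.adjacency_sets()
    di, dj = len(adj[i]), len(adj[j])
    if kind == "edges":
        return np.array([1.0])
    if kind == "kstar":
        k = t.order_k
        return np.array([float(comb(di, k - 1) + comb(dj, k - 1))])
    if kind == "triangle":
        return np.array([float(len(adj[i] & adj[j]))])
    if kind == "isolates":
        return np.array([-float((di == 0) + (dj == 0))])
    if kind == "sociality":
        out = np.zeros(max(g.n_nodes - 1, 0))
        for v in (i, j):
            if v >= 1:
                out[v - 1] = 1.0
        return out
    if kind == "degree_popularity":
        return np.array(
            [
                (di + 1) ** 1.5 - di**1.5 + (dj + 1) ** 1.5 - dj**1.5
            ]
        )
    if kind == "gwdegree":
        tau = t.decay
        return np.array(
            [
                _gw_weight(di + 1, tau)
                - _gw_weight(di, tau)
                + _gw_weight(dj + 1, tau)
                - _gw_weight(dj, tau)
            ]
        )
    if kind == "degree_cross_product":
        m = g.n_edges
        d = degrees(g)
        s_old = sum(int(d[a]) * int(d[b]) for a, b in g.edges) if m else 0
        ds = sum(int(d[v]) for v in adj[i]) + sum(int(d[v]) for v in adj[j])
        s_new = s_old + ds + (di + 1) * (dj + 1)
        old = s_old / m if m else 0.0
        return np.array([s_new / (m + 1) - old])
    if kind in ("dsp", "esp", "nsp"):
        k = t.order_k
        d_dsp, d_esp = _sp_change_up(g, i, j, adj, k)
        if kind == "dsp":
            return np.array([float(d_dsp)])
        if kind == "esp":
            return np.array([float(d_esp)])
        return np.array([float(d_dsp - d_esp)])
    if kind in ("gwesp", "gwnsp", "gwdsp"):
        tau = t.decay
        d_gwdsp, d_gwesp = _gwsp_change_up(g, i, j, adj, tau)
        if kind == "gwdsp":
            return np.array([d_gwdsp])
        if kind == "gwesp":
            return np.array([d_gwesp])
        return np.array([d_gwdsp - d_gwesp])
    if kind == "nodecov":
        x = _covariate_vector(t, g, attrs)
        return np.array([x[i] + x[j]])
    if kind == "absdiff":
        x = _covariate_vector(t, g, attrs)
        return np.array([abs(x[i] - x[j])])
    raise TermConfigError(f"unhandled kind {kind!r}")  # pragma: no cover


def _sp_change_up(g: Graph, i: int, j: int, adj, k: int) -> tuple[int, int]:
    """(d dsp[k], d esp[k]) from adding edge (i, j).

    Adding (i, j) gives every dyad (i, w) with w in N(j)\\{i} one extra shared
    partner (namely j), and symmetrically for (j, w); the dyad (i, j) itself
    keeps its shared-partner count but switches from the nonedge to the edge
    class.
    """
    d_dsp = 0
    d_esp = 0
    for a, b in ((i, j), (j, i)):
        for w in adj[b]:
            if w == a:
                continue
            c = len(adj[a] & adj[w])
            delta = (1 if c + 1 == k else 0) - (1 if c == k else 0)
            d_dsp += delta
            if w in adj[a]:
                d_esp += delta
    cn = len(adj[i] & adj[j])
    if cn == k:
        d_esp += 1  # dyad (i, j) becomes an edge with k shared partners
    return d_dsp, d_esp


def _gwsp_change_up(g: Graph, i: int, j: int, adj, tau: float) -> tuple[float, float]:
    """(d gwdsp, d gwesp) from adding edge (i, j)."""
    d_gwdsp = 0.0
    d_gwesp = 0.0
    for a, b in ((i, j), (j, i)):
        for w in adj[b]:
            if w == a:
                continue
            c = len(adj[a] & adj[w])
            delta = _gw_weight(c + 1, tau) - _gw_weight(c, tau)
            d_gwdsp += delta
            if w in adj[a]:
                d_gwesp += delta
    cn = len(adj[i] & adj[j])
    d_gwesp += _gw_weight(cn, tau)
    return d_gwdsp, d_gwesp
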