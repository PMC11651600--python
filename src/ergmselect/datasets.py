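"""Bundled classic networks and synthetic graph generators.

The registry lists the nine benchmark networks commonly used for undirected
ERGM methodology, with their published node/edge/2-star/triangle counts
(2-stars and triangles in the ordered convention, see
:func:`ergmselect.graphs.motif_summary`).  Three of them are bundled as
plain-text edge lists rebuilt from canonical public sources (see
``scripts/make_fixtures.py``): the Zachary karate club, the Padgett
Florentine marriage network (with the Pucci isolate) and the Padgett
Florentine business network.  The remaining six circulate only inside
software archives that are not redistributable here; loading them raises
:class:`FixtureUnavailableError` so callers can fall back to synthetic data.

Synthetic generators cover every stage: Bernoulli random graphs and
well-mixed draws from small known ERGMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .engine import ERGMModel, MCMCConfig, simulate
from .graphs import Graph, motif_summary, read_edgelist, read_node_list

__all__ = [
    "FixtureEntry",
    "FixtureUnavailableError",
    "FixtureIntegrityError",
    "REGISTRY",
    "list_fixtures",
    "load_classic",
    "generate_bernoulli",
    "generate_from_ergm",
]


class FixtureUnavailableError(LookupError):
    """The named network is registered but its data is not bundled."""


class FixtureIntegrityError(RuntimeError):
    """A bundled fixture no longer matches its published counts."""


@dataclass(frozen=True)
class FixtureEntry:
    name: str
    n_nodes: int
    n_edges: int
    two_stars_ordered: int
    triangles_ordered: int
    filename: Optional[str]  # None -> not bundled


REGISTRY: dict[str, FixtureEntry] = {
    e.name: e
    for e in [
        FixtureEntry("lazega", 36, 115, 1852, 240, None),
        FixtureEntry("kapferer", 39, 158, 3132, 402, None),
        FixtureEntry("kapferer2", 43, 190, 4074, 504, None),
        FixtureEntry("zach", 34, 78, 1056, 90, "zach.edges"),
        FixtureEntry("molecule", 20, 28, 120, 12, None),
        FixtureEntry("faux_mesa_high", 205, 203, 1318, 124, None),
        FixtureEntry("ecoli", 418, 519, 10580, 84, None),
        FixtureEntry("florentine_marriage", 16, 20, 94, 6, "florentine_marriage.edges"),
        FixtureEntry("florentine_business", 16, 15, 72, 10, "florentine_business.edges"),
    ]
}


def list_fixtures() -> list[FixtureEntry]:
    return list(REGISTRY.values())


def load_classic(name: str) -> Graph:
    """Load a bundled classic network, validating its published counts."""
    if name not in REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(REGISTRY)}")
    entry = REGISTRY[name]
    if entry.filename is None:
        raise FixtureUnavailableError(
            f"network {name!r} is registered but its edge list is not bundled "
            "(no redistributable public source); use the synthetic generators instead"
        )
    pkg = resources.files("ergmselect").joinpath("data")
    nodes_file = pkg.joinpath(entry.filename.replace(".edges", ".nodes"))
    declared = None
    if nodes_file.is_file():
        with nodes_file.open("r") as fh:
            declared = read_node_list(fh)
    with pkg.joinpath(entry.filename).open("r") as fh:
        g = read_edgelist(fh, declared_nodes=declared)
    m = motif_summary(g, convention="ordered")
    observed = (g.n_nodes, g.n_edges, m.two_stars, m.triangles)
    expected = (entry.n_nodes, entry.n_edges, entry.two_stars_ordered, entry.triangles_ordered)
    if observed != expected:
        raise FixtureIntegrityError(
            f"fixture {name!r}: loaded (nodes, edges, 2-stars, triangles) = {observed}, "
            f"published = {expected}"
        )
    return g


def generate_bernoulli(n: int, p: float, seed: int) -> Graph:
    """G(n, p): every dyad present independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((i, j))
    return Graph(n, edges)


def generate_from_ergm(
    model: ERGMModel,
    theta: np.ndarray,
    n: int,
    seed: int,
    burn_factor: int = 100,
) -> Graph:
    """One well-mixed draw from the model via an extended-burn-in chain.

    The chain starts from a density-matched Bernoulli graph (density from
    the edge coefficient's Bernoulli limit) and runs ``burn_factor * C(n,2)``
    toggles before the draw is taken.
    """
    theta = np.asarray(theta, dtype=float)
    p0 = float(1.0 / (1.0 + np.exp(-theta[0])))
    g0 = generate_bernoulli(n, p0, seed=seed)
    d = n * (n - 1) // 2
    cfg = MCMCConfig(burn_in=burn_factor * d, interval=1, n_samples=1, seed=seed)
    _, graphs = simulate(model, theta, g0, cfg, return_graphs=True)
    return graphs[0]
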