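"""Term statistics vs naive recounts; change statistics vs toggle differences."""

from itertools import combinations
from math import comb, exp

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergmselect import (
    Dyad,
    TermConfigError,
    TermSpec,
    change_statistic,
    format_term,
    parse_term,
    term_statistic,
)

from conftest import attrs_for, random_graph

ALL_TERMS = [
    TermSpec("edges"),
    TermSpec("kstar", order_k=2),
    TermSpec("kstar", order_k=4),
    TermSpec("dsp", order_k=1),
    TermSpec("dsp", order_k=3),
    TermSpec("esp", order_k=1),
    TermSpec("esp", order_k=2),
    TermSpec("nsp", order_k=2),
    TermSpec("triangle"),
    TermSpec("isolates"),
    TermSpec("sociality"),
    TermSpec("degree_cross_product"),
    TermSpec("degree_popularity"),
    TermSpec("gwesp", decay=0.5),
    TermSpec("gwnsp", decay=0.8),
    TermSpec("gwdsp", decay=0.3),
    TermSpec("gwdegree", decay=0.5),
    TermSpec("nodecov", covariate="w"),
    TermSpec("absdiff", covariate="w"),
]

TERM_IDS = [t.name for t in ALL_TERMS]


def _naive_statistic(t, g, attrs):
    """From-scratch recount working only from the raw edge set."""
    n = g.n_nodes
    adj = {v: set() for v in range(n)}
    for i, j in g.edges:
        adj[i].add(j)
        adj[j].add(i)
    deg = {v: len(adj[v]) for v in range(n)}
    gw = lambda k, tau: exp(tau) * (1 - (1 - exp(-tau)) ** k) if k > 0 else 0.0  # noqa: E731

    def sp(i, j):
        return len(adj[i] & adj[j])

    kind = t.kind
    if kind == "edges":
        return [len(g.edges)]
    if kind == "kstar":
        return [sum(comb(deg[v], t.order_k) for v in range(n))]
    if kind == "dsp":
        return [sum(1 for i, j in combinations(range(n), 2) if sp(i, j) == t.order_k)]
    if kind == "esp":
        return [sum(1 for i, j in g.edges if sp(i, j) == t.order_k)]
    if kind == "nsp":
        return [
            sum(
                1
                for i, j in combinations(range(n), 2)
                if j not in adj[i] and sp(i, j) == t.order_k
            )
        ]
    if kind == "triangle":
        return [
            sum(
                1
                for a, b, c in combinations(range(n), 3)
                if b in adj[a] and c in adj[a] and c in adj[b]
            )
        ]
    if kind == "isolates":
        return [sum(1 for v in range(n) if deg[v] == 0)]
    if kind == "sociality":
        return [deg[v] for v in range(1, n)]
    if kind == "degree_cross_product":
        if not g.edges:
            return [0.0]
        return [sum(deg[i] * deg[j] for i, j in g.edges) / len(g.edges)]
    if kind == "degree_popularity":
        return [sum(deg[v] ** 1.5 for v in range(n))]
    if kind == "gwesp":
        return [sum(gw(sp(i, j), t.decay) for i, j in g.edges)]
    if kind == "gwnsp":
        return [
            sum(
                gw(sp(i, j), t.decay)
                for i, j in combinations(range(n), 2)
                if j not in adj[i]
            )
        ]
    if kind == "gwdsp":
        return [sum(gw(sp(i, j), t.decay) for i, j in combinations(range(n), 2))]
    if kind == "gwdegree":
        return [sum(gw(deg[v], t.decay) for v in range(n))]
    x = [attrs.loc[str(lab), t.covariate] for lab in g.node_labels]
    if kind == "nodecov":
        return [sum(x[i] + x[j] for i, j in g.edges)]
    if kind == "absdiff":
        return [sum(abs(x[i] - x[j]) for i, j in g.edges)]
    raise AssertionError(kind)


@pytest.mark.parametrize("term", ALL_TERMS, ids=TERM_IDS)
def test_statistic_matches_naive_recount(term, rng):
    for _ in range(12):
        g = random_graph(rng, n_min=4, n_max=7, p=0.4)
        attrs = attrs_for(g, rng)
        got = term_statistic(term, g, attrs)
        want = np.asarray(_naive_statistic(term, g, attrs), dtype=float)
        np.testing.assert_allclose(got, want, atol=1e-10)


@pytest.mark.parametrize("term", ALL_TERMS, ids=TERM_IDS)
def test_change_statistic_equals_toggle_difference(term, rng):
    """The central correctness oracle: local change = full-recount difference,
    in both toggle directions."""
    for _ in range(25):
        g = random_graph(rng, n_min=3, n_max=10)
        attrs = attrs_for(g, rng)
        i, j = sorted(int(v) for v in rng.choice(g.n_nodes, 2, replace=False))
        d = Dyad(i, j)
        ch = change_statistic(term, g, d, attrs)
        diff = term_statistic(term, g.with_edge(i, j, True), attrs) - term_statistic(
            term, g.with_edge(i, j, False), attrs
        )
        np.testing.assert_allclose(ch, diff, atol=1e-9)


def test_change_statistic_examples(triangle_graph):
    assert change_statistic(TermSpec("edges"), triangle_graph, Dyad(0, 1))[0] == 1.0
    # triangle change on a dyad = number of common neighbours
    assert change_statistic(TermSpec("triangle"), triangle_graph, Dyad(0, 1))[0] == 1.0
    with pytest.raises(ValueError):
        change_statistic(TermSpec("edges"), triangle_graph, Dyad(0, 7))


def test_gwesp_single_triangle_independent_of_decay(triangle_graph):
    for tau in (0.0, 0.25, 0.5, 1.5):
        val = term_statistic(TermSpec("gwesp", decay=tau), triangle_graph)[0]
        assert val == pytest.approx(3.0, abs=1e-12)


def test_gwesp_zero_decay_counts_edges_with_shared_partner(rng):
    for _ in range(10):
        g = random_graph(rng, n_min=5, n_max=9)
        adj = g.adjacency_sets()
        expected = sum(1 for i, j in g.edges if len(adj[i] & adj[j]) >= 1)
        got = term_statistic(TermSpec("gwesp", decay=0.0), g)[0]
        assert got == pytest.approx(expected, abs=1e-12)


def test_sociality_sums_to_twice_edges_minus_reference(rng):
    from ergmselect import degrees

    for _ in range(10):
        g = random_graph(rng)
        soc = term_statistic(TermSpec("sociality"), g)
        assert soc.sum() + degrees(g)[0] == 2 * g.n_edges


def test_dsp_terms_partition_all_dyads(rng):
    g = random_graph(rng, n_min=6, n_max=6)
    total = sum(
        term_statistic(TermSpec("dsp", order_k=k), g)[0] for k in range(1, g.n_nodes - 1)
    )
    dsp0 = sum(
        1
        for i, j in combinations(range(g.n_nodes), 2)
        if len(g.adjacency_sets()[i] & g.adjacency_sets()[j]) == 0
    )
    assert total + dsp0 == comb(g.n_nodes, 2)


# -- spec validation and the term mini-language --------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(kind="kstar"),  # missing order
        dict(kind="kstar", order_k=0),
        dict(kind="triangle", order_k=2),  # inapplicable order
        dict(kind="gwesp"),  # missing decay
        dict(kind="gwesp", decay=-0.1),
        dict(kind="triangle", decay=0.5),
        dict(kind="nodecov"),  # missing covariate
        dict(kind="edges", covariate="w"),
        dict(kind="nonsense"),
    ],
)
def test_termspec_validation(kwargs):
    with pytest.raises(TermConfigError):
        TermSpec(**kwargs)


@pytest.mark.parametrize(
    "text", ["edges", "triangle", "kstar(2)", "dsp(3)", "gwesp(0.5)", "gwdegree(1.25)", "nodecov(wealth)", "absdiff(age)"]
)
def test_term_language_roundtrip(text):
    assert format_term(parse_term(text)) == text


@pytest.mark.parametrize("text", ["kstar", "kstar()", "nodecov", "triangle(2)", "foo(1)"])
def test_term_language_rejects(text):
    with pytest.raises(TermConfigError):
        parse_term(text)


def test_covariate_term_requires_attrs(triangle_graph):
    with pytest.raises(TermConfigError):
        term_statistic(TermSpec("nodecov", covariate="w"), triangle_graph, None)


@given(st.integers(0, 2**30))
@settings(max_examples=25, deadline=None)
def test_kernel_change_matches_python(seed):
    """The compiled sampler's change statistics equal the Python catalog's."""
    from ergmselect import ERGMModel
    from ergmselect import _kernel
    from ergmselect.engine import _CompiledModel

    rng = np.random.default_rng(seed)
    g = random_graph(rng, n_min=3, n_max=9)
    attrs = attrs_for(g, rng)
    model = ERGMModel(tuple(ALL_TERMS), attrs=attrs)
    cm = _CompiledModel(model, g)
    i, j = sorted(int(v) for v in rng.choice(g.n_nodes, 2, replace=False))
    base = g.with_edge(i, j, False)
    A = base.adjacency_matrix()
    deg = A.sum(axis=1).astype(np.int64)
    out = np.zeros(cm.dim)
    _kernel._change_up(
        A, deg, cm.x, cm.codes, cm.kparam, cm.fparam, cm.covidx, cm.offsets, out, i, j
    )
    np.testing.assert_allclose(out, model.change_vector(g, Dyad(i, j)), atol=1e-9)
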