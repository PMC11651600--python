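"""Simulation, estimation and AIC machinery against the enumeration oracle."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from ergmselect import (
    CapabilityError,
    ERGMModel,
    FitOptions,
    Graph,
    MCMCConfig,
    TermSpec,
    cd_initialize,
    enumerate_graph_statistics,
    exact_expected_statistics,
    exact_loglik,
    fit_mcmcmle,
    generate_bernoulli,
    is_divergent,
    mple,
    simulate,
)
from ergmselect.engine import certified_divergence

from conftest import attrs_for


def edges_model():
    return ERGMModel.from_endogenous([])


def edge_triangle_model():
    return ERGMModel.from_endogenous([TermSpec("triangle")])


@pytest.fixture(scope="module")
def g5():
    return generate_bernoulli(5, 0.5, seed=1)


# -- model construction --------------------------------------------------


def test_model_requires_leading_edges_term():
    with pytest.raises(ValueError):
        ERGMModel([TermSpec("triangle")])
    with pytest.raises(ValueError):
        ERGMModel([TermSpec("edges"), TermSpec("edges")])
    with pytest.raises(ValueError):
        ERGMModel([TermSpec("edges"), TermSpec("triangle"), TermSpec("triangle")])


def test_model_dimension_counts_sociality_block():
    m = ERGMModel.from_endogenous([TermSpec("sociality")])
    assert m.dimension(10) == 1 + 9


# -- exact enumeration ---------------------------------------------------


def test_exact_loglik_closed_forms(g5):
    D = comb(5, 2)
    assert exact_loglik(edges_model(), np.array([0.0]), g5) == pytest.approx(-D * np.log(2))
    th = 0.73
    expected = g5.n_edges * th - D * np.log1p(np.exp(th))
    assert exact_loglik(edges_model(), np.array([th]), g5) == pytest.approx(expected)


def test_exact_loglik_matches_independent_enumeration(g5):
    """Second, naive enumeration of all 1024 graphs on n = 5."""
    model = edge_triangle_model()
    theta = np.array([-0.3, 0.5])
    dyads = list(combinations(range(5), 2))
    weights = []
    for mask in range(1 << 10):
        edges = {dyads[b] for b in range(10) if mask >> b & 1}
        adj = {v: set() for v in range(5)}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        tri = sum(
            1 for a, b, c in combinations(range(5), 3) if b in adj[a] and c in adj[a] and c in adj[b]
        )
        weights.append(theta[0] * len(edges) + theta[1] * tri)
    log_psi = logsumexp(weights)
    want = float(model.statistics(g5) @ theta) - log_psi
    assert exact_loglik(model, theta, g5) == pytest.approx(want, abs=1e-10)


def test_exact_loglik_scale_guard():
    g = generate_bernoulli(8, 0.3, seed=0)  # 28 dyads > 21
    with pytest.raises(CapabilityError):
        exact_loglik(edges_model(), np.array([0.0]), g)


# -- simulation ----------------------------------------------------------

def test_simulate_bernoulli_density(g5):
    D = comb(5, 2)
    stats, _ = simulate(edges_model(), np.array([0.0]), g5, MCMCConfig(n_samples=1500, seed=2))
    se = stats[:, 0].std(ddof=1) / np.sqrt(len(stats))
    assert abs(stats[:, 0].mean() - D / 2) < 3 * se + 0.05

    p = 0.2
    th = np.log(p / (1 - p))
    stats, _ = simulate(edges_model(), np.array([th]), g5, MCMCConfig(n_samples=1500, seed=3))
    se = stats[:, 0].std(ddof=1) / np.sqrt(len(stats))
    assert abs(stats[:, 0].mean() - D * p) < 3 * se + 0.05


def test_simulate_matches_exact_expectations(g5):
    model = edge_triangle_model()
    theta = np.array([-0.5, 0.4])
    exact = exact_expected_statistics(model, theta, 5)
    stats, _ = simulate(model, theta, g5, MCMCConfig(n_samples=3000, seed=11))
    se = stats.std(axis=0, ddof=1) / np.sqrt(len(stats))
    assert np.all(np.abs(stats.mean(axis=0) - exact) < 3 * se + 1e-3)


def test_simulate_deterministic_under_seed(g5):
    model = edge_triangle_model()
    a, _ = simulate(model, np.array([-0.2, 0.1]), g5, MCMCConfig(n_samples=50, seed=9))
    b, _ = simulate(model, np.array([-0.2, 0.1]), g5, MCMCConfig(n_samples=50, seed=9))
    np.testing.assert_array_equal(a, b)


def test_simulate_rejects_nonfinite_theta(g5):
    with pytest.raises(ValueError):
        simulate(edges_model(), np.array([np.inf]), g5, MCMCConfig(n_samples=2, seed=0))


def test_simulated_graphs_consistent_with_stats(g5):
    model = edge_triangle_model()
    stats, graphs = simulate(
        model, np.array([0.1, 0.2]), g5, MCMCConfig(n_samples=20, seed=4), return_graphs=True
    )
    for s, gr in zip(stats, graphs):
        np.testing.assert_allclose(s, model.statistics(gr))


# -- MPLE ----------------------------------------------------------------


def test_mple_edges_only_closed_form(rng):
    for _ in range(5):
        n = int(rng.integers(6, 15))
        g = generate_bernoulli(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(1 << 30)))
        if g.n_edges in (0, g.n_dyads):
            continue
        res = mple(edges_model(), g)
        want = np.log(g.n_edges / (g.n_dyads - g.n_edges))
        assert res.theta[0] == pytest.approx(want, rel=1e-10)
        assert res.aic == pytest.approx(-2 * res.loglik + 2)


def test_mple_zero_change_column_flags_divergence():
    # kstar(4) on a path: statistic identically 0, observed count at minimum
    path = Graph(5, {(0, 1), (1, 2), (2, 3), (3, 4)})
    model = ERGMModel.from_endogenous([TermSpec("kstar", order_k=4)])
    res = mple(model, path)
    assert is_divergent(res)[1] == -1
    assert not np.isfinite(res.aic)


def test_mple_dyad_independent_equals_exact_mle(rng):
    g = generate_bernoulli(5, 0.6, seed=8)
    attrs = attrs_for(g, rng)
    model = ERGMModel.from_endogenous([TermSpec("nodecov", covariate="w")], attrs=attrs)
    res = mple(model, g)
    S = enumerate_graph_statistics(model, 5, g.node_labels)
    obs = model.statistics(g)
    nll = lambda th: -(obs @ th - logsumexp(S @ th))  # noqa: E731
    opt = minimize(nll, np.zeros(2), method="BFGS")
    np.testing.assert_allclose(res.theta, opt.x, atol=1e-5)
    assert res.loglik == pytest.approx(-opt.fun, abs=1e-6)


# -- divergence certification -------------------------------------------


def test_certificate_on_boundary_statistics():
    g = Graph(5, {(0, 1), (1, 2)})  # no triangles
    cert = certified_divergence(edge_triangle_model(), g)
    assert cert.tolist() == [0, -1]
    empty = Graph(4)
    assert certified_divergence(edges_model(), empty)[0] == -1
    full = Graph(4, set(combinations(range(4), 2)))
    assert certified_divergence(edges_model(), full)[0] == 1


def test_divergence_flags_match_hull_oracle_n4():
    """On enumerable models the MLE exists iff the observed statistic lies in
    the relative interior of the convex hull of attainable statistics."""
    model = edge_triangle_model()
    S = enumerate_graph_statistics(model, 4)
    pts = np.unique(S, axis=0)
    cases = [
        Graph(4, set()),  # empty: boundary
        Graph(4, {(0, 1), (1, 2), (2, 3)}),  # path: triangles at min -> boundary
        Graph(4, set(combinations(range(4), 2))),  # complete: boundary
        Graph(4, {(0, 1), (0, 2), (1, 2), (2, 3)}),  # interior
    ]
    for g in cases:
        obs = model.statistics(g)
        interior = _in_relative_interior(pts, obs)
        fitres = fit_mcmcmle(
            model, g, cfg=MCMCConfig(n_samples=256, seed=5),
            options=FitOptions(compute_loglik=False),
        )
        assert fitres.divergent == (not interior), (obs, interior, fitres.directions)


def _in_relative_interior(pts, x):
    # 2-d hull check: x strictly inside conv(pts) (no supporting hyperplane
    # through x). Works for full-dimensional 2-d point clouds.
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    eqs = hull.equations  # A x + b <= 0 on the hull
    margins = eqs[:, :-1] @ x + eqs[:, -1]
    return bool(np.all(margins < -1e-9))


# -- contrastive divergence ----------------------------------------------


def test_cd_recovers_bernoulli_logit():
    g = generate_bernoulli(10, 0.4, seed=6)
    theta = cd_initialize(edges_model(), g, MCMCConfig(seed=3))
    want = np.log(g.n_edges / (g.n_dyads - g.n_edges))
    assert abs(theta[0] - want) < 0.5


def test_cd_moves_toward_exact_mle_on_toy_two_term():
    """CD is an initializer, not the MLE: short chains give a biased fixed
    point, but the start it returns must climb the exact likelihood surface
    into the MLE's basin (within ~1.5 nats of the optimum on this toy)."""
    from ergmselect.engine import mple as _mple

    g = generate_bernoulli(5, 0.5, seed=1)
    model = edge_triangle_model()
    S = enumerate_graph_statistics(model, 5)
    obs = model.statistics(g)
    nll = lambda th: -(obs @ th - logsumexp(S @ th))  # noqa: E731
    opt = minimize(nll, np.zeros(2), method="BFGS")
    start = np.clip(_mple(model, g).theta, -3, 3)
    theta = cd_initialize(model, g, MCMCConfig(seed=17))
    ll_start = exact_loglik(model, start, g)
    ll_cd = exact_loglik(model, theta, g)
    assert ll_cd >= ll_start
    assert (-opt.fun) - ll_cd < 1.5


def test_cd_empty_graph_divergence_route():
    g = Graph(6)
    fitres = fit_mcmcmle(edges_model(), g, cfg=MCMCConfig(seed=0))
    assert fitres.divergent and is_divergent(fitres)[0] == -1


# -- MCMC MLE ------------------------------------------------------------


def test_mcmcmle_edges_only_matches_bernoulli_aic(g5):
    res = fit_mcmcmle(
        edges_model(), g5, cfg=MCMCConfig(seed=3), options=FitOptions(force_mcmc=True)
    )
    th0 = np.log(g5.n_edges / (g5.n_dyads - g5.n_edges))
    exact_aic = -2 * (g5.n_edges * th0 - g5.n_dyads * np.log1p(np.exp(th0))) + 2
    assert res.aic == pytest.approx(exact_aic, abs=0.25)


def test_mcmcmle_two_term_matches_enumeration(g5):
    model = edge_triangle_model()
    S = enumerate_graph_statistics(model, 5)
    obs = model.statistics(g5)
    nll = lambda th: -(obs @ th - logsumexp(S @ th))  # noqa: E731
    opt = minimize(nll, np.zeros(2), method="BFGS")
    res = fit_mcmcmle(model, g5, cfg=MCMCConfig(seed=21))
    assert res.converged and not res.divergent
    assert np.linalg.norm(res.theta - opt.x) < 0.35
    mc_se = res.diagnostics["loglik_mc_se"]
    assert abs(res.loglik - (-opt.fun)) < 3 * mc_se + 0.05


def test_mcmcmle_deterministic_under_seed(g5):
    model = edge_triangle_model()
    a = fit_mcmcmle(model, g5, cfg=MCMCConfig(seed=33))
    b = fit_mcmcmle(model, g5, cfg=MCMCConfig(seed=33))
    np.testing.assert_array_equal(a.theta, b.theta)
    assert a.aic == b.aic


def test_path_sampled_loglik_matches_independent_bridge():
    """Dual-route check on a real 16-node network: the thermodynamic
    integration estimate must agree with an independent importance-sampling
    bridge built from i.i.d. Bernoulli reference draws.

    The marriage network is used because its fitted gwesp coefficient is
    small, so the single-step bridge from the Bernoulli reference keeps a
    healthy effective sample size (on strongly transitive networks the
    one-step bridge collapses and only the path estimator stays reliable).
    """
    from ergmselect import generate_bernoulli as gb, load_classic

    g = load_classic("florentine_marriage")
    model = ERGMModel.from_endogenous([TermSpec("gwesp", decay=0.5)])
    res = fit_mcmcmle(model, g, cfg=MCMCConfig(seed=5))
    dens = g.n_edges / g.n_dyads
    th0 = np.log(dens / (1 - dens))
    ref = np.array([th0, 0.0])
    u = res.theta - ref
    rng = np.random.default_rng(99)
    vals = np.array(
        [
            u @ model.statistics(gb(g.n_nodes, dens, seed=int(rng.integers(1 << 30))))
            for _ in range(3000)
        ]
    )
    log_ratio = logsumexp(vals) - np.log(len(vals))
    log_psi_ref = g.n_dyads * np.log1p(np.exp(th0))
    bridge_ll = float(res.theta @ model.statistics(g) - (log_psi_ref + log_ratio))
    assert abs(res.loglik - bridge_ll) < 0.05


def test_parameter_recovery_from_simulated_data():
    """Refitting data simulated at known coefficients recovers them within
    sampling tolerance: exactly for the Bernoulli model's closed form, and
    within a generous single-draw band for edges+gwesp at n = 30."""
    from ergmselect import generate_from_ergm

    null = edges_model()
    theta0 = np.log(0.3 / 0.7)
    edge_counts = []
    for s in range(40):
        g = generate_from_ergm(null, np.array([theta0]), n=30, seed=100 + s)
        edge_counts.append(g.n_edges)
    d = 30 * 29 // 2
    se = np.sqrt(d * 0.3 * 0.7 / 40)
    assert abs(np.mean(edge_counts) - 0.3 * d) < 4 * se

    model = ERGMModel.from_endogenous([TermSpec("gwesp", decay=0.5)])
    theta_true = np.array([-2.5, 0.8])
    g = generate_from_ergm(model, theta_true, n=30, seed=314)
    res = fit_mcmcmle(model, g, cfg=MCMCConfig(seed=3), options=FitOptions(compute_loglik=False))
    assert not res.divergent
    assert np.all(np.abs(res.theta - theta_true) < 1.0)


def test_mcmcmle_boundary_statistic_flags_negative_infinity():
    # edge + kstar(3) where the observed 3-star count is 0
    g = Graph(6, {(0, 1), (2, 3), (4, 5)})
    model = ERGMModel.from_endogenous([TermSpec("kstar", order_k=3)])
    res = fit_mcmcmle(model, g, cfg=MCMCConfig(seed=2))
    assert is_divergent(res)[1] == -1
    assert not np.isfinite(res.aic)
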