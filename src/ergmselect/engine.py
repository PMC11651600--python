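"""ERGM probability model, simulation, estimation and AIC machinery.

The model is the exponential family over graphs on a fixed node set,

    P_theta(Y = y) = exp{ theta' s(y) } / psi(theta),

with s(y) the concatenated term statistics (the edge term first).  Three
estimation routes are provided:

* ``mple`` — maximum pseudo-likelihood, i.e. logistic regression of the dyad
  indicators on the change statistics.  Exact MLE for dyad-independent
  models; the standard cheap initializer otherwise, and the place where
  complete separation ("estimates at infinity") is detected.
* ``cd_initialize`` — contrastive-divergence refinement of starting values
  via short chains restarted at the observed graph with Robbins-Monro steps.
* ``fit_mcmcmle`` — Monte-Carlo MLE by importance-weighted Newton updates,
  followed by a thermodynamic-integration estimate of the log-likelihood
  (linear path from a fitted Bernoulli reference model) and hence the AIC.

``exact_loglik`` enumerates all graphs at toy scale and anchors every
stochastic estimator in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from . import _kernel
from .graphs import Dyad, Graph
from .terms import TermSpec, change_statistic, term_statistic

logger = logging.getLogger(__name__)

__all__ = [
    "ERGMModel",
    "MCMCConfig",
    "FitOptions",
    "FitResult",
    "CapabilityError",
    "simulate",
    "exact_loglik",
    "enumerate_graph_statistics",
    "exact_expected_statistics",
    "mple",
    "cd_initialize",
    "fit_mcmcmle",
    "fit",
    "is_divergent",
    "derive_seed",
]

_DYAD_INDEPENDENT_KINDS = {"edges", "sociality", "nodecov", "absdiff"}

#: kinds whose statistic is a nonnegative count-like quantity with minimum 0;
#: an observed value of 0 puts s_obs on the boundary of the convex hull of
#: attainable statistics, where the MLE does not exist (direction -inf).
_NONNEG_COUNT_KINDS = {
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
}


class CapabilityError(RuntimeError):
    """Requested an exact computation beyond enumerable scale."""


def derive_seed(root: int, *tokens) -> int:
    """Deterministic child seed below 2**31 from a root seed and tokens."""
    ss = np.random.SeedSequence([int(root) & 0x7FFFFFFF] + [_token_int(t) for t in tokens])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def _token_int(t) -> int:
    if isinstance(t, (int, np.integer)):
        return int(t) & 0x7FFFFFFF
    import zlib

    return zlib.crc32(str(t).encode()) & 0x7FFFFFFF


# -- model ---------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ERGMModel:
    """An ordered term list (edges first) plus an optional attribute table."""

    terms: tuple[TermSpec, ...]
    attrs: Optional[object] = None  # pandas DataFrame indexed by node label

    def __init__(self, terms: Sequence[TermSpec], attrs=None):
        terms = tuple(terms)
        if not terms or terms[0].kind != "edges":
            raise ValueError("model must start with the edges term")
        if sum(1 for t in terms if t.kind == "edges") != 1:
            raise ValueError("exactly one edges term allowed")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in model")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "attrs", attrs)

    @classmethod
    def from_endogenous(cls, extra: Sequence[TermSpec], attrs=None) -> "ERGMModel":
        return cls((TermSpec("edges"), *extra), attrs=attrs)

    def dimension(self, n_nodes: int) -> int:
        return sum(t.dimension(n_nodes) for t in self.terms)

    def term_offsets(self, n_nodes: int) -> list[int]:
        offs, acc = [], 0
        for t in self.terms:
            offs.append(acc)
            acc += t.dimension(n_nodes)
        return offs

    def statistics(self, g: Graph) -> np.ndarray:
        return np.concatenate([term_statistic(t, g, self.attrs) for t in self.terms])

    def change_vector(self, g: Graph, d: Dyad) -> np.ndarray:
        return np.concatenate([change_statistic(t, g, d, self.attrs) for t in self.terms])

    @property
    def is_dyad_independent(self) -> bool:
        return all(t.kind in _DYAD_INDEPENDENT_KINDS for t in self.terms)

    def describe(self) -> list[str]:
        return [t.name for t in self.terms]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings; ``None`` for burn_in/interval means the per-graph
    defaults 20 * C(n,2) and C(n,2) toggles."""

    burn_in: Optional[int] = None
    interval: Optional[int] = None
    n_samples: int = 512
    seed: int = 0

    def resolve(self, n_nodes: int) -> "MCMCConfig":
        d = n_nodes * (n_nodes - 1) // 2
        burn = self.burn_in if self.burn_in is not None else 20 * d
        interval = self.interval if self.interval is not None else max(d, 1)
        if burn < 0 or interval < 1 or self.n_samples < 1:
            raise ValueError("burn_in >= 0, interval >= 1, n_samples >= 1 required")
        return MCMCConfig(burn, interval, self.n_samples, self.seed)


@dataclass(frozen=True)
class FitOptions:
    """Estimation settings shared by the fitting entry points."""

    method: str = "mcmcmle"  # "mcmcmle" or "mple"
    divergence_threshold: float = 20.0
    mcmle_max_iter: int = 8
    mcmle_step_bound: float = 1.0
    ti_points: int = 16
    ti_samples: int = 512
    compute_loglik: bool = True
    force_mcmc: bool = False
    cd_iters: int = 300
    cd_chain_factor: int = 4  # CD chain length = factor * C(n,2) toggles
    cd_a: float = 1.0
    cd_b: float = 10.0


@dataclass
class FitResult:
    """Estimate, estimated log-likelihood/AIC and divergence flags."""

    model: ERGMModel
    theta: np.ndarray
    loglik: float
    aic: float
    converged: bool
    directions: np.ndarray  # per-coordinate: -1, 0, +1 ("reaching infinity")
    diagnostics: dict = field(default_factory=dict)

    @property
    def divergent(self) -> bool:
        return bool(np.any(self.directions != 0))

    def to_record(self) -> dict:
        return {
            "terms": self.model.describe(),
            "theta": [None if not np.isfinite(v) else float(v) for v in self.theta],
            "loglik": None if not np.isfinite(self.loglik) else float(self.loglik),
            "aic": None if not np.isfinite(self.aic) else float(self.aic),
            "converged": bool(self.converged),
            "divergent": self.divergent,
            "directions": [int(v) for v in self.directions],
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if isinstance(v, (int, float, str, bool))
            },
        }


def is_divergent(f: FitResult) -> np.ndarray:
    """Per-coordinate divergence directions (-1, 0, +1)."""
    return f.directions


def certified_divergence(model: ERGMModel, g: Graph) -> np.ndarray:
    """Coordinates whose MLE provably does not exist ("reaching infinity").

    For nonnegative count-like statistics an observed value of 0 lies at the
    minimum of the attainable range, hence on the boundary of the convex
    hull of sufficient statistics, where the exponential-family MLE diverges
    to -infinity.  The observed complete graph certifies +infinity for the
    edge coordinate.  This is a sufficient (one-sided) certificate; softer
    failures are caught later from |theta| thresholds and degenerate chains.
    """
    obs = model.statistics(g)
    n = g.n_nodes
    dirs = np.zeros(len(obs), dtype=np.int8)
    off = 0
    for t in model.terms:
        d = t.dimension(n)
        if t.kind in _NONNEG_COUNT_KINDS:
            for q in range(off, off + d):
                if obs[q] == 0:
                    dirs[q] = -1
        if t.kind == "edges" and g.n_edges == g.n_dyads and g.n_dyads > 0:
            dirs[off] = 1
        off += d
    return dirs


# -- kernel bridge -------------------------------------------------------


class _CompiledModel:
    """Dense-array encoding of a model for the numba kernel."""

    def __init__(self, model: ERGMModel, g: Graph):
        n = g.n_nodes
        codes, kparam, fparam, covidx, offsets = [], [], [], [], []
        covs: list[str] = []
        off = 0
        for t in model.terms:
            codes.append(_kernel.CODE[t.kind])
            kparam.append(t.order_k or 0)
            fparam.append(t.decay if t.decay is not None else 0.0)
            if t.covariate is not None:
                if t.covariate not in covs:
                    covs.append(t.covariate)
                covidx.append(covs.index(t.covariate))
            else:
                covidx.append(-1)
            offsets.append(off)
            off += t.dimension(n)
        self.dim = off
        self.codes = np.asarray(codes, dtype=np.int64)
        self.kparam = np.asarray(kparam, dtype=np.int64)
        self.fparam = np.asarray(fparam, dtype=np.float64)
        self.covidx = np.asarray(covidx, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        if covs:
            from .terms import _covariate_vector

            cols = [
                _covariate_vector(TermSpec("nodecov", covariate=c), g, model.attrs) for c in covs
            ]
            self.x = np.column_stack(cols).astype(np.float64)
        else:
            self.x = np.zeros((n, 1), dtype=np.float64)


class _Chain:
    """A persistent MH chain over one model, advanced in segments."""

    def __init__(self, model: ERGMModel, theta: np.ndarray, g0: Graph, seed: int):
        self.model = model
        self.cm = _CompiledModel(model, g0)
        self.A = g0.adjacency_matrix()
        self.deg = self.A.sum(axis=1).astype(np.int64)
        self.theta = np.asarray(theta, dtype=np.float64).copy()
        if self.theta.shape != (self.cm.dim,):
            raise ValueError(f"theta has dim {self.theta.shape}, model dim {self.cm.dim}")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite parameter vector")
        self.stats = model.statistics(g0).astype(np.float64)
        self.state = _kernel.make_rng_state(seed)
        self._delta = np.empty(self.cm.dim, dtype=np.float64)
        self.labels = list(g0.node_labels)

    def set_theta(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=np.float64)
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite parameter vector")
        self.theta = theta.copy()

    def advance(self, n_steps: int) -> None:
        _kernel.advance(
            self.A,
            self.deg,
            self.cm.x,
            self.cm.codes,
            self.cm.kparam,
            self.cm.fparam,
            self.cm.covidx,
            self.cm.offsets,
            self.theta,
            self.stats,
            n_steps,
            self.state,
            self._delta,
        )

    def graph(self) -> Graph:
        return Graph.from_numpy(self.A, self.labels)


def simulate(
    model: ERGMModel,
    theta: np.ndarray,
    g0: Graph,
    cfg: MCMCConfig,
    return_graphs: bool = False,
):
    """Draw networks (or their statistics) from P_theta by MH dyad toggles.

    Returns ``(stats, graphs)`` where ``stats`` is an (n_samples, dim) array
    and ``graphs`` a list of Graph (``None`` unless ``return_graphs``).
    """
    cfg = cfg.resolve(g0.n_nodes)
    chain = _Chain(model, theta, g0, cfg.seed)
    chain.advance(cfg.burn_in)
    stats = np.empty((cfg.n_samples, chain.cm.dim))
    graphs = [] if return_graphs else None
    for s in range(cfg.n_samples):
        chain.advance(cfg.interval)
        stats[s] = chain.stats
        if return_graphs:
            graphs.append(chain.graph())
    return stats, graphs


# -- exact enumeration oracle --------------------------------------------


def enumerate_graph_statistics(model: ERGMModel, n_nodes: int, node_labels=None) -> np.ndarray:
    """Statistics of every graph on ``n_nodes`` nodes (2**C(n,2) rows)."""
    n_dyads = n_nodes * (n_nodes - 1) // 2
    if n_dyads > 21:
        raise CapabilityError(
            f"enumeration needs C(n,2) <= 21 dyads, got {n_dyads} (n = {n_nodes})"
        )
    dyads = list(combinations(range(n_nodes), 2))
    labels = list(node_labels) if node_labels is not None else list(range(n_nodes))
    dim = model.dimension(n_nodes)
    out = np.empty((1 << n_dyads, dim))
    for mask in range(1 << n_dyads):
        edges = {dyads[b] for b in range(n_dyads) if mask >> b & 1}
        out[mask] = model.statistics(Graph(n_nodes, edges, list(labels)))
    return out


def exact_loglik(model: ERGMModel, theta: np.ndarray, g: Graph) -> float:
    """log P_theta(Y = g) with the normalizing constant summed exhaustively."""
    theta = np.asarray(theta, dtype=float)
    stats = enumerate_graph_statistics(model, g.n_nodes, g.node_labels)
    log_psi = logsumexp(stats @ theta)
    return float(model.statistics(g) @ theta - log_psi)


def exact_expected_statistics(model: ERGMModel, theta: np.ndarray, n_nodes: int) -> np.ndarray:
    """E_theta[s(Y)] by enumeration (toy scale)."""
    stats = enumerate_graph_statistics(model, n_nodes)
    w = np.asarray(stats @ np.asarray(theta, float), dtype=float)
    w = np.exp(w - logsumexp(w))
    return w @ stats


# -- MPLE ----------------------------------------------------------------


def _design_matrix(model: ERGMModel, g: Graph) -> tuple[np.ndarray, np.ndarray]:
    rows, y = [], []
    for i, j in g.dyads():
        rows.append(model.change_vector(g, Dyad(i, j)))
        y.append(1.0 if g.has_edge(i, j) else 0.0)
    return np.asarray(rows), np.asarray(y)


def _logistic_newton(X, y, threshold, max_iter=60, tol=1e-12):
    """Unpenalized logistic MLE with separation detection.

    Returns (theta, loglik, converged, directions).  Coordinates whose
    estimates run past ``threshold`` on the log-odds scale are flagged with
    their sign; identically-zero columns are left at 0 with direction set by
    the caller.
    """
    n, p = X.shape
    theta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ theta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:  # pragma: no cover
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        theta = theta + step
        if np.linalg.norm(step) < tol * (1 + np.linalg.norm(theta)):
            converged = True
            break
        if np.max(np.abs(theta)) > 3 * threshold:
            break
    mu = expit(X @ theta)
    loglik = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1))) + np.sum(
        (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))
    ))
    directions = np.zeros(p, dtype=np.int8)
    over = np.abs(theta) > threshold
    directions[over] = np.sign(theta[over]).astype(np.int8)
    return theta, loglik, converged and not over.any(), directions


def mple(model: ERGMModel, g: Graph, options: FitOptions = FitOptions()) -> FitResult:
    """Maximum pseudo-likelihood fit (exact MLE for dyad-independent models)."""
    X, y = _design_matrix(model, g)
    p = X.shape[1]
    zero_cols = ~np.any(X != 0, axis=0)
    theta = np.zeros(p)
    directions = np.zeros(p, dtype=np.int8)
    keep = ~zero_cols
    if keep.any():
        th, ll, conv, dirs = _logistic_newton(X[:, keep], y, options.divergence_threshold)
        theta[keep] = th
        directions[keep] = dirs
    else:
        ll, conv = float(len(y)) * np.log(0.5), True
    if zero_cols.any():
        obs = model.statistics(g)
        empty_stats = model.statistics(Graph(g.n_nodes, set(), list(g.node_labels)))
        for idx in np.nonzero(zero_cols)[0]:
            directions[idx] = -1 if obs[idx] <= empty_stats[idx] else 1
    divergent = bool(np.any(directions != 0))
    loglik = float("nan") if divergent else ll
    aic = float("nan") if divergent else -2.0 * ll + 2.0 * p
    return FitResult(
        model=model,
        theta=theta,
        loglik=loglik,
        aic=aic,
        converged=conv and not divergent,
        directions=directions,
        diagnostics={"method": "mple", "n_dyads": len(y), "exact": model.is_dyad_independent},
    )


# -- contrastive divergence ----------------------------------------------


def cd_initialize(
    model: ERGMModel,
    g: Graph,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
) -> np.ndarray:
    """Contrastive-divergence starting values.

    Robbins-Monro ascent theta += a/(t+b) * (s(y_obs) - s(y_CD)), where y_CD
    comes from a short chain (``cd_chain_factor * C(n,2)`` toggles) restarted
    at the observed graph.  Falls back to the finite part of the MPLE if the
    trajectory leaves the divergence box.
    """
    base = mple(model, g, options)
    # MPLE quasi-separation can overshoot badly on small graphs even when the
    # MLE exists; start Robbins-Monro from a clipped, safe box.
    theta = np.clip(base.theta, -3.0, 3.0)
    if certified_divergence(model, g).any():
        return theta
    obs = model.statistics(g).astype(float)
    chain = _Chain(model, theta, g, derive_seed(cfg.seed, "cd"))
    k = options.cd_chain_factor * max(g.n_dyads, 1)
    A0 = chain.A.copy()
    deg0 = chain.deg.copy()
    stats0 = chain.stats.copy()
    scale = np.maximum(np.abs(obs), 1.0)
    for t in range(options.cd_iters):
        chain.A[:] = A0
        chain.deg[:] = deg0
        chain.stats[:] = stats0
        chain.set_theta(theta)
        chain.advance(k)
        theta = theta + options.cd_a / (t + options.cd_b) * (obs - chain.stats) / scale
        bound = options.divergence_threshold
        if np.any(np.abs(theta) > bound):
            logger.warning("CD trajectory left the divergence box; reverting to clipped MPLE")
            return np.clip(base.theta, -3.0, 3.0)
    return theta


# -- MCMC MLE ------------------------------------------------------------


def _boundary_directions(model, g, mean_stats, se_stats, obs) -> np.ndarray:
    """Flag coordinates whose simulated statistic collapsed to a constant
    while the observed value sits elsewhere (degenerate boundary)."""
    dirs = np.zeros(len(obs), dtype=np.int8)
    const = se_stats < 1e-12
    off = np.abs(mean_stats - obs) > 1e-8
    for idx in np.nonzero(const & off)[0]:
        dirs[idx] = -1 if obs[idx] < mean_stats[idx] else 1
    return dirs


def fit_mcmcmle(
    model: ERGMModel,
    g: Graph,
    init: Optional[np.ndarray] = None,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """MCMC maximum likelihood with a path-sampled log-likelihood / AIC.

    Dyad-independent models have an exact likelihood (the dyads are
    independent Bernoulli given the change statistics), so unless
    ``options.force_mcmc`` is set they are fitted exactly via the
    pseudo-likelihood route, which coincides with the MLE there.
    """
    n = g.n_nodes
    dim = model.dimension(n)
    obs = model.statistics(g).astype(float)
    cert = certified_divergence(model, g)
    pre = mple(model, g, options)
    if cert.any():
        return FitResult(
            model, pre.theta, float("nan"), float("nan"), False, cert,
            {"method": "mcmcmle", "stage": "boundary-certificate"},
        )
    if model.is_dyad_independent and not options.force_mcmc:
        if pre.divergent:
            return FitResult(
                model, pre.theta, float("nan"), float("nan"), False, pre.directions,
                {"method": "mcmcmle", "stage": "mple-separation"},
            )
        res = pre
        res.diagnostics["method"] = "exact-dyad-independent"
        return res

    theta = np.asarray(init, float).copy() if init is not None else cd_initialize(
        model, g, cfg, options
    )
    theta = np.clip(theta, -5.0, 5.0)
    rcfg = cfg.resolve(n)
    thr = options.divergence_threshold
    chain = _Chain(model, theta, g, derive_seed(cfg.seed, "mcmle"))
    converged = False
    it_used = 0
    for it in range(options.mcmle_max_iter):
        it_used = it + 1
        chain.set_theta(theta)
        chain.advance(rcfg.burn_in if it == 0 else rcfg.burn_in // 4)
        S = np.empty((rcfg.n_samples, dim))
        for s in range(rcfg.n_samples):
            chain.advance(rcfg.interval)
            S[s] = chain.stats
        mean_s = S.mean(axis=0)
        se_s = S.std(axis=0, ddof=1) / np.sqrt(rcfg.n_samples)
        bdirs = _boundary_directions(model, g, mean_s, S.std(axis=0, ddof=1), obs)
        if bdirs.any():
            return FitResult(
                model, theta, float("nan"), float("nan"), False, bdirs,
                {"method": "mcmcmle", "stage": "degenerate-boundary", "iterations": it_used},
            )
        # convergence: observed statistics within MC noise of simulated means
        tstat = np.max(np.abs(obs - mean_s) / np.maximum(se_s, 1e-12))
        if tstat < 1.0 and it > 0:
            converged = True
            break
        # importance-weighted Newton steps on l(theta') - l(theta)
        new = theta.copy()
        for _ in range(3):
            lw = S @ (new - theta)
            lw -= logsumexp(lw)
            w = np.exp(lw)
            mu = w @ S
            cov = (S - mu).T @ (w[:, None] * (S - mu))
            grad = obs - mu
            try:
                step = np.linalg.solve(cov + 1e-8 * np.eye(dim), grad)
            except np.linalg.LinAlgError:  # pragma: no cover
                step = grad / np.maximum(np.diag(cov), 1e-8)
            nstep = np.linalg.norm(step)
            if nstep > options.mcmle_step_bound:
                step *= options.mcmle_step_bound / nstep
            new = new + step
            if np.linalg.norm(new - theta) > 2 * options.mcmle_step_bound:
                break
        theta = new
        if np.any(np.abs(theta) > thr):
            dirs = np.zeros(dim, dtype=np.int8)
            over = np.abs(theta) > thr
            dirs[over] = np.sign(theta[over]).astype(np.int8)
            return FitResult(
                model, theta, float("nan"), float("nan"), False, dirs,
                {"method": "mcmcmle", "stage": "theta-threshold", "iterations": it_used},
            )

    loglik = float("nan")
    aic = float("nan")
    mc_se = float("nan")
    if options.compute_loglik:
        loglik, mc_se = _path_sampling_loglik(model, theta, g, cfg, options)
        aic = -2.0 * loglik + 2.0 * dim
    return FitResult(
        model,
        theta,
        loglik,
        aic,
        converged,
        np.zeros(dim, dtype=np.int8),
        {
            "method": "mcmcmle",
            "iterations": it_used,
            "loglik_mc_se": mc_se,
            "seed": cfg.seed,
        },
    )


def _path_sampling_loglik(model, theta, g, cfg, options) -> tuple[float, float]:
    """Thermodynamic integration from a Bernoulli reference to ``theta``.

    The reference is the edges-only model at the observed density embedded
    in the model's parameter space; its log normalizer is available in
    closed form, and d/dt log psi(theta_t) = u' E_t[S] is integrated along
    the linear path theta_t = ref + t u by the trapezoid rule.
    """
    n = g.n_nodes
    n_dyads = max(g.n_dyads, 1)
    dens = min(max(g.n_edges / n_dyads, 0.5 / n_dyads), 1 - 0.5 / n_dyads)
    theta0 = float(np.log(dens / (1 - dens)))
    ref = np.zeros_like(theta)
    ref[0] = theta0
    log_psi_ref = n_dyads * np.log1p(np.exp(theta0))
    u = theta - ref
    ts = np.linspace(0.0, 1.0, options.ti_points)
    chain = _Chain(model, ref, g, derive_seed(cfg.seed, "ti"))
    rcfg = cfg.resolve(n)
    derivs = np.empty(len(ts))
    vars_ = np.empty(len(ts))
    for idx, t in enumerate(ts):
        chain.set_theta(ref + t * u)
        chain.advance(rcfg.burn_in if idx == 0 else max(rcfg.burn_in // 4, rcfg.interval))
        vals = np.empty(options.ti_samples)
        for s in range(options.ti_samples):
            chain.advance(rcfg.interval)
            vals[s] = u @ chain.stats
        derivs[idx] = vals.mean()
        vars_[idx] = vals.var(ddof=1) / options.ti_samples
    log_psi = log_psi_ref + float(np.trapezoid(derivs, ts))
    # trapezoid-weight propagation of the per-point MC variances
    w = np.gradient(ts)
    mc_se = float(np.sqrt(np.sum((w**2) * vars_)))
    obs = model.statistics(g).astype(float)
    return float(theta @ obs - log_psi), mc_se


def fit(
    model: ERGMModel,
    g: Graph,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Dispatch on ``options.method`` ("mcmcmle" or "mple")."""
    if options.method == "mple":
        return mple(model, g, options)
    if options.method == "mcmcmle":
        return fit_mcmcmle(model, g, cfg=cfg, options=options)
    raise ValueError(f"unknown fit method {options.method!r}")
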