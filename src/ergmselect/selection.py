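"""Data-driven order bounds and stochastic forward selection.

Two stages:

1. **Bounding** — for each order-parameterized family (kstar, dsp, esp, nsp),
   univariate edge + family(l) models are fitted for l = 2, 3, ... until a
   run of consecutive fits with parameter estimates "at infinity"
   (divergent) is observed; the largest non-divergent order is the family's
   upper bound.  The bounds, together with the nine unbounded endogenous
   terms, define the initial candidate set S_M.

2. **Stochastic forward selection** — each candidate enters a univariate
   model whose AIC is estimated by MCMC, so the relative AIC change

       b = (AIC_null - AIC_term) / AIC_null

   is itself a random variable.  Each univariate model is refitted R times
   with distinct derived seeds; a term survives when the 10th percentile of
   its replicate b values is positive.  The replicate behaviour also sorts
   terms into three categories: consistent improvers, degenerate/harmful
   terms, and ambiguous terms resolved by the percentile's sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import ERGMModel, FitOptions, FitResult, MCMCConfig, derive_seed, fit
from .graphs import Graph
from .terms import BOUNDED_FAMILIES, UNBOUNDED_ENDOGENOUS, TermSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "AICChangeRecord",
    "SelectionResult",
    "bound_parameter_k",
    "build_candidate_set",
    "relative_aic_change",
    "stochastic_forward_select",
    "categorize",
]


@dataclass
class CandidateSet:
    """The candidate endogenous terms S_M plus the per-family order bounds."""

    terms: list[TermSpec]
    bounds: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.terms)

    def names(self) -> list[str]:
        return [t.name for t in self.terms]


@dataclass
class AICChangeRecord:
    """Replicate relative-AIC-change outcomes for one candidate term."""

    term: TermSpec
    aic0: float  # mean null AIC over the replicate streams
    b_values: np.ndarray  # finite replicate b's (divergent refits excluded)
    n_divergent: int
    n_replicates: int
    b_p10: float
    category: int
    kept: bool

    def to_record(self) -> dict:
        return {
            "term": self.term.name,
            "aic0": float(self.aic0) if np.isfinite(self.aic0) else None,
            "b_values": [float(v) for v in self.b_values],
            "n_divergent": int(self.n_divergent),
            "n_replicates": int(self.n_replicates),
            "b_p10": float(self.b_p10) if np.isfinite(self.b_p10) else None,
            "category": int(self.category),
            "kept": bool(self.kept),
        }


@dataclass
class SelectionResult:
    records: list[AICChangeRecord]
    surviving: CandidateSet
    seed: int
    config: dict = field(default_factory=dict)

    def summary_rows(self) -> list[dict]:
        return [r.to_record() | {"b_mean": float(np.mean(r.b_values)) if len(r.b_values) else None}
                for r in self.records]

    def replicate_histogram(self, term_name: str, bins: int = 10):
        """Histogram (counts, bin edges) of a term's replicate b values —
        the per-term refit-noise picture behind the percentile decision."""
        for rec in self.records:
            if rec.term.name == term_name:
                if len(rec.b_values) == 0:
                    return np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
                return np.histogram(rec.b_values, bins=bins)
        raise KeyError(f"no record for term {term_name!r}")


# -- data-driven order bounds --------------------------------------------


def bound_parameter_k(
    family: str,
    g: Graph,
    start_order: int = 2,
    run_length: int = 3,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
) -> int:
    """Largest order l with a non-divergent univariate edge + family(l) fit.

    Orders are scanned upward from ``start_order``; the scan stops at the
    first run of ``run_length`` consecutive divergent fits (or at the hard
    cap l = n - 1).  Returns 0 when no order fits.
    """
    if family not in BOUNDED_FAMILIES:
        raise ValueError(f"{family!r} is not an order-bounded family")
    if start_order < 1 or run_length < 1:
        raise ValueError("start_order and run_length must be >= 1")
    bound_options = FitOptions(
        **{**options.__dict__, "compute_loglik": False}
    )
    cap = max(g.n_nodes - 1, 0)
    best = 0
    run = 0
    l = start_order
    from .engine import certified_divergence

    while l <= cap:
        model = ERGMModel.from_endogenous([TermSpec(family, order_k=l)])
        if certified_divergence(model, g).any():
            divergent = True
        else:
            sub = MCMCConfig(
                cfg.burn_in, cfg.interval, cfg.n_samples, derive_seed(cfg.seed, family, l)
            )
            res = fit(model, g, cfg=sub, options=bound_options)
            divergent = res.divergent
        if divergent:
            run += 1
            if run >= run_length:
                return best
        else:
            best = l
            run = 0
        l += 1
    logger.warning("order scan for %s exhausted at the cap l = %d", family, cap)
    return best


def build_candidate_set(
    g: Graph,
    start_order: int = 2,
    run_length: int = 3,
    decay: float = 0.5,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
) -> CandidateSet:
    """Initial candidate set S_M: bounded families up to their data-driven
    bounds plus the nine unbounded endogenous terms (gw* at ``decay``)."""
    bounds: dict[str, int] = {}
    terms: list[TermSpec] = []
    for family in BOUNDED_FAMILIES:
        b = bound_parameter_k(family, g, start_order, run_length, cfg, options)
        bounds[family] = b
        for l in range(start_order, b + 1):
            terms.append(TermSpec(family, order_k=l))
    for kind in UNBOUNDED_ENDOGENOUS:
        if kind.startswith("gw"):
            terms.append(TermSpec(kind, decay=decay))
        else:
            terms.append(TermSpec(kind))
    return CandidateSet(terms=terms, bounds=bounds)


# -- stochastic forward selection ----------------------------------------


def relative_aic_change(aic0: float, aic_i: float) -> float:
    """Relative AIC change b = (AIC0 - AICi) / AIC0; positive = improvement."""
    if not (np.isfinite(aic0) and np.isfinite(aic_i)):
        raise ValueError("AIC values must be finite")
    if aic0 == 0:
        raise ValueError("null AIC must be nonzero")
    return (aic0 - aic_i) / aic0


def categorize(
    b_values, n_divergent: int | None = None, n_replicates: int | None = None,
    b_p10: float | None = None,
) -> int:
    """Three-way taxonomy of a candidate's replicate AIC behaviour.

    1 — every finite replicate improved the AIC (b > 0 throughout);
    2 — degenerate or harmful: divergent-majority refits, or a negative mean
        relative change together with a nonpositive 10th percentile;
    3 — ambiguous: mixed signs, resolved by the sign of the percentile.

    Accepts either an :class:`AICChangeRecord` or the raw pieces.
    """
    if isinstance(b_values, AICChangeRecord):
        rec = b_values
        b_values, n_divergent = rec.b_values, rec.n_divergent
        n_replicates, b_p10 = rec.n_replicates, rec.b_p10
    b = np.asarray(b_values, dtype=float)
    if n_divergent > n_replicates / 2 or len(b) == 0:
        return 2
    if np.all(b > 0):
        return 1
    if np.mean(b) < 0 and b_p10 <= 0:
        return 2
    return 3


def stochastic_forward_select(
    g: Graph,
    candidates: CandidateSet,
    n_replicates: int = 30,
    percentile: float = 10.0,
    cfg: MCMCConfig = MCMCConfig(),
    options: FitOptions = FitOptions(),
    attrs=None,
    fixed_null_aic: Optional[float] = None,
) -> SelectionResult:
    """Screen each candidate by the 10th percentile of its relative AIC change.

    For replicate r the null (edges-only) model and the univariate model are
    fitted with seeds derived from ``cfg.seed``, the term name and r, and
    b_r = (AIC0_r - AICi_r)/AIC0_r is recorded.  Divergent refits are
    excluded from the percentile but counted; a term is removed when more
    than half of its refits diverge or when the percentile is nonpositive.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    null_model = ERGMModel.from_endogenous([])
    null_aics = np.empty(n_replicates)
    for r in range(n_replicates):
        if fixed_null_aic is not None:
            null_aics[r] = fixed_null_aic
            continue
        sub = MCMCConfig(cfg.burn_in, cfg.interval, cfg.n_samples, derive_seed(cfg.seed, "null", r))
        res = fit(null_model, g, cfg=sub, options=options)
        if not np.isfinite(res.aic):
            raise RuntimeError("null model AIC is undefined (degenerate observed graph?)")
        null_aics[r] = res.aic

    records: list[AICChangeRecord] = []
    survivors: list[TermSpec] = []
    for term in candidates.terms:
        model = ERGMModel.from_endogenous([term], attrs=attrs)
        bs = []
        n_div = 0
        for r in range(n_replicates):
            sub = MCMCConfig(
                cfg.burn_in, cfg.interval, cfg.n_samples, derive_seed(cfg.seed, term.name, r)
            )
            res: FitResult = fit(model, g, cfg=sub, options=options)
            if res.divergent or not np.isfinite(res.aic):
                n_div += 1
                continue
            bs.append(relative_aic_change(null_aics[r], res.aic))
        b = np.asarray(bs, dtype=float)
        b_p10 = float(np.percentile(b, percentile)) if len(b) else float("-inf")
        category = categorize(b, n_div, n_replicates, b_p10)
        kept = b_p10 > 0 and n_div <= n_replicates / 2
        if n_div > n_replicates / 2:
            logger.info("term %s removed: %d/%d refits divergent", term.name, n_div, n_replicates)
        if kept:
            survivors.append(term)
        records.append(
            AICChangeRecord(
                term=term,
                aic0=float(np.mean(null_aics)),
                b_values=b,
                n_divergent=n_div,
                n_replicates=n_replicates,
                b_p10=b_p10,
                category=category,
                kept=kept,
            )
        )
    surviving = CandidateSet(terms=survivors, bounds=dict(candidates.bounds))
    config = {
        "n_replicates": n_replicates,
        "percentile": percentile,
        "method": options.method,
        "n_samples": cfg.n_samples,
    }
    return SelectionResult(records=records, surviving=surviving, seed=cfg.seed, config=config)
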