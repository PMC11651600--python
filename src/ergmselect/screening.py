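"""Degeneracy screening on simulated edge counts and motif-based ranking.

A fitted candidate model is screened by simulating networks from it and
comparing the mean simulated edge count H_M with the observed count H_O: the
model is discarded when |H_M - H_O| / H_O >= threshold (default 4, i.e. a
400% relative error — deliberately lenient, catching only models that have
collapsed toward the empty or complete graph).  Surviving models are then
ranked by how closely their mean edge, 2-star and triangle counts track the
observed motif counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .engine import ERGMModel, FitResult, MCMCConfig, simulate
from .graphs import Graph, MotifCounts, motif_summary
from .selection import CandidateSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "ModelRanking",
    "enumerate_model_space",
    "screen_degeneracy",
    "rank_models",
]


@dataclass
class ScreeningResult:
    model: ERGMModel
    h_obs: int
    h_sim: float
    rel_discrepancy: float
    discarded: bool
    reason: str  # "", "edge-count" or "divergent-fit"
    motif_means: Optional[dict]  # mean simulated edges / two_stars / triangles
    motif_se: Optional[dict]
    n_sims: int
    seed: int

    def to_record(self) -> dict:
        return {
            "terms": self.model.describe(),
            "h_obs": int(self.h_obs),
            "h_sim": None if self.h_sim is None or not np.isfinite(self.h_sim) else float(self.h_sim),
            "rel_discrepancy": None
            if self.rel_discrepancy is None or not np.isfinite(self.rel_discrepancy)
            else float(self.rel_discrepancy),
            "discarded": bool(self.discarded),
            "reason": self.reason,
            "motif_means": self.motif_means,
            "motif_se": self.motif_se,
            "n_sims": int(self.n_sims),
            "seed": int(self.seed),
        }


@dataclass
class ModelRanking:
    entries: list[tuple[ERGMModel, dict, float]]  # (model, motif_means, score)
    observed: MotifCounts

    def to_records(self) -> list[dict]:
        return [
            {"rank": r + 1, "terms": m.describe(), "motif_means": mm, "score": float(s)}
            for r, (m, mm, s) in enumerate(self.entries)
        ]


def enumerate_model_space(surviving: CandidateSet, attrs=None) -> list[ERGMModel]:
    """All models with one or two distinct surviving terms plus edges."""
    models = [ERGMModel.from_endogenous([t], attrs=attrs) for t in surviving.terms]
    for t, u in combinations(surviving.terms, 2):
        models.append(ERGMModel.from_endogenous([t, u], attrs=attrs))
    return models


def screen_degeneracy(
    model: ERGMModel,
    fit_result: FitResult,
    g_obs: Graph,
    n_sims: int = 100,
    threshold: float = 4.0,
    cfg: MCMCConfig = MCMCConfig(),
) -> ScreeningResult:
    """Simulate from the fitted model and screen on the mean edge count."""
    h_obs = g_obs.n_edges
    if h_obs <= 0:
        raise ValueError("degeneracy screening requires an observed edge count > 0")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if fit_result.divergent:
        return ScreeningResult(
            model, h_obs, float("nan"), float("nan"), True, "divergent-fit",
            None, None, 0, cfg.seed,
        )
    sim_cfg = MCMCConfig(cfg.burn_in, cfg.interval, n_sims, cfg.seed)
    _, graphs = simulate(model, fit_result.theta, g_obs, sim_cfg, return_graphs=True)
    motifs = np.array(
        [[m.edges, m.two_stars, m.triangles] for m in (motif_summary(gr) for gr in graphs)],
        dtype=float,
    )
    means = motifs.mean(axis=0)
    ses = motifs.std(axis=0, ddof=1) / np.sqrt(n_sims)
    h_sim = float(means[0])
    rel = abs(h_sim - h_obs) / h_obs
    discarded = rel >= threshold
    return ScreeningResult(
        model=model,
        h_obs=h_obs,
        h_sim=h_sim,
        rel_discrepancy=float(rel),
        discarded=discarded,
        reason="edge-count" if discarded else "",
        motif_means={"edges": means[0], "two_stars": means[1], "triangles": means[2]},
        motif_se={"edges": ses[0], "two_stars": ses[1], "triangles": ses[2]},
        n_sims=n_sims,
        seed=cfg.seed,
    )


def rank_models(results: list[ScreeningResult], observed: MotifCounts) -> ModelRanking:
    """Rank non-discarded models by normalized L1 motif discrepancy.

    score = sum over {edges, 2-stars, triangles} of |mean - observed| /
    max(observed, 1); ties broken by fewer terms, then term names.
    """
    entries = []
    for res in results:
        if res.discarded or res.motif_means is None:
            continue
        score = sum(
            abs(res.motif_means[k] - getattr(observed, k)) / max(getattr(observed, k), 1)
            for k in ("edges", "two_stars", "triangles")
        )
        entries.append((res.model, res.motif_means, float(score)))
    if not entries:
        logger.warning("all candidate models were discarded; empty ranking")
    entries.sort(key=lambda e: (e[2], len(e[0].terms), tuple(e[0].describe())))
    return ModelRanking(entries=entries, observed=observed)
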