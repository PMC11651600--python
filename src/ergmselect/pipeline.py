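"""End-to-end orchestration: bounds -> selection -> model space -> screening.

All stochastic stages draw their seeds deterministically from one root seed,
so a pipeline report is reproducible from its configuration echo alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .engine import FitOptions, MCMCConfig, derive_seed, fit
from .graphs import Graph, motif_summary
from .screening import ModelRanking, ScreeningResult, enumerate_model_space, rank_models, screen_degeneracy
from .selection import build_candidate_set, stochastic_forward_select

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on; echoed into the report."""

    seed: int = 0
    # candidate-set construction
    start_order: int = 2
    run_length: int = 3
    decay: float = 0.5
    # selection
    n_replicates: int = 30
    percentile: float = 10.0
    # screening
    n_sims: int = 100
    screening_threshold: float = 4.0
    # engine
    fit: FitOptions = field(default_factory=FitOptions)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(
    g: Graph,
    config: PipelineConfig = PipelineConfig(),
    attrs=None,
    out_dir: Optional[str] = None,
) -> dict:
    """Run candidate bounding, stochastic forward selection, model-space
    enumeration, degeneracy screening and motif ranking; return the report.

    The report is JSON-serializable.  When ``out_dir`` is given, the report
    and a flat selection summary table are written there.
    """
    observed = motif_summary(g)
    report: dict = {
        "config": config.to_dict(),
        "network": {
            "n_nodes": g.n_nodes,
            "n_edges": g.n_edges,
            "motifs": observed.as_dict(),
            "motifs_ordered": motif_summary(g, convention="ordered").as_dict(),
        },
    }

    mcmc = lambda tag: MCMCConfig(  # noqa: E731
        config.mcmc.burn_in, config.mcmc.interval, config.mcmc.n_samples,
        derive_seed(config.seed, tag),
    )

    cands = build_candidate_set(
        g,
        start_order=config.start_order,
        run_length=config.run_length,
        decay=config.decay,
        cfg=mcmc("bounds"),
        options=config.fit,
    )
    report["bounds"] = dict(cands.bounds)
    report["candidates"] = cands.names()

    sel = stochastic_forward_select(
        g,
        cands,
        n_replicates=config.n_replicates,
        percentile=config.percentile,
        cfg=mcmc("selection"),
        options=config.fit,
        attrs=attrs,
    )
    report["selection"] = sel.summary_rows()
    report["surviving"] = sel.surviving.names()

    models = enumerate_model_space(sel.surviving, attrs=attrs)
    report["model_space_size"] = len(models)

    screening: list[ScreeningResult] = []
    for idx, model in enumerate(models):
        fcfg = MCMCConfig(
            config.mcmc.burn_in, config.mcmc.interval, config.mcmc.n_samples,
            derive_seed(config.seed, "screenfit", idx),
        )
        try:
            fres = fit(model, g, cfg=fcfg, options=config.fit)
        except Exception as exc:  # pragma: no cover - stage isolation
            logger.error("fit failed for %s: %s", model.describe(), exc)
            continue
        scfg = MCMCConfig(
            config.mcmc.burn_in, config.mcmc.interval, config.mcmc.n_samples,
            derive_seed(config.seed, "screensim", idx),
        )
        screening.append(
            screen_degeneracy(
                model, fres, g,
                n_sims=config.n_sims,
                threshold=config.screening_threshold,
                cfg=scfg,
            )
        )
    report["screening"] = [s.to_record() for s in screening]
    report["n_models_screened"] = len(screening)
    report["n_models_kept"] = sum(0 if s.discarded else 1 for s in screening)

    ranking: ModelRanking = rank_models(screening, observed)
    report["ranking"] = ranking.to_records()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        _write_selection_table(report, out / "selection.tsv")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_selection_table(report: dict, path: Path) -> None:
    cols = ["term", "b_p10", "b_mean", "category", "kept", "n_divergent", "n_replicates"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report["selection"]:
            fh.write("\t".join(str(row.get(c)) for c in cols) + "\n")
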