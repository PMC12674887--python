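"""End-to-end reproduce-on-synthetic pipeline and atomic output helpers."""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from dscore.association import compare_groups, signature_correlation
from dscore.enrichment import EnrichmentConfig
from dscore.genesets import GeneSet, load_core_panel
from dscore.gsea import gsea_preranked
from dscore.scoring import compute_dscore
from dscore.screening import ScreenConfig, build_plus_panel, run_screen
from dscore.simulate import SimulationConfig, simulate_cohort, simulate_starvation_experiment
from dscore.survival import km_analysis

logger = logging.getLogger(__name__)

__all__ = ["run_full_pipeline", "atomic_write_text", "atomic_write_json"]


def atomic_write_text(text: str, path: str | Path) -> None:
    """Write text via a temp file and atomic rename (no partial outputs)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(obj: Any, path: str | Path) -> None:
    atomic_write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", path)


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            report.setdefault("stages", {})[name] = "ok" if exc is None else f"error: {exc}"
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
            return False

    return _Ctx()


def run_full_pipeline(
    out_dir: str | Path,
    sim_cfg: SimulationConfig | None = None,
    enrich_cfg: EnrichmentConfig | None = None,
    screen_cfg: ScreenConfig | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """simulate -> score -> screen -> plus panel -> score+ -> GSEA -> associations -> survival.

    Writes every table plus a JSON report of the statistics and truth-table
    recovery metrics to ``out_dir``; returns the report dict. Stage failures
    propagate after being recorded in the report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    enrich_cfg = enrich_cfg or EnrichmentConfig()
    screen_cfg = screen_cfg or ScreenConfig()
    report: dict[str, Any] = {"seed": sim_cfg.seed, "stages": {}}

    with _stage(report, "simulate"):
        cohort = simulate_cohort(sim_cfg)
        cohort.write_dir(out / "sim")
        starv = simulate_starvation_experiment(sim_cfg)
    core = load_core_panel()

    with _stage(report, "dscore"):
        scores = compute_dscore(cohort.expr, core, enrich_cfg)
        scores.to_tsv(out / "scores_core.tsv")
        starv_scores = compute_dscore(starv, core, enrich_cfg)
        cond = starv.annotation("condition")
        starv_cmp = compare_groups(starv_scores.as_series(), cond)
        report["starvation"] = {
            "mean_dscore_starved": float(starv_scores.as_series()[cond == "starved"].mean()),
            "mean_dscore_control": float(starv_scores.as_series()[cond == "control"].mean()),
            "wilcoxon_p": starv_cmp.p_value,
        }

    with _stage(report, "screen"):
        records, calls = run_screen(cohort.expr, scores, screen_cfg, panel=core)
        records.to_csv(out / "screen_records.tsv", sep="\t", index=False)
        calls.to_csv(out / "screen_calls.tsv", sep="\t", index=False)
        truth = cohort.truth
        planted = set(truth.loc[truth.role.str.startswith("candidate"), "gene"])
        called = set(calls["gene"])
        background = set(truth.loc[truth.role == "background", "gene"])
        sensitivity = len(called & planted) / len(planted) if planted else float("nan")
        report["screen"] = {
            "n_calls": int(len(calls)),
            "sensitivity": sensitivity,
            "false_calls_on_background": int(len(called & background)),
        }

    with _stage(report, "plus_panel"):
        plus = build_plus_panel(core, calls)
        scores_plus = compute_dscore(cohort.expr, plus, enrich_cfg)
        scores_plus.to_tsv(out / "scores_plus.tsv")
        report["plus_panel"] = {
            "n_promoters": len(plus.promoters),
            "n_suppressors": len(plus.suppressors),
        }

    with _stage(report, "gsea_validation"):
        truth = cohort.truth
        prom_set = GeneSet(
            "called_promoters",
            tuple(calls.loc[calls.direction == "promoter", "gene"])
            or tuple(truth.loc[truth.role == "candidate_promoter", "gene"]),
        )
        supp_set = GeneSet(
            "called_suppressors",
            tuple(calls.loc[calls.direction == "suppressor", "gene"])
            or tuple(truth.loc[truth.role == "candidate_suppressor", "gene"]),
        )
        res_p = gsea_preranked(cohort.ranked, prom_set, n_permutations, seed=sim_cfg.seed)
        res_s = gsea_preranked(cohort.ranked, supp_set, n_permutations, seed=sim_cfg.seed)
        report["gsea"] = {
            "promoters": {"es": res_p.es, "nes": res_p.nes, "p": res_p.p_value},
            "suppressors": {"es": res_s.es, "nes": res_s.nes, "p": res_s.p_value},
        }

    with _stage(report, "associations"):
        cmap, order = signature_correlation(
            cohort.signatures, scores_plus, cohort.expr.annotation("cancer_type")
        )
        cmap.to_tsv(out / "signature_rho.tsv", out / "signature_padj.tsv")
        mstage = cohort.expr.annotation("mstage")
        met = compare_groups(scores_plus.as_series(), mstage)
        report["associations"] = {
            "signature_row_order": list(order),
            "mean_rho_RPS": float(cmap.rho.loc["RPS"].mean()),
            "mean_rho_HRD": float(cmap.rho.loc["HRD"].mean()),
            "metastasis_p": met.p_value,
            "mean_dscore_plus_M1_minus_M0": float(
                scores_plus.as_series()[mstage == "M1"].mean()
                - scores_plus.as_series()[mstage == "M0"].mean()
            ),
        }

    with _stage(report, "survival"):
        per_type = {}
        types = cohort.expr.annotation("cancer_type")
        for t in sorted(types.unique()):
            samples = list(types.index[types == t])
            sub_scores = scores_plus.subset(samples)
            try:
                fit = km_analysis(sub_scores, cohort.clinical.loc[samples])
                per_type[t] = {
                    "chi_square": fit.chi_square,
                    "p": fit.p_value,
                    "hr_high_vs_low": fit.hazard_ratio,
                }
            except (ValueError, RuntimeError) as exc:
                per_type[t] = {"error": str(exc)}
        report["survival_per_type"] = per_type

    atomic_write_json(report, out / "report.json")
    return report
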