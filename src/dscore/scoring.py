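"""Signed composite score: promoter-set enrichment minus suppressor-set enrichment.

When cohort-range normalization is on, the promoter and suppressor scores are
normalized over their pooled range (single enrichment run) so the difference
stays on one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from dscore.enrichment import EnrichmentConfig, EnrichmentError, ssgsea_scores
from dscore.expression import ExpressionMatrix
from dscore.genesets import GeneSet, RegulatorPanel

logger = logging.getLogger(__name__)

__all__ = ["ScoreTable", "compute_dscore", "stratify_two_markers", "StratifyResult"]


@dataclass
class ScoreTable:
    """Per-sample promoter/suppressor enrichment and their signed difference."""

    samples: tuple[str, ...]
    es_promoter: np.ndarray
    es_suppressor: np.ndarray
    dscore: np.ndarray
    panel_label: str = "core"

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.es_promoter = np.asarray(self.es_promoter, dtype=float)
        self.es_suppressor = np.asarray(self.es_suppressor, dtype=float)
        self.dscore = np.asarray(self.dscore, dtype=float)
        n = len(self.samples)
        for name, arr in (
            ("es_promoter", self.es_promoter),
            ("es_suppressor", self.es_suppressor),
            ("dscore", self.dscore),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per sample")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if not np.allclose(self.dscore, self.es_promoter - self.es_suppressor, atol=1e-12, rtol=0):
            raise ValueError("dscore must equal es_promoter - es_suppressor")

    def subset(self, samples: Sequence[str]) -> "ScoreTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in samples]
        return ScoreTable(
            samples=tuple(samples),
            es_promoter=self.es_promoter[idx],
            es_suppressor=self.es_suppressor[idx],
            dscore=self.dscore[idx],
            panel_label=self.panel_label,
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.dscore, index=list(self.samples), name="dscore")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.samples),
                "es_promoter": self.es_promoter,
                "es_suppressor": self.es_suppressor,
                "dscore": self.dscore,
                "panel_label": self.panel_label,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        label = str(df["panel_label"].iloc[0]) if len(df) else "core"
        return cls(
            samples=tuple(df["sample"]),
            es_promoter=df["es_promoter"].to_numpy(),
            es_suppressor=df["es_suppressor"].to_numpy(),
            dscore=df["dscore"].to_numpy(),
            panel_label=label,
        )


def compute_dscore(
    expr: ExpressionMatrix,
    panel: RegulatorPanel,
    cfg: EnrichmentConfig | None = None,
) -> ScoreTable:
    """Run the enrichment engine on the panel's two sets jointly and difference them.

    Normalization (if enabled) is applied over the pooled promoter+suppressor
    score range. Raises :class:`EnrichmentError` naming the failing set when
    either set does not survive the matrix overlap.
    """
    cfg = cfg or EnrichmentConfig()
    sets = [
        GeneSet("__promoters__", panel.promoters.genes),
        GeneSet("__suppressors__", panel.suppressors.genes),
    ]
    result = ssgsea_scores(expr, sets, cfg)
    for gs in sets:
        if gs.name in result.failed:
            side = "promoter" if gs.name == "__promoters__" else "suppressor"
            raise EnrichmentError(f"{side} set failed: {result.failed[gs.name]}")
    frame = result.to_frame()
    es_p = frame["__promoters__"].to_numpy()
    es_s = frame["__suppressors__"].to_numpy()
    return ScoreTable(
        samples=expr.samples,
        es_promoter=es_p,
        es_suppressor=es_s,
        dscore=es_p - es_s,
        panel_label=panel.label,
    )


class StratifyResult(NamedTuple):
    labels: pd.Series  # one of hi_hi, hi_lo, lo_hi, lo_lo per sample
    unreliable_strata: tuple[str, ...]  # strata with < 4 samples


def stratify_two_markers(
    expr: ExpressionMatrix,
    marker1: str,
    marker2_values: pd.Series | Sequence[float],
    group_by: str = "cancer_type",
) -> StratifyResult:
    """Four-way median split on two per-sample markers within each stratum.

    Within each ``group_by`` stratum, each marker is split at the stratum
    median; samples exactly at the median go to "low". Labels are
    ``hi_hi``/``hi_lo``/``lo_hi``/``lo_lo`` (marker1 first). Strata with
    fewer than 4 samples are labelled anyway but flagged unreliable.
    """
    if marker1 not in expr.gene_index():
        raise KeyError(f"marker gene {marker1!r} not in matrix")
    m1 = pd.Series(expr.values[expr.gene_index()[marker1]], index=list(expr.samples))
    m2 = pd.Series(np.asarray(marker2_values, dtype=float).ravel(), index=list(expr.samples)) \
        if not isinstance(marker2_values, pd.Series) else marker2_values.astype(float)
    missing = set(expr.samples) - set(m2.index)
    if missing:
        raise ValueError(f"marker2_values missing for {len(missing)} sample(s)")
    m2 = m2.loc[list(expr.samples)]
    strata = expr.annotation(group_by)

    labels = pd.Series(index=list(expr.samples), dtype=object, name="group")
    unreliable: list[str] = []
    for stratum, idx in strata.groupby(strata).groups.items():
        samples = list(idx)
        if len(samples) < 4:
            unreliable.append(str(stratum))
            logger.warning("stratum %r has %d < 4 samples: labels unreliable", stratum, len(samples))
        hi1 = m1.loc[samples] > m1.loc[samples].median()
        hi2 = m2.loc[samples] > m2.loc[samples].median()
        lab = np.char.add(
            np.char.add(np.where(hi1, "hi", "lo"), "_"), np.where(hi2, "hi", "lo")
        )
        labels.loc[samples] = lab
    return StratifyResult(labels=labels, unreliable_strata=tuple(unreliable))
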