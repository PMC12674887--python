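"""Pan-cancer correlation screen for candidate score regulators.

Per cancer type, every gene's expression is correlated with the composite
score across that type's samples; p-values are Benjamini-Hochberg adjusted
within each cancer type across genes. A gene recurrently passing the
threshold (|rho| beyond the cutoff with adjusted p below alpha) in at least
``min_recurrent_types`` types is called as a candidate promoter (positive
correlations) or suppressor (negative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dscore.expression import ExpressionMatrix
from dscore.genesets import GeneSet, RegulatorPanel, extend_panel
from dscore.scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CandidateCall",
    "ConstantInputError",
    "spearman_correlation",
    "adjust_pvalues",
    "run_screen",
    "build_plus_panel",
    "load_candidate_table",
]


class ConstantInputError(ValueError):
    """Correlation is undefined because an input vector is constant."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the recurrence-based correlation screen.

    Defaults encode the published screen: |rho| > 0.45, adjusted p < 0.05,
    recurrence in more than 10 (i.e. >= 11) cancer types, Spearman
    correlation, Benjamini-Hochberg adjustment within each cancer type.
    """

    rho_pos_threshold: float = 0.45
    rho_neg_threshold: float = -0.45
    alpha_adjusted: float = 0.05
    min_recurrent_types: int = 11
    correlation_method: str = "spearman"
    adjust_method: str = "benjamini_hochberg"

    def __post_init__(self) -> None:
        if not (self.rho_pos_threshold > 0 > self.rho_neg_threshold):
            raise ValueError("need rho_pos_threshold > 0 > rho_neg_threshold")
        if not (0 < self.alpha_adjusted < 1):
            raise ValueError("alpha_adjusted must be in (0, 1)")
        if self.min_recurrent_types < 1:
            raise ValueError("min_recurrent_types must be >= 1")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError("correlation_method must be 'spearman' or 'pearson'")
        if self.adjust_method != "benjamini_hochberg":
            raise ValueError("only benjamini_hochberg adjustment is shipped")


@dataclass(frozen=True)
class CandidateCall:
    gene: str
    direction: str  # "promoter" | "suppressor"
    n_significant_types: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("promoter", "suppressor"):
            raise ValueError(f"direction must be promoter|suppressor, got {self.direction!r}")


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson on average ranks) with two-sided t-approximation p.

    Requires equal lengths >= 4 and at least two distinct values per vector.
    A perfect |rho| = 1 returns the smallest positive float as p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_pvalue(rho, x.size)


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0 - 1e-13:
        return float(np.finfo(float).tiny)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for a constant vector")
    rho = float(np.corrcoef(x, y)[0, 1])
    return rho, _t_pvalue(rho, x.size)


def adjust_pvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def _correlation_matrix(X: np.ndarray, y: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Correlate each row of X (genes x samples) with y. Constant rows -> NaN."""
    n = y.size
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Xc @ yc) / (sx * sy)
    rho[sx == 0] = np.nan
    if sy == 0:
        rho[:] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho)
    near_one = ok & (np.abs(rho) >= 1.0)
    p[near_one] = np.finfo(float).tiny
    mid = ok & ~near_one
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[mid] * np.sqrt((n - 2) / (1.0 - rho[mid] ** 2))
    p[mid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return rho, p


def run_screen(
    expr: ExpressionMatrix,
    scores: ScoreTable,
    cfg: ScreenConfig | None = None,
    panel: RegulatorPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every gene with the score per cancer type and call candidates.

    Returns ``(records, calls)``: records has one row per (gene, cancer_type)
    with finite rho (gene, cancer_type, rho, p_value, p_adjusted); calls has
    one row per candidate (gene, direction, n_significant_types).

    Genes of ``panel`` (when given) are barred from candidacy so the extended
    panel stays well-defined. Cancer types with fewer than 4 samples are
    skipped with a warning; a gene qualifying for both directions across types
    is excluded with a warning.
    """
    cfg = cfg or ScreenConfig()
    score = scores.as_series()
    missing = set(expr.samples) - set(score.index)
    if missing:
        raise ValueError(f"scores missing for {len(missing)} sample(s)")
    types = expr.annotation("cancer_type")

    records: list[pd.DataFrame] = []
    pos_counts: dict[str, int] = {}
    neg_counts: dict[str, int] = {}
    genes = np.asarray(expr.genes)
    sample_pos = {s: j for j, s in enumerate(expr.samples)}
    n_types_used = 0
    for cancer_type, idx in types.groupby(types).groups.items():
        samples = list(idx)
        if len(samples) < 4:
            warnings.warn(f"cancer type {cancer_type!r}: {len(samples)} < 4 samples, skipped")
            continue
        n_types_used += 1
        cols = [sample_pos[s] for s in samples]
        X = expr.values[:, cols]
        y = score.loc[samples].to_numpy()
        if np.all(y == y[0]):
            warnings.warn(f"cancer type {cancer_type!r}: constant score, skipped")
            continue
        rho, p = _correlation_matrix(X, y, cfg.correlation_method)
        ok = np.isfinite(rho)
        p_adj = np.full(rho.shape, np.nan)
        p_adj[ok] = adjust_pvalues(p[ok])
        records.append(
            pd.DataFrame(
                {
                    "gene": genes[ok],
                    "cancer_type": cancer_type,
                    "rho": rho[ok],
                    "p_value": p[ok],
                    "p_adjusted": p_adj[ok],
                }
            )
        )
        sig = ok & (p_adj < cfg.alpha_adjusted)
        for g in genes[sig & (rho > cfg.rho_pos_threshold)]:
            pos_counts[g] = pos_counts.get(g, 0) + 1
        for g in genes[sig & (rho < cfg.rho_neg_threshold)]:
            neg_counts[g] = neg_counts.get(g, 0) + 1

    if n_types_used == 0:
        raise ValueError("no cancer type with >= 4 samples")
    records_df = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["gene", "cancer_type", "rho", "p_value", "p_adjusted"])
    )

    barred = set(panel.genes) if panel is not None else set()
    promoters = {g for g, k in pos_counts.items() if k >= cfg.min_recurrent_types} - barred
    suppressors = {g for g, k in neg_counts.items() if k >= cfg.min_recurrent_types} - barred
    both = promoters & suppressors
    if both:
        warnings.warn(f"{len(both)} gene(s) qualified for both directions; excluded: {sorted(both)[:5]}")
        promoters -= both
        suppressors -= both
    calls_df = pd.DataFrame(
        [(g, "promoter", pos_counts[g]) for g in sorted(promoters)]
        + [(g, "suppressor", neg_counts[g]) for g in sorted(suppressors)],
        columns=["gene", "direction", "n_significant_types"],
    )
    return records_df, calls_df


def build_plus_panel(
    core: RegulatorPanel, calls: pd.DataFrame | Sequence[CandidateCall]
) -> RegulatorPanel:
    """Union candidate calls into the core panel, labelled "plus"."""
    if isinstance(calls, pd.DataFrame):
        items = [CandidateCall(row.gene, row.direction) for row in calls.itertuples()]
    else:
        items = list(calls)
    promoters = [c.gene for c in items if c.direction == "promoter"]
    suppressors = [c.gene for c in items if c.direction == "suppressor"]
    return extend_panel(core, promoters, suppressors, label="plus")


def load_candidate_table(path: str | Path | None = None) -> list[CandidateCall]:
    """Load a candidate-call table (TSV: gene, direction[, n_significant_types]).

    With no path, loads the bundled table mirroring the published candidate
    list's row counts (475 promoters, 31 suppressors); see the data file
    header for its provenance caveats.
    """
    if path is None:
        ref = resources.files("dscore").joinpath("data/candidate_regulators.tsv")
        with resources.as_file(ref) as p:
            return load_candidate_table(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns or "direction" not in df.columns:
        raise ValueError(f"{path}: expected columns 'gene' and 'direction'")
    has_n = "n_significant_types" in df.columns
    return [
        CandidateCall(
            str(row.gene),
            str(row.direction),
            int(row.n_significant_types) if has_n else None,
        )
        for row in df.itertuples()
    ]
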