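"""Associations of the composite score with pathway activity, genomic-aberration
signatures, the PCA-based EMT score, and two-group contrasts."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from dscore.enrichment import EnrichmentConfig, ssgsea_scores
from dscore.expression import ExpressionMatrix
from dscore.genesets import GeneSet
from dscore.scoring import ScoreTable
from dscore.screening import adjust_pvalues, spearman_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMap",
    "EmtResult",
    "ComparisonResult",
    "hallmark_correlation",
    "signature_correlation",
    "emt_score",
    "compare_groups",
]


@dataclass
class CorrelationMap:
    """Rows (pathways/signatures) x columns (cancer types) of rho and adjusted p."""

    rho: pd.DataFrame
    p_adjusted: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rho.shape != self.p_adjusted.shape or not self.rho.index.equals(
            self.p_adjusted.index
        ) or not self.rho.columns.equals(self.p_adjusted.columns):
            raise ValueError("rho and p_adjusted must be congruent")
        if ((self.rho.isna()) != (self.p_adjusted.isna())).any().any():
            raise ValueError("rho and p_adjusted must share missingness")

    def to_tsv(self, rho_path: str | Path, p_path: str | Path) -> None:
        self.rho.to_csv(rho_path, sep="\t")
        self.p_adjusted.to_csv(p_path, sep="\t")


@dataclass
class EmtResult:
    samples: tuple[str, ...]
    emt_score: np.ndarray
    explained_variance_fraction: float
    orientation_marker: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.emt_score, index=list(self.samples), name="emt_score")


class ComparisonResult(NamedTuple):
    statistic: float
    p_value: float
    direction: int  # sign of median(group a) - median(group b)


def _per_type_correlations(
    feature_frame: pd.DataFrame, score: pd.Series, types: pd.Series
) -> CorrelationMap:
    """Spearman of each feature column vs score per cancer type, BH within type."""
    feature_names = list(feature_frame.columns)
    type_labels = sorted(types.unique())
    rho = pd.DataFrame(np.nan, index=feature_names, columns=type_labels)
    padj = pd.DataFrame(np.nan, index=feature_names, columns=type_labels)
    for cancer_type in type_labels:
        samples = types.index[types == cancer_type]
        raw: dict[str, float] = {}
        for name in feature_names:
            pair = pd.concat(
                [feature_frame.loc[samples, name], score.loc[samples]], axis=1
            ).dropna()
            if len(pair) < 4:
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, p = spearman_correlation(x, y)
            rho.loc[name, cancer_type] = r
            raw[name] = p
        if raw:
            names = list(raw)
            padj.loc[names, cancer_type] = adjust_pvalues([raw[n] for n in names])
    return CorrelationMap(rho=rho, p_adjusted=padj)


def hallmark_correlation(
    expr: ExpressionMatrix,
    scores: ScoreTable,
    hallmark_sets: Iterable[GeneSet],
    cfg: EnrichmentConfig | None = None,
) -> CorrelationMap:
    """Correlate per-sample pathway enrichment with the score, per cancer type.

    Pathways failing the enrichment engine's overlap requirement appear as
    missing rows.
    """
    hallmark_sets = list(hallmark_sets)
    result = ssgsea_scores(expr, hallmark_sets, cfg)
    es = result.to_frame()
    for name, reason in result.failed.items():
        logger.warning("pathway %s not scored: %s", name, reason)
    score = scores.as_series().loc[list(expr.samples)]
    types = expr.annotation("cancer_type")
    cmap = _per_type_correlations(es, score, types)
    failed = [gs.name for gs in hallmark_sets if gs.name in result.failed]
    if failed:
        pad = pd.DataFrame(np.nan, index=failed, columns=cmap.rho.columns)
        cmap = CorrelationMap(
            rho=pd.concat([cmap.rho, pad]), p_adjusted=pd.concat([cmap.p_adjusted, pad.copy()])
        )
    return cmap


def _row_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation over pairwise-complete cells (1.0 if undefined)."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return 1.0
    x, y = a[ok], b[ok]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 1.0
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def signature_correlation(
    signatures: pd.DataFrame,
    scores: ScoreTable,
    group_by: pd.Series,
) -> tuple[CorrelationMap, list[str]]:
    """Correlate each genomic-aberration signature with the score per cancer type.

    ``signatures`` is samples x signature columns (missing allowed; pairwise
    complete observations are used, cells with < 4 pairs are missing).
    Returns the correlation map and the signature row order from
    average-linkage hierarchical clustering on (1 - correlation) distance
    between row vectors. Signatures missing everywhere are dropped with a
    warning.
    """
    score = scores.as_series()
    common = [s for s in signatures.index if s in score.index]
    signatures = signatures.loc[common]
    empty = [c for c in signatures.columns if signatures[c].notna().sum() == 0]
    if empty:
        warnings.warn(f"signature(s) with no data dropped: {empty}")
        signatures = signatures.drop(columns=empty)
    cmap = _per_type_correlations(signatures, score.loc[common], group_by.loc[common])

    rows = cmap.rho.to_numpy()
    n = rows.shape[0]
    if n <= 2:
        order = list(cmap.rho.index)
    else:
        condensed = np.array(
            [_row_distance(rows[i], rows[j]) for i in range(n) for j in range(i + 1, n)]
        )
        Z = linkage(condensed, method="average")
        order = [cmap.rho.index[i] for i in leaves_list(Z)]
    return cmap, order


def emt_score(
    expr: ExpressionMatrix,
    emt_genes: GeneSet,
    orientation_marker: str = "VIM",
    scale: bool = False,
) -> EmtResult:
    """First principal component of samples over an EMT gene list.

    Genes are centered across samples (optionally scaled to unit variance);
    the PC1 sign is flipped so the orientation marker's loading is positive.
    """
    gene_idx = expr.gene_index()
    present = [g for g in emt_genes.genes if g in gene_idx]
    if len(present) < 3:
        raise ValueError(f"need >= 3 EMT genes in the matrix, found {len(present)}")
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples")
    if orientation_marker not in present:
        raise ValueError(f"orientation marker {orientation_marker!r} not among present EMT genes")
    X = expr.values[[gene_idx[g] for g in present], :].T.astype(float)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance gene cannot be scaled")
        X = X / sd
    if np.allclose(X, 0):
        raise ValueError("zero-variance expression submatrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, 0] * s[0]
    loading = Vt[0, present.index(orientation_marker)]
    if loading < 0:
        coords = -coords
    evf = float(s[0] ** 2 / np.sum(s**2))
    return EmtResult(
        samples=expr.samples,
        emt_score=coords,
        explained_variance_fraction=evf,
        orientation_marker=orientation_marker,
    )


def compare_groups(
    values: Sequence[float] | pd.Series, labels: Sequence[str] | pd.Series
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum comparison of a two-level factor.

    Exact enumeration when both groups are small (min n <= 8) and untied;
    otherwise the normal approximation with continuity and tie correction.
    Direction is the sign of the difference of group medians (first level
    in sorted label order minus the second).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    levels = sorted(pd.unique(lab))
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    a = v[lab == levels[0]]
    b = v[lab == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    diff = np.median(a) - np.median(b)
    return ComparisonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), direction=int(np.sign(diff))
    )
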