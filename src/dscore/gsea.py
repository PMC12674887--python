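"""Preranked GSEA of a gene set against a ranked perturbation-score list.

The enrichment score is the maximum deviation of the weighted
Kolmogorov-Smirnov running statistic over the descending-sorted list (hit
increments proportional to |score|, weight exponent 1; miss decrements
1/(N - m)). The null distribution comes from gene-label permutations: when
the number of distinct hit subsets C(N, m) does not exceed the requested
permutation count the null is enumerated exhaustively (deterministic),
otherwise subsets are sampled under the stated seed.

NES = ES / mean(|null ES|) over same-sign null scores. The two-tailed p is
the +1-smoothed fraction of same-sign null scores at least as extreme,
doubled and capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from dscore.genesets import GeneSet

__all__ = ["RankedList", "GseaResult", "gsea_preranked", "enrichment_score"]


@dataclass
class RankedList:
    """Unique gene symbols with one finite score each, sorted descending."""

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list genes must be unique")
        if self.scores.shape != (len(self.genes),):
            raise ValueError("one score per gene required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        order = np.argsort(-self.scores, kind="stable")
        self.genes = tuple(np.asarray(self.genes)[order])
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene": list(self.genes), "normz": self.scores}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        gene_col, score_col = df.columns[:2]
        return cls(tuple(df[gene_col]), df[score_col].to_numpy(dtype=float))


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int
    n_overlap: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")
        if self.es != 0 and np.sign(self.nes) != np.sign(self.es):
            raise ValueError("NES must carry the sign of ES")


def enrichment_score(scores: np.ndarray, hit: np.ndarray) -> float:
    """Max-deviation weighted KS statistic for a hit mask over sorted scores."""
    n = scores.size
    m = int(hit.sum())
    w = np.abs(scores) * hit
    denom = w.sum()
    if denom == 0:
        # all hit scores are zero: fall back to unweighted hit steps
        p_hit = np.cumsum(hit) / m
    else:
        p_hit = np.cumsum(w) / denom
    p_miss = np.cumsum(~hit) / (n - m)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def _null_es(scores: np.ndarray, m: int, n_permutations: int, seed: int) -> np.ndarray:
    """Null ES from random (or exhaustive) m-subsets of the gene labels."""
    n = scores.size
    if comb(n, m) <= n_permutations:
        masks = np.zeros((comb(n, m), n), dtype=bool)
        for i, subset in enumerate(combinations(range(n), m)):
            masks[i, list(subset)] = True
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((n_permutations, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        masks = np.zeros((n_permutations, n), dtype=bool)
        np.put_along_axis(masks, idx, True, axis=1)
    absw = np.abs(scores)[None, :] * masks
    denom = absw.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    p_hit = np.cumsum(absw, axis=1)
    p_hit[~zero] /= denom[~zero]
    if zero.any():
        p_hit[zero] = np.cumsum(masks[zero], axis=1) / m
    p_miss = np.cumsum(~masks, axis=1) / (n - m)
    dev = p_hit - p_miss
    return dev[np.arange(dev.shape[0]), np.argmax(np.abs(dev), axis=1)]


def gsea_preranked(
    ranked: RankedList, gene_set: GeneSet, n_permutations: int = 1000, seed: int = 0
) -> GseaResult:
    """Score one gene set against the ranked list with a permutation null.

    Requires at least 2 overlapping genes and ``n_permutations >= 100``.
    Deterministic for a fixed seed.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    members = set(gene_set.genes)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    m = int(hit.sum())
    if m < 2:
        raise ValueError(f"set {gene_set.name!r}: only {m} gene(s) overlap the ranked list")
    if m == len(ranked):
        raise ValueError(f"set {gene_set.name!r} covers the whole ranked list")

    es = enrichment_score(ranked.scores, hit)
    null = _null_es(ranked.scores, m, n_permutations, seed)
    sign = np.sign(es) if es != 0 else 1.0
    same = null[np.sign(null) == sign]
    if same.size == 0:
        raise ValueError("no same-sign null scores: NES undefined")
    nes = float(es / np.mean(np.abs(same)))
    k = int(np.sum(np.abs(same) >= abs(es)))
    p = min(1.0, 2.0 * (k + 1) / (same.size + 1))
    return GseaResult(
        set_name=gene_set.name,
        es=es,
        nes=nes,
        p_value=p,
        n_permutations=int(null.size),
        seed=seed,
        n_overlap=m,
    )
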