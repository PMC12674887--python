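"""Gene-by-sample expression matrices with per-sample annotations, and TSV I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "read_annotation_tsv"]


@dataclass
class ExpressionMatrix:
    """Continuous (log-scale) expression values for genes x samples.

    Parameters
    ----------
    genes : sequence of str
        Unique gene symbols (rows).
    samples : sequence of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_genes, n_samples)
        Finite expression values.
    annotations : pandas.DataFrame, optional
        Per-sample annotations indexed by sample id (e.g. cancer_type,
        condition, mstage).
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.samples = tuple(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.annotations is not None:
            missing = set(self.samples) - set(self.annotations.index)
            if missing:
                raise ValueError(f"annotations missing for samples: {sorted(missing)[:5]}...")
            self.annotations = self.annotations.loc[list(self.samples)]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def annotation(self, key: str) -> pd.Series:
        if self.annotations is None or key not in self.annotations.columns:
            raise KeyError(f"annotation {key!r} not available")
        return self.annotations[key]

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.samples)}
        cols = [idx[s] for s in keep]
        ann = self.annotations.loc[keep] if self.annotations is not None else None
        return ExpressionMatrix(self.genes, tuple(keep), self.values[:, cols], ann)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, annotations: pd.DataFrame | None = None
    ) -> "ExpressionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float), annotations)


def read_expression_tsv(
    path: str | Path, annotations_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read an expression TSV (first column "gene", remaining columns samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ann = read_annotation_tsv(annotations_path) if annotations_path is not None else None
    return ExpressionMatrix.from_frame(df, ann)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-sample annotation TSV keyed by its first (sample id) column."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
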