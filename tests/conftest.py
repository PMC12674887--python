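import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dscore.expression import ExpressionMatrix
from dscore.genesets import GeneSet, RegulatorPanel


def make_expr(n_genes, n_samples, rng, annotations=None, prefix="G"):
    genes = tuple(f"{prefix}{i:03d}" for i in range(n_genes))
    samples = tuple(f"S{j:03d}" for j in range(n_samples))
    values = rng.normal(size=(n_genes, n_samples))
    return ExpressionMatrix(genes, samples, values, annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """10 genes x 4 samples."""
    return make_expr(10, 4, rng)


@pytest.fixture
def three_gene_set():
    return GeneSet("trio", ("G001", "G004", "G007"))


@pytest.fixture
def tiny_panel():
    return RegulatorPanel(
        promoters=GeneSet("promoters", ("G000", "G002", "G004")),
        suppressors=GeneSet("suppressors", ("G001", "G003", "G005")),
        label="tiny",
    )


@pytest.fixture
def annotated_expr(rng):
    """40 genes x 30 samples over 3 cancer types with mstage labels."""
    n_genes, n_samples = 40, 30
    genes = tuple(f"G{i:03d}" for i in range(n_genes))
    samples = tuple(f"S{j:03d}" for j in range(n_samples))
    ann = pd.DataFrame(
        {
            "cancer_type": np.repeat(["CTA", "CTB", "CTC"], 10),
            "condition": "baseline",
            "mstage": np.tile(["M0", "M0", "M0", "M0", "M1"], 6),
        },
        index=samples,
    )
    values = rng.normal(size=(n_genes, n_samples))
    return ExpressionMatrix(genes, samples, values, ann)
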