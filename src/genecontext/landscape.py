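"""Gene-cancer association landscape derived from the TF-IDF matrix.

Restricts the gene x term-feature matrix to cancer-category columns
(optionally aggregating MeSH cancer descriptors into display cancer-type
names), derives a per-gene relative literature frequency (normalized row
sums), and validates it against an external clinical frequency vector by
cosine similarity.  Year-sliced matrices are produced by filtering the
corpus by publication year upstream and re-running the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from genecontext.feature_matrix import GeneTermMatrix


@dataclass
class GeneCancerMatrix:
    """Genes x cancer types, TF-IDF scores."""

    genes: list[str]
    cancer_types: list[str]
    scores: np.ndarray  # dense genes x types

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.cancer_types)


def gene_cancer_matrix(
    matrix: GeneTermMatrix,
    cancer_map: Mapping[str, str] | None = None,
) -> GeneCancerMatrix:
    """Cancer-category column subset, optionally aggregated by display type.

    Descriptors mapped to the same display name are summed elementwise;
    unmapped cancer descriptors keep their own identifier as column name.
    """
    if matrix.scores is None:
        raise ValueError("matrix has no TF-IDF scores; run build_tfidf first")
    cancer_cols = [
        (j, fid) for j, (fid, cat) in enumerate(matrix.features) if cat == "cancer"
    ]
    if not cancer_cols:
        raise ValueError("matrix has no cancer-category features")
    cancer_map = dict(cancer_map or {})
    names = sorted({cancer_map.get(fid, fid) for _, fid in cancer_cols})
    name_idx = {n: i for i, n in enumerate(names)}
    dense = np.zeros((matrix.n_gene, len(names)))
    scores = sp.csc_matrix(matrix.scores)
    for j, fid in cancer_cols:
        dense[:, name_idx[cancer_map.get(fid, fid)]] += np.asarray(
            scores[:, j].todense()
        ).ravel()
    return GeneCancerMatrix(genes=list(matrix.genes), cancer_types=names, scores=dense)


def gene_frequency(gcm: GeneCancerMatrix) -> pd.Series:
    """Relative literature frequency: row sums normalized to total 1."""
    totals = gcm.scores.sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("all-zero gene-cancer matrix")
    return pd.Series(totals / grand, index=gcm.genes, name="frequency")


def cosine_similarity(u: pd.Series | Mapping[str, float], v: pd.Series | Mapping[str, float]) -> float:
    """Cosine of two non-negative gene-frequency vectors, union-aligned.

    Gene ids present in only one vector contribute zero in the other;
    symmetric and invariant to positive rescaling of either input.
    """
    u = pd.Series(u, dtype=float)
    v = pd.Series(v, dtype=float)
    ids = sorted(set(u.index) | set(v.index))
    a = u.reindex(ids, fill_value=0.0).to_numpy()
    b = v.reindex(ids, fill_value=0.0).to_numpy()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def read_frequency_tsv(path: str | Path) -> pd.Series:
    """External clinical frequency file: TSV of (gene_id, frequency)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "frequency"])
    return pd.Series(df["frequency"].to_numpy(), index=df["gene_id"], name="frequency")


def write_heatmap_tsv(gcm: GeneCancerMatrix, path: str | Path) -> None:
    """Long-format export (gene, cancer_type, score) for any plotting layer."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tcancer_type\tscore\n")
        for i, g in enumerate(gcm.genes):
            for j, c in enumerate(gcm.cancer_types):
                fh.write(f"{g}\t{c}\t{gcm.scores[i, j]:.10g}\n")
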