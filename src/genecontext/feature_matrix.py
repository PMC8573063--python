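"""Sparse gene x term-feature matrix with log-scaled TF-IDF weighting.

The association weight of gene *g* and term feature *t* is

    TF(g, t)  = ln(1 + tf_{g,t})          tf = co-occurrence count
    IDF(t)    = ln(1 + n_gene / df_t)     df = #genes with tf > 0
    score     = TF x IDF

Natural logarithms throughout; a fixed base change only rescales all
scores uniformly, so rankings are base-invariant.  Genes with fewer than a
minimum number of distinct features (default 10) are dropped, after which
df and n_gene are recomputed so the matrix stays self-consistent.

Rows and columns are ordered lexicographically by identifier, making
serialization (MatrixMarket + label sidecars) deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from genecontext.gene_windows import FeatureKey, GeneWindow


@dataclass
class GeneTermMatrix:
    """Counts and TF-IDF scores over genes (rows) x term features (columns)."""

    genes: list[str]
    features: list[FeatureKey]
    counts: sp.csr_matrix
    scores: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.features)):
            raise ValueError("counts shape does not match gene/feature labels")
        if (self.counts.data < 0).any():
            raise ValueError("negative co-occurrence count")

    @property
    def n_gene(self) -> int:
        return len(self.genes)

    @property
    def df(self) -> np.ndarray:
        """Per-feature number of genes with a nonzero count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_index(self, gene_id: str) -> int:
        return self.genes.index(gene_id)

    def subset(
        self,
        gene_idx: Sequence[int] | np.ndarray | None = None,
        feature_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GeneTermMatrix":
        gi = np.arange(self.n_gene) if gene_idx is None else np.asarray(gene_idx)
        fi = (
            np.arange(len(self.features))
            if feature_idx is None
            else np.asarray(feature_idx)
        )
        return GeneTermMatrix(
            genes=[self.genes[i] for i in gi],
            features=[self.features[j] for j in fi],
            counts=self.counts[gi][:, fi],
            scores=None if self.scores is None else self.scores[gi][:, fi],
        )


def count_cooccurrence(windows: Mapping[str, list[GeneWindow]]) -> GeneTermMatrix:
    """Aggregate window feature multisets into the count matrix.

    ``counts[g, t]`` is the total multiplicity of feature ``t`` over all
    windows of gene ``g``.  Rows/columns sorted by identifier.
    """
    if not windows:
        raise ValueError("no gene windows to count")
    genes = sorted(windows)
    feature_set: set[FeatureKey] = set()
    for ws in windows.values():
        for w in ws:
            feature_set.update(w.features)
    features = sorted(feature_set)
    fidx = {f: j for j, f in enumerate(features)}
    mat = sp.dok_matrix((len(genes), len(features)), dtype=np.int64)
    for i, g in enumerate(genes):
        for w in windows[g]:
            for f, n in w.features.items():
                mat[i, fidx[f]] += n
    return GeneTermMatrix(genes=genes, features=features, counts=mat.tocsr())


def tf_score(tf: float) -> float:
    """ln(1 + tf); zero iff the count is zero, strictly increasing."""
    if tf < 0:
        raise ValueError(f"negative term frequency {tf}")
    return math.log1p(tf)


def idf_score(n_gene: int, df: int) -> float:
    """ln(1 + n_gene/df); log 2 at df = n_gene, decreasing in df."""
    if df <= 0:
        raise ValueError("df must be >= 1 (feature absent from all genes)")
    if df > n_gene:
        raise ValueError(f"df={df} exceeds n_gene={n_gene}")
    return math.log1p(n_gene / df)


def build_tfidf(matrix: GeneTermMatrix) -> GeneTermMatrix:
    """Fill ``scores = TF x IDF`` cellwise, preserving the sparsity pattern."""
    counts = matrix.counts.tocoo()
    df = matrix.df
    tf_part = np.log1p(counts.data.astype(float))
    idf_part = np.log1p(matrix.n_gene / df[counts.col])
    scores = sp.csr_matrix(
        (tf_part * idf_part, (counts.row, counts.col)), shape=counts.shape
    )
    return replace(matrix, scores=scores)


def filter_min_features(matrix: GeneTermMatrix, k: int = 10) -> GeneTermMatrix:
    """Drop genes with fewer than ``k`` distinct features, then orphan columns.

    After row removal, features no longer present in any retained gene are
    dropped and df/n_gene implicitly recomputed.  Scores are invalidated
    (re-run :func:`build_tfidf` on the result).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    distinct = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    keep_rows = np.flatnonzero(distinct >= k)
    if keep_rows.size == 0:
        raise ValueError(f"min-feature filter k={k} removed every gene")
    sub = matrix.subset(gene_idx=keep_rows)
    keep_cols = np.flatnonzero(sub.df >= 1)
    out = sub.subset(feature_idx=keep_cols)
    out.scores = None
    return out


# serialization --------------------------------------------------------------

def save_matrix(matrix: GeneTermMatrix, out_dir: str | Path, stem: str = "matrix") -> None:
    """MatrixMarket counts/scores plus row/column label TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / f"{stem}.counts.mtx", sp.coo_matrix(matrix.counts))
    if matrix.scores is not None:
        scipy.io.mmwrite(out_dir / f"{stem}.scores.mtx", sp.coo_matrix(matrix.scores))
    (out_dir / f"{stem}.genes.tsv").write_text(
        "".join(f"{g}\n" for g in matrix.genes), encoding="utf-8"
    )
    (out_dir / f"{stem}.features.tsv").write_text(
        "".join(f"{fid}\t{cat}\n" for fid, cat in matrix.features), encoding="utf-8"
    )


def load_matrix(out_dir: str | Path, stem: str = "matrix") -> GeneTermMatrix:
    out_dir = Path(out_dir)
    counts = sp.csr_matrix(scipy.io.mmread(out_dir / f"{stem}.counts.mtx"))
    scores_path = out_dir / f"{stem}.scores.mtx"
    scores = sp.csr_matrix(scipy.io.mmread(scores_path)) if scores_path.exists() else None
    genes = (out_dir / f"{stem}.genes.tsv").read_text(encoding="utf-8").split()
    features = [
        (line.split("\t")[0], line.split("\t")[1])
        for line in (out_dir / f"{stem}.features.tsv")
        .read_text(encoding="utf-8")
        .splitlines()
        if line
    ]
    return GeneTermMatrix(genes=genes, features=features, counts=counts, scores=scores)
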