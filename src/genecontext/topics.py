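"""NMF topic modeling of the gene x term-feature matrix.

Factorizes the non-negative score matrix X (genes x features) as X ~ W H
with W >= 0 (gene-topic loadings) and H >= 0 (topic-feature loadings),
minimizing the squared Frobenius norm ||X - WH||_F^2 by multiplicative
updates, which are monotone: the per-iteration loss trace never increases.
Initialization is NNDSVDa (non-negative double SVD with zeros filled by
the matrix mean), which is deterministic; a seeded random init is
available behind ``init="random"``.

Each topic is summarized by its top genes (columns of W) and top features
(rows of H), descending by loading with ties broken by identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from genecontext.feature_matrix import GeneTermMatrix
from genecontext.gene_windows import FeatureKey

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TopicModel:
    k: int
    W: np.ndarray  # genes x k
    H: np.ndarray  # k x features
    loss_trace: list[float]
    seed: int | None
    n_iter: int
    genes: list[str]
    features: list[FeatureKey]

    @property
    def loss(self) -> float:
        return self.loss_trace[-1]


def _nndsvda(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic non-negative double-SVD initialization (mean-filled)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    m, n = X.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            u_, v_ = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            sigma = n_un * n_vn
            u_, v_ = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * u_
        H[j, :] = np.sqrt(S[j] * sigma) * v_
    # fill zeros on the factor scale (sqrt of the matrix mean) so the init,
    # like the updates, is equivariant under X -> cX with W,H -> sqrt(c) W,H
    fill = np.sqrt(max(X.mean(), _EPS) / k)
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def fit_nmf(
    X: GeneTermMatrix | np.ndarray | sp.spmatrix,
    k: int,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    init: str = "nndsvda",
    genes: list[str] | None = None,
    features: list[FeatureKey] | None = None,
) -> TopicModel:
    """Fit X ~ WH by multiplicative updates on the Frobenius objective.

    Stops when the relative loss change drops below ``tol`` or after
    ``max_iter`` iterations.  Deterministic given ``seed`` (which only
    matters for ``init="random"``).
    """
    if isinstance(X, GeneTermMatrix):
        genes = X.genes
        features = X.features
        mat = X.scores if X.scores is not None else X.counts
        A = np.asarray(mat.todense(), dtype=float)
    else:
        A = np.asarray(sp.csr_matrix(X).todense(), dtype=float) if sp.issparse(X) else np.asarray(X, dtype=float)
    if (A < 0).any():
        raise ValueError("NMF requires a non-negative matrix")
    m, n = A.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k={k} outside [1, min(n_genes={m}, n_features={n})]")
    genes = genes if genes is not None else [f"row{i}" for i in range(m)]
    features = features if features is not None else [(f"col{j}", "") for j in range(n)]

    if init == "nndsvda":
        W, H = _nndsvda(A, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(A.mean() / k)
        W = scale * rng.random((m, k))
        H = scale * rng.random((k, n))
    else:
        raise ValueError(f"unknown init {init!r}")

    def loss(W: np.ndarray, H: np.ndarray) -> float:
        return float(np.linalg.norm(A - W @ H, "fro") ** 2)

    trace = [loss(W, H)]
    n_iter = 0
    for it in range(1, max_iter + 1):
        # multiplicative updates (Lee & Seung) for the Frobenius objective
        H *= (W.T @ A) / np.maximum(W.T @ W @ H, _EPS)
        W *= (A @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        cur = loss(W, H)
        trace.append(cur)
        n_iter = it
        prev = trace[-2]
        if prev < 1e-15 or (prev - cur) / max(prev, _EPS) < tol:
            break
    return TopicModel(
        k=k, W=W, H=H, loss_trace=trace, seed=seed, n_iter=n_iter,
        genes=list(genes), features=list(features),
    )


def topic_summaries(
    model: TopicModel, n_top: int = 20
) -> list[dict[str, list[tuple[str, float]]]]:
    """Per-topic top genes (by W column) and top features (by H row).

    Descending by loading, ties broken by identifier; truncated with a
    warning when ``n_top`` exceeds a dimension.
    """
    if n_top > min(len(model.genes), len(model.features)):
        logger.warning(
            "n_top=%d exceeds matrix dimensions; summaries truncated", n_top
        )
    out = []
    for j in range(model.k):
        genes_ranked = sorted(
            zip(model.genes, model.W[:, j]), key=lambda t: (-t[1], t[0])
        )[:n_top]
        feats_ranked = sorted(
            zip(model.features, model.H[j, :]), key=lambda t: (-t[1], t[0])
        )[:n_top]
        out.append(
            {
                "genes": [(g, float(w)) for g, w in genes_ranked],
                "features": [(f, float(w)) for f, w in feats_ranked],
            }
        )
    return out
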