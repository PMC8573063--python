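"""Panel-characteristic term-feature selection by the hypergeometric test.

Background construction: the background set S' is the panel genes present
in the matrix (S) plus a fixed number of non-panel genes (default 500)
sampled without replacement from the matrix under a seed.  For each term
feature t, with

    N   = |S'|,   Ns = |S|,
    Nt  = #genes in S' containing t (count > 0),
    Nst = #panel genes containing t,

the number of panel genes containing t is hypergeometric, and the
upper-tail p-value

    p = sum_{y = Nst}^{min(Ns, Nt)} C(Nt, y) C(N - Nt, Ns - y) / C(N, Ns)

measures how concentrated the feature is in the panel.  Features with
p <= alpha are retained.  Probabilities are computed in log space
(log-gamma) to avoid under/overflow at corpus scale.

No multiple-testing correction is applied by default; an optional
Benjamini-Hochberg mode is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from genecontext.corpus_io import GenePanel
from genecontext.feature_matrix import GeneTermMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HypergeomInput:
    """Parameters (N, Ns, Nt, Nst) of one feature's enrichment test."""

    N: int
    Ns: int
    Nt: int
    Nst: int

    def __post_init__(self) -> None:
        if not (0 <= self.Ns <= self.N and 0 <= self.Nt <= self.N):
            raise ValueError(f"invalid hypergeometric parameters {self}")
        if not (0 <= self.Nst <= min(self.Ns, self.Nt)):
            raise ValueError(f"Nst={self.Nst} outside [0, min(Ns, Nt)] for {self}")

    @property
    def support(self) -> range:
        lo = max(0, self.Ns - (self.N - self.Nt))
        return range(lo, min(self.Ns, self.Nt) + 1)


def _log_binom(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(h: HypergeomInput, y: int) -> float:
    """Exact P(Y = y); zero outside the support."""
    if y not in h.support:
        return 0.0
    logp = (
        _log_binom(h.Nt, y)
        + _log_binom(h.N - h.Nt, h.Ns - y)
        - _log_binom(h.N, h.Ns)
    )
    return float(math.exp(logp))


def hypergeom_pvalue(h: HypergeomInput) -> float:
    """Upper-tail sum P(Y >= Nst), evaluated by log-sum-exp over the tail."""
    ys = [y for y in h.support if y >= h.Nst]
    if not ys:  # Nst below the entire support cannot happen; above -> empty
        return 0.0
    if ys[0] == h.support.start:
        return 1.0
    logs = [
        _log_binom(h.Nt, y)
        + _log_binom(h.N - h.Nt, h.Ns - y)
        - _log_binom(h.N, h.Ns)
        for y in ys
    ]
    return float(min(1.0, math.exp(logsumexp(logs))))


def build_background(
    matrix_genes: set[str] | list[str],
    panel: GenePanel,
    n_random: int = 500,
    seed: int = 0,
) -> set[str]:
    """S' = (panel ∩ matrix genes) ∪ seeded sample of non-panel matrix genes.

    Sampling is without replacement; when fewer than ``n_random`` non-panel
    genes exist, all of them are taken with a warning.
    """
    matrix_genes = set(matrix_genes)
    in_panel = matrix_genes & panel.genes
    if not in_panel:
        raise ValueError("panel has no genes in the matrix")
    pool = sorted(matrix_genes - panel.genes)
    if len(pool) <= n_random:
        if len(pool) < n_random:
            logger.warning(
                "only %d non-panel genes available (requested %d); taking all",
                len(pool), n_random,
            )
        sample = pool
    else:
        rng = np.random.default_rng(seed)
        sample = list(rng.choice(pool, size=n_random, replace=False))
    return in_panel | set(sample)


def select_features(
    matrix: GeneTermMatrix,
    panel: GenePanel,
    alpha: float = 0.05,
    n_random: int = 500,
    seed: int = 0,
    *,
    bh_correction: bool = False,
    keep_all_genes: bool = True,
) -> tuple[GeneTermMatrix, pd.DataFrame]:
    """Hypergeometric feature selection against the panel background.

    Presence (count > 0), not score magnitude, defines Nt and Nst.  Returns
    the matrix restricted to selected features (all genes kept by default)
    and the full per-feature table with columns ``feature_id, category, Nt,
    Nst, p_value, selected``.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    background = build_background(matrix.genes, panel, n_random=n_random, seed=seed)
    s_genes = set(matrix.genes) & panel.genes
    bg_rows = np.array([g in background for g in matrix.genes])
    panel_rows = np.array([g in s_genes for g in matrix.genes])

    presence = matrix.counts > 0
    Nt = np.asarray(presence[bg_rows].sum(axis=0)).ravel()
    Nst = np.asarray(presence[panel_rows].sum(axis=0)).ravel()
    N, Ns = int(bg_rows.sum()), int(panel_rows.sum())

    pvals = np.ones(len(matrix.features))
    for j in range(len(matrix.features)):
        if Nt[j] > 0:
            pvals[j] = hypergeom_pvalue(HypergeomInput(N, Ns, int(Nt[j]), int(Nst[j])))

    crit = pvals
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        crit = multipletests(pvals, method="fdr_bh")[1]
    selected = crit <= alpha

    table = pd.DataFrame(
        {
            "feature_id": [f for f, _ in matrix.features],
            "category": [c for _, c in matrix.features],
            "Nt": Nt,
            "Nst": Nst,
            "p_value": pvals,
            "selected": selected,
        }
    )
    keep_cols = np.flatnonzero(selected)
    if keep_all_genes:
        filtered = matrix.subset(feature_idx=keep_cols)
    else:
        filtered = matrix.subset(
            gene_idx=np.flatnonzero(bg_rows), feature_idx=keep_cols
        )
    return filtered, table


def category_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category feature proportions before vs after selection.

    The qualitative readout of enrichment: selection shifts mass toward the
    categories characteristic of the panel.
    """
    before = table["category"].value_counts(normalize=True)
    sel = table.loc[table["selected"], "category"]
    after = sel.value_counts(normalize=True) if len(sel) else before * float("nan")
    out = pd.DataFrame({"before": before, "after": after}).fillna(0.0)
    out.index.name = "category"
    return out.sort_index()
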