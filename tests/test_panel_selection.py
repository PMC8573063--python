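import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from genecontext.corpus_io import GenePanel
from genecontext.feature_matrix import GeneTermMatrix, build_tfidf
from genecontext.panel_selection import (
    HypergeomInput,
    build_background,
    category_proportions,
    hypergeom_pmf,
    hypergeom_pvalue,
    select_features,
)


def exact_pmf(N, Ns, Nt, y):
    """Independent oracle: exact rational arithmetic."""
    return Fraction(math.comb(Nt, y) * math.comb(N - Nt, Ns - y), math.comb(N, Ns))


def exact_pvalue(N, Ns, Nt, Nst):
    return float(sum(exact_pmf(N, Ns, Nt, y) for y in range(Nst, min(Ns, Nt) + 1)))


class TestHypergeomPmf:
    def test_panel_is_everything(self):
        assert hypergeom_pmf(HypergeomInput(10, 10, 4, 4), 4) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # C(4,2) C(6,1) / C(10,3) = 36/120
        assert hypergeom_pmf(HypergeomInput(10, 3, 4, 2), 2) == pytest.approx(
            0.3, abs=1e-14
        )

    def test_outside_support_is_zero(self):
        h = HypergeomInput(10, 3, 4, 0)
        assert hypergeom_pmf(h, 5) == 0.0
        assert hypergeom_pmf(h, -1) == 0.0

    def test_normalizes_over_support(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 40))
            Ns = int(rng.integers(0, N + 1))
            Nt = int(rng.integers(0, N + 1))
            h = HypergeomInput(N, Ns, Nt, max(0, Ns - (N - Nt)))
            total = sum(hypergeom_pmf(h, y) for y in h.support)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            HypergeomInput(10, 11, 4, 0)
        with pytest.raises(ValueError):
            HypergeomInput(10, 3, 4, 4)  # Nst > min(Ns, Nt)


class TestHypergeomPvalue:
    def test_whole_support_is_one(self):
        assert hypergeom_pvalue(HypergeomInput(10, 3, 4, 0)) == 1.0

    def test_enumeration_example(self):
        # P(2) + P(3) = 36/120 + 4/120
        assert hypergeom_pvalue(HypergeomInput(10, 3, 4, 2)) == pytest.approx(
            40 / 120, abs=1e-14
        )

    def test_grid_against_exact_enumeration(self):
        """Log-space tail equals rational enumeration on a dense small grid."""
        for N in range(1, 13):
            for Ns in range(0, N + 1):
                for Nt in range(0, N + 1):
                    for Nst in range(0, min(Ns, Nt) + 1):
                        got = hypergeom_pvalue(HypergeomInput(N, Ns, Nt, Nst))
                        assert got == pytest.approx(
                            exact_pvalue(N, Ns, Nt, Nst), abs=1e-12
                        )

    def test_agrees_with_scipy_sf(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            Ns = int(rng.integers(1, N + 1))
            Nt = int(rng.integers(1, N + 1))
            Nst = int(rng.integers(0, min(Ns, Nt) + 1))
            ours = hypergeom_pvalue(HypergeomInput(N, Ns, Nt, Nst))
            ref = float(scipy_hypergeom.sf(Nst - 1, N, Nt, Ns))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_monotone_in_nst(self):
        for N, Ns, Nt in [(20, 6, 9), (15, 15, 4), (30, 10, 25)]:
            ps = [
                hypergeom_pvalue(HypergeomInput(N, Ns, Nt, nst))
                for nst in range(0, min(Ns, Nt) + 1)
            ]
            assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBackground:
    def test_exhaustive_sample(self):
        genes = {f"G{i}" for i in range(600)}
        panel = GenePanel("p", frozenset(f"G{i}" for i in range(100)))
        assert len(build_background(genes, panel, n_random=500, seed=0)) == 600

    def test_deterministic_under_seed(self):
        genes = {f"G{i}" for i in range(900)}
        panel = GenePanel("p", frozenset(f"G{i}" for i in range(100)))
        a = build_background(genes, panel, n_random=500, seed=42)
        assert a == build_background(genes, panel, n_random=500, seed=42)
        assert a != build_background(genes, panel, n_random=500, seed=43)

    def test_no_overlap_with_matrix_errors(self):
        with pytest.raises(ValueError):
            build_background({"G1"}, GenePanel("p", frozenset({"X"})), seed=0)

    def test_sampling_frequencies_binomial(self):
        """Each pool gene is drawn with rate n_random/pool within 3 sigma."""
        pool_size, n_random, n_seeds = 60, 20, 600
        genes = {f"G{i}" for i in range(pool_size + 5)}
        panel = GenePanel("p", frozenset(f"G{i}" for i in range(pool_size, pool_size + 5)))
        counts = {g: 0 for g in genes - panel.genes}
        for seed in range(n_seeds):
            for g in build_background(genes, panel, n_random=n_random, seed=seed):
                if g not in panel.genes:
                    counts[g] += 1
        p = n_random / pool_size
        sigma = math.sqrt(p * (1 - p) / n_seeds)
        for g, c in counts.items():
            assert abs(c / n_seeds - p) < 3.3 * sigma


def planted_matrix():
    """30 genes, 10 in the panel; signal features present only in the panel."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:02d}" for i in range(30)]
    panel = GenePanel("p", frozenset(genes[:10]))
    features = [(f"SIG{j}", "cancer") for j in range(5)] + [
        (f"NOI{j}", "phenotype") for j in range(15)
    ]
    counts = np.zeros((30, 20), dtype=int)
    counts[:10, :5] = 1  # signal: all panel genes
    counts[:, 5:] = rng.integers(0, 2, size=(30, 15))  # noise everywhere
    counts[0, 5] = counts[0, 5] or 1
    return build_tfidf(
        GeneTermMatrix(genes=genes, features=features, counts=counts)
    ), panel


class TestSelectFeatures:
    def test_alpha_one_keeps_everything(self):
        m, panel = planted_matrix()
        filtered, table = select_features(m, panel, alpha=1.0, seed=0)
        assert len(filtered.features) == len(m.features)
        assert table["selected"].all()

    def test_signal_beats_noise(self):
        m, panel = planted_matrix()
        _, table = select_features(m, panel, alpha=0.05, seed=0)
        sig = table[table["feature_id"].str.startswith("SIG")]["p_value"]
        noi = table[table["feature_id"].str.startswith("NOI")]["p_value"]
        assert sig.max() < noi.min()
        assert table[table["feature_id"].str.startswith("SIG")]["selected"].all()

    def test_monotone_in_alpha(self):
        m, panel = planted_matrix()
        _, t1 = select_features(m, panel, alpha=0.01, seed=0)
        _, t2 = select_features(m, panel, alpha=0.2, seed=0)
        sel1 = set(t1.loc[t1["selected"], "feature_id"])
        sel2 = set(t2.loc[t2["selected"], "feature_id"])
        assert sel1 <= sel2

    def test_alpha_out_of_range(self):
        m, panel = planted_matrix()
        with pytest.raises(ValueError):
            select_features(m, panel, alpha=0.0)

    def test_presence_counts_reported(self):
        m, panel = planted_matrix()
        _, table = select_features(m, panel, alpha=0.05, seed=0)
        sig_rows = table[table["feature_id"].str.startswith("SIG")]
        assert (sig_rows["Nst"] == 10).all()
        assert (sig_rows["Nt"] == 10).all()

    def test_category_proportions_shift_toward_signal(self):
        m, panel = planted_matrix()
        _, table = select_features(m, panel, alpha=0.05, seed=0)
        props = category_proportions(table)
        assert props.loc["cancer", "after"] > props.loc["cancer", "before"]
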