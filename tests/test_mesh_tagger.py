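import numpy as np
import pytest

from genecontext.corpus_io import EntityAnnotation
from genecontext.mesh_tagger import (
    MeshIndexing,
    build_mapping_set,
    categorize_feature,
    descendants,
    tag_with_mesh,
)
from genecontext.synthetic import generate_corpus
from tests.conftest import make_abstract, make_thesaurus


def brute_force_descendants(thesaurus, did):
    """Independent oracle: direct prefix scan over all tree-number pairs."""
    roots = thesaurus[did].tree_numbers
    out = {did}
    for other, d in thesaurus.descriptors.items():
        for t in d.tree_numbers:
            if any(t.startswith(r + ".") for r in roots):
                out.add(other)
    return out


def random_toy_thesaurus(rng, n=30):
    """A random forest of dot-path tree numbers under two letter roots."""
    entries = []
    paths = ["C04", "G05"]
    for i in range(n):
        parent = paths[rng.integers(0, len(paths))]
        path = f"{parent}.{rng.integers(100, 999)}"
        paths.append(path)
        entries.append((f"D{i:04d}", f"term{i}", [path], []))
    entries.append(("DC04", "rootC", ["C04"], []))
    entries.append(("DG05", "rootG", ["G05"], []))
    return make_thesaurus(entries)


class TestDescendants:
    def test_leaf_is_singleton(self, toy_thesaurus):
        assert descendants(toy_thesaurus, "D008175") == {"D008175"}

    def test_three_level_chain(self, toy_thesaurus):
        """C04 -> C04.588 -> C04.588.894 closure has all three descriptors."""
        assert descendants(toy_thesaurus, "D009369") == {
            "D009369",
            "D009385",
            "D008175",
        }

    def test_unknown_id(self, toy_thesaurus):
        with pytest.raises(KeyError):
            descendants(toy_thesaurus, "D999999")

    def test_matches_brute_force_and_nests(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            thes = random_toy_thesaurus(rng)
            for did in thes.descriptors:
                assert descendants(thes, did) == brute_force_descendants(thes, did)
            # child closure contained in parent closure for every edge
            for child in thes.descriptors:
                for parent in thes.descriptors:
                    if any(
                        t.startswith(r + ".")
                        for t in thes[child].tree_numbers
                        for r in thes[parent].tree_numbers
                    ):
                        assert descendants(thes, child) <= descendants(thes, parent)


class TestMappingSet:
    def test_empty_indexing(self, toy_thesaurus):
        assert build_mapping_set(toy_thesaurus, MeshIndexing("1", frozenset())) == set()

    def test_disjoint_roots_union(self, toy_thesaurus):
        got = build_mapping_set(
            toy_thesaurus, MeshIndexing("1", frozenset({"D009369", "D030342"}))
        )
        assert got == descendants(toy_thesaurus, "D009369") | descendants(
            toy_thesaurus, "D030342"
        )

    def test_whole_tree_root(self, toy_thesaurus):
        got = build_mapping_set(
            toy_thesaurus, MeshIndexing("1", frozenset({"D009369"}))
        )
        assert got == {"D009369", "D009385", "D008175"}


class TestTagWithMesh:
    def test_entry_term_gets_descriptor_id(self, toy_thesaurus):
        """'Lung Cancer' in text resolves to the Lung Neoplasms descriptor."""
        doc = make_abstract("1", ["Patients had Lung Cancer in both lobes."])
        new = tag_with_mesh(
            doc, toy_thesaurus, MeshIndexing("1", frozenset({"D008175"}))
        )
        assert len(new) == 1
        assert new[0].concept_id == "D008175"
        assert new[0].etype == "MeSH"
        assert doc.text[new[0].start : new[0].end] == "Lung Cancer"

    def test_no_occurrence_no_annotation(self, toy_thesaurus):
        doc = make_abstract("1", ["Nothing relevant is mentioned here."])
        assert tag_with_mesh(
            doc, toy_thesaurus, MeshIndexing("1", frozenset({"D008175"}))
        ) == []

    def test_case_insensitive_and_hyphen_tolerant(self, toy_thesaurus):
        up = make_abstract("1", ["Severe LUNG CANCER was found."])
        lo = make_abstract("1", ["Severe lung-cancer was found."])
        for doc in (up, lo):
            new = tag_with_mesh(
                doc, toy_thesaurus, MeshIndexing("1", frozenset({"D008175"}))
            )
            assert [a.concept_id for a in new] == ["D008175"]

    def test_existing_annotation_not_double_tagged(self, toy_thesaurus):
        doc = make_abstract(
            "1",
            ["Patients had Lung Cancer in both lobes."],
            annotations=[(13, 24, "Disease", "D008175")],
        )
        assert (
            tag_with_mesh(doc, toy_thesaurus, MeshIndexing("1", frozenset({"D008175"})))
            == []
        )

    def test_longest_match_wins(self):
        thes = make_thesaurus(
            [
                ("D1", "small cell carcinoma", ["C04.100"], []),
                ("D2", "non small cell carcinoma", ["C04.200"], []),
                ("DR", "root", ["C04"], []),
            ]
        )
        doc = make_abstract("1", ["We found non small cell carcinoma here."])
        new = tag_with_mesh(doc, thes, MeshIndexing("1", frozenset({"DR"})))
        assert [a.concept_id for a in new] == ["D2"]

    def test_idempotent(self, toy_thesaurus):
        doc = make_abstract("1", ["Patients had Lung Cancer in both lobes."])
        idx = MeshIndexing("1", frozenset({"D008175"}))
        first = tag_with_mesh(doc, toy_thesaurus, idx)
        assert len(first) == 1
        assert tag_with_mesh(doc, toy_thesaurus, idx) == []

    def test_emitted_ids_stay_in_mapping_set(self):
        from genecontext.synthetic import SyntheticSpec

        corpus = generate_corpus(SyntheticSpec(seed=5, n_genes=15, n_panel=4))
        for doc in corpus.abstracts:
            idx = MeshIndexing(doc.doc_id, frozenset(corpus.indexing[doc.doc_id]))
            mapping = build_mapping_set(corpus.thesaurus, idx)
            new = tag_with_mesh(doc, corpus.thesaurus, idx)
            assert all(a.concept_id in mapping for a in new)

    def test_recall_on_planted_occurrences(self):
        """Every untagged planted mention is recovered with its descriptor."""
        from genecontext.synthetic import SyntheticSpec

        corpus = generate_corpus(SyntheticSpec(seed=3, n_genes=20, n_panel=5))
        found_missing = 0
        total = 0
        for doc in corpus.abstracts:
            idx = MeshIndexing(doc.doc_id, frozenset(corpus.indexing[doc.doc_id]))
            tag_with_mesh(doc, corpus.thesaurus, idx)
            got = {(a.concept_id) for a in doc.annotations}
            for fid, cat, _s, tagged, _m in corpus.manifest.docs[doc.doc_id][
                "mentions"
            ]:
                if not tagged:
                    total += 1
                    if fid not in got:
                        found_missing += 1
        assert total > 0
        assert found_missing == 0  # recall 1.0


class TestCategorize:
    def test_mutation(self):
        a = EntityAnnotation(0, 5, "V600E", "Mutation", "V600E")
        assert categorize_feature(a) == "mutation"

    def test_chemical_is_drug(self):
        a = EntityAnnotation(0, 9, "gefitinib", "Chemical", "CHEBI:49668")
        assert categorize_feature(a) == "drug"

    def test_neoplasms_branch_is_cancer(self, toy_thesaurus):
        a = EntityAnnotation(0, 11, "Lung Cancer", "MeSH", "D008175")
        assert categorize_feature(a, toy_thesaurus, neoplasms_root="C04") == "cancer"

    def test_genetic_phenomena_branch(self, toy_thesaurus):
        a = EntityAnnotation(0, 5, "Genes", "MeSH", "D005796")
        assert (
            categorize_feature(a, toy_thesaurus, genetic_phenomena_root="G05")
            == "genetic_phenomena"
        )

    def test_unknown_mesh_concept_warns_phenotype(self, toy_thesaurus, caplog):
        a = EntityAnnotation(0, 4, "mist", "MeSH", "D404404")
        with caplog.at_level("WARNING"):
            assert categorize_feature(a, toy_thesaurus) == "phenotype"
        assert any("D404404" in r.getMessage() for r in caplog.records)

    def test_species_defaults_phenotype(self):
        a = EntityAnnotation(0, 5, "human", "Species", "9606")
        assert categorize_feature(a) == "phenotype"
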