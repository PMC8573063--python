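import pytest

from genecontext.corpus_io import AnnotatedAbstract, EntityAnnotation
from genecontext.mesh_tagger import MeshDescriptor, MeshThesaurus
from genecontext.synthetic import SyntheticSpec, generate_corpus


def make_thesaurus(entries):
    """entries: iterable of (id, name, tree_numbers, extra_entry_terms)."""
    descriptors = {}
    for did, name, trees, extra in entries:
        descriptors[did] = MeshDescriptor(
            descriptor_id=did,
            name=name,
            tree_numbers=frozenset(trees),
            entry_terms=frozenset({name, *extra}),
        )
    return MeshThesaurus(descriptors=descriptors)


@pytest.fixture
def toy_thesaurus():
    """Three-level chain under C04 plus side branches, as in real MeSH."""
    return make_thesaurus(
        [
            ("D009369", "Neoplasms", ["C04"], ["Cancer", "Tumors"]),
            ("D009385", "Neoplasms by Site", ["C04.588"], []),
            ("D008175", "Lung Neoplasms", ["C04.588.894"], ["Lung Cancer"]),
            ("D005796", "Genes", ["G05.360"], []),
            ("D030342", "Genetic Phenomena", ["G05"], []),
            ("D010641", "Phenotype", ["G05.695"], []),
        ]
    )


def make_abstract(doc_id, sentences, annotations=(), year=None):
    """Build an abstract from explicit sentence strings; first is the title."""
    title = sentences[0]
    abstract = " ".join(sentences[1:])
    doc = AnnotatedAbstract(doc_id=doc_id, title=title, abstract=abstract, year=year)
    for start, end, etype, cid in annotations:
        doc.annotations.append(
            EntityAnnotation(start, end, doc.text[start:end], etype, cid)
        )
    doc.ensure_sentences()
    return doc


@pytest.fixture(scope="session")
def strong_corpus():
    """Default study conditions: panel genes enriched for signal features."""
    return generate_corpus(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def strong_spec():
    return SyntheticSpec(seed=7)
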