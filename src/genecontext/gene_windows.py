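"""Three-sentence gene context windows and their co-occurring features.

A gene window is the sentence containing a gene mention plus the previous
and the next sentence (clipped at document boundaries).  Everything else
annotated inside those sentences — diseases, chemicals, mutations, MeSH
concepts, and other genes — counts as a term feature of the focal gene,
with multiset semantics: a feature mentioned twice in one window
contributes count 2.  Windows of the same gene centered on the same
sentence are deduplicated; overlapping windows from adjacent center
sentences are both kept and counted independently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from genecontext.corpus_io import AnnotatedAbstract
from genecontext.mesh_tagger import MeshThesaurus, categorize_feature

#: Category assigned to other genes appearing inside a window.
GENE_FEATURE_CATEGORY = "phenotype"

FeatureKey = tuple[str, str]  # (concept_id, category)


@dataclass
class GeneWindow:
    doc_id: str
    gene_id: str
    first_sentence: int
    last_sentence: int  # inclusive
    features: Counter = field(default_factory=Counter)

    @property
    def n_sentences(self) -> int:
        return self.last_sentence - self.first_sentence + 1


def extract_gene_windows(
    abstract: AnnotatedAbstract,
    thesaurus: MeshThesaurus | None = None,
    *,
    neoplasms_root: str | None = None,
    genetic_phenomena_root: str | None = None,
) -> list[GeneWindow]:
    """One window per (gene id, center sentence) pair in the document.

    The focal gene's own annotations are excluded from the feature multiset;
    annotations of *other* genes are kept as features (category
    ``phenotype`` by default).  An abstract without gene annotations yields
    an empty list.
    """
    sentences = abstract.ensure_sentences()
    if not sentences:
        return []
    cat_kwargs = {}
    if neoplasms_root is not None:
        cat_kwargs["neoplasms_root"] = neoplasms_root
    if genetic_phenomena_root is not None:
        cat_kwargs["genetic_phenomena_root"] = genetic_phenomena_root

    centers = {
        (a.concept_id, abstract.sentence_of(a.start))
        for a in abstract.annotations
        if a.etype == "Gene"
    }
    windows: list[GeneWindow] = []
    for gene_id, center in sorted(centers):
        lo = max(0, center - 1)
        hi = min(len(sentences) - 1, center + 1)
        span_lo, span_hi = sentences[lo][0], sentences[hi][1]
        feats: Counter = Counter()
        for a in abstract.annotations:
            if a.start < span_hi and span_lo < a.end:
                if a.etype == "Gene":
                    if a.concept_id == gene_id:
                        continue
                    feats[(a.concept_id, GENE_FEATURE_CATEGORY)] += 1
                else:
                    cat = categorize_feature(a, thesaurus, **cat_kwargs)
                    feats[(a.concept_id, cat)] += 1
        windows.append(
            GeneWindow(
                doc_id=abstract.doc_id,
                gene_id=gene_id,
                first_sentence=lo,
                last_sentence=hi,
                features=feats,
            )
        )
    return windows


def collect_windows(
    abstracts: Iterable[AnnotatedAbstract],
    thesaurus: MeshThesaurus | None = None,
    **kwargs,
) -> dict[str, list[GeneWindow]]:
    """Group every window in the corpus by gene id, each window once."""
    out: dict[str, list[GeneWindow]] = {}
    for doc in abstracts:
        for w in extract_gene_windows(doc, thesaurus, **kwargs):
            out.setdefault(w.gene_id, []).append(w)
    return out


def write_windows_tsv(
    windows: Mapping[str, list[GeneWindow]], path: str | Path
) -> None:
    """Audit export: doc, gene, sentence span, feature, count per row."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tgene_id\tfirst_sentence\tlast_sentence\tfeature_id\tcategory\tcount\n")
        for gene_id in sorted(windows):
            for w in windows[gene_id]:
                for (fid, cat), n in sorted(w.features.items()):
                    fh.write(
                        f"{w.doc_id}\t{gene_id}\t{w.first_sentence}\t{w.last_sentence}"
                        f"\t{fid}\t{cat}\t{n}\n"
                    )
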