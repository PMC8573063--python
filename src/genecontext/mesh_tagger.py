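"""MeSH hierarchy tagging: descendant expansion and entry-term matching.

MeSH descriptors sit in a polyhierarchy encoded by dot-delimited tree
numbers ("C04.588.894" is below "C04.588" which is below "C04").  Articles
come with a small set of curator-assigned (indexed) descriptors.  The
tagging algorithm expands each indexed descriptor to the set of itself plus
all descendants (the mapping set) and then string-matches every entry term
(synonym) of every mapping-set descriptor against the article text, so that
concept mentions missed by the upstream NER still become features, keyed by
descriptor id so surface variants merge.

Matching is case-insensitive, whole-token, and hyphen/space tolerant
("non small cell" matches "Non-Small Cell").  Matches never cross a
sentence boundary.  Spans already covered by an existing annotation are not
double-tagged; among overlapping candidate matches the longest span wins,
ties broken by the lexicographically smallest descriptor id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from genecontext.corpus_io import AnnotatedAbstract, EntityAnnotation

logger = logging.getLogger(__name__)

#: Default tree-branch roots used to group features (real-MeSH defaults).
NEOPLASMS_ROOT = "C04"
GENETIC_PHENOMENA_ROOT = "G05"

CATEGORIES = ("cancer", "drug", "genetic_phenomena", "mutation", "phenotype")


@dataclass(frozen=True)
class MeshDescriptor:
    descriptor_id: str
    name: str
    tree_numbers: frozenset[str]
    entry_terms: frozenset[str]  # includes the preferred name


@dataclass
class MeshThesaurus:
    """Descriptor table: id -> (name, tree numbers, entry terms)."""

    descriptors: dict[str, MeshDescriptor]

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.descriptors

    def __len__(self) -> int:
        return len(self.descriptors)

    def __getitem__(self, descriptor_id: str) -> MeshDescriptor:
        return self.descriptors[descriptor_id]


@dataclass(frozen=True)
class MeshIndexing:
    """Curator-assigned descriptors of one article."""

    doc_id: str
    indexed_ids: frozenset[str]


def _is_strict_extension(tree: str, ancestor: str) -> bool:
    return tree != ancestor and tree.startswith(ancestor + ".")


def descendants(thesaurus: MeshThesaurus, descriptor_id: str) -> set[str]:
    """The descriptor itself plus every descriptor below it in the tree.

    A descriptor is a descendant when any of its tree numbers strictly
    extends (dot-prefix) any tree number of ``descriptor_id``.
    """
    if descriptor_id not in thesaurus:
        raise KeyError(f"unknown MeSH descriptor {descriptor_id!r}")
    roots = thesaurus[descriptor_id].tree_numbers
    out = {descriptor_id}
    for did, d in thesaurus.descriptors.items():
        if any(
            _is_strict_extension(t, r) for t in d.tree_numbers for r in roots
        ):
            out.add(did)
    return out


def build_mapping_set(thesaurus: MeshThesaurus, indexing: MeshIndexing) -> set[str]:
    """Union of descendant closures over all indexed descriptors."""
    out: set[str] = set()
    for did in indexing.indexed_ids:
        out |= descendants(thesaurus, did)
    return out


def _term_pattern(term: str) -> str:
    """Regex for a whole-token, hyphen/space-equivalent entry-term match."""
    tokens = [t for t in re.split(r"[\s\-]+", term.strip()) if t]
    body = r"[\s\-]+".join(re.escape(t) for t in tokens)
    return rf"(?<![\w]){body}(?![\w])"


def tag_with_mesh(
    abstract: AnnotatedAbstract,
    thesaurus: MeshThesaurus,
    indexing: MeshIndexing,
) -> list[EntityAnnotation]:
    """Emit MeSH annotations for entry-term occurrences of the mapping set.

    Returns the newly created annotations (they are also appended to
    ``abstract.annotations``).  Tagging is idempotent: occurrences whose
    span overlaps an existing annotation are skipped, so re-tagging adds
    nothing.
    """
    sentences = abstract.ensure_sentences()
    mapping_set = build_mapping_set(thesaurus, indexing)
    text = abstract.text

    candidates: list[tuple[int, int, str]] = []  # (start, end, descriptor_id)
    for did in sorted(mapping_set):
        for term in thesaurus[did].entry_terms:
            pat = re.compile(_term_pattern(term), re.IGNORECASE)
            for lo, hi in sentences:
                for m in pat.finditer(text, lo, hi):
                    candidates.append((m.start(), m.end(), did))

    # longest-match-wins among overlapping candidates, ties by smallest id
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    taken: list[tuple[int, int]] = [(a.start, a.end) for a in abstract.annotations]
    new: list[EntityAnnotation] = []
    for start, end, did in candidates:
        if any(start < t_end and t_start < end for t_start, t_end in taken):
            continue
        ann = EntityAnnotation(start, end, text[start:end], "MeSH", did)
        new.append(ann)
        taken.append((start, end))
    new.sort(key=lambda a: (a.start, a.end, a.concept_id))
    abstract.annotations.extend(new)
    abstract.annotations.sort(key=lambda a: (a.start, a.end, a.concept_id))
    return new


def categorize_feature(
    annotation: EntityAnnotation,
    thesaurus: MeshThesaurus | None = None,
    *,
    neoplasms_root: str = NEOPLASMS_ROOT,
    genetic_phenomena_root: str = GENETIC_PHENOMENA_ROOT,
) -> str:
    """Map an annotation to one of the five term-feature groups.

    Mutations -> ``mutation``; chemicals -> ``drug``; disease/MeSH concepts
    under the neoplasms branch -> ``cancer``; MeSH concepts under the
    genetic-phenomena branch -> ``genetic_phenomena``; everything else ->
    ``phenotype``.  Disease concepts that cannot be resolved in the
    thesaurus default to ``cancer`` (their ids are disease descriptors);
    unresolvable MeSH concepts fall back to ``phenotype`` with a warning.
    """
    if annotation.etype == "Mutation":
        return "mutation"
    if annotation.etype == "Chemical":
        return "drug"
    if annotation.etype in ("Disease", "MeSH"):
        desc = (
            thesaurus.descriptors.get(annotation.concept_id)
            if thesaurus is not None
            else None
        )
        if desc is None:
            if annotation.etype == "MeSH":
                logger.warning(
                    "MeSH annotation %r not in thesaurus; categorized as phenotype",
                    annotation.concept_id,
                )
                return "phenotype"
            return "cancer"
        in_branch = lambda root: any(
            t == root or t.startswith(root + ".") for t in desc.tree_numbers
        )
        if in_branch(neoplasms_root):
            return "cancer"
        if in_branch(genetic_phenomena_root):
            return "genetic_phenomena"
        return "phenotype"
    return "phenotype"
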