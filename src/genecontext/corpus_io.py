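"""Readers/writers for the exchange formats and sentence segmentation.

Formats handled here:

* **PubTator exchange dialect** — line-oriented annotated abstracts::

      <PMID>|t|<title>
      <PMID>|a|<abstract>
      <PMID>|y|<year>                 (optional dialect extension)
      <PMID>\\t<start>\\t<end>\\t<mention>\\t<type>\\t<concept id>
      ...
      <blank line between documents>

  Offsets are 0-based half-open character positions into the concatenation
  ``title + " " + abstract``.  The ``|y|`` year line is an extension of the
  common dialect (the base format carries no publication year).

* **MeSH thesaurus table** — TSV with columns ``descriptor_id``, ``name``,
  ``tree_numbers`` (pipe-separated), ``entry_terms`` (pipe-separated).

* **Gene panel list** — one gene identifier per line.

Sentence segmentation is rule-based and deterministic: boundaries at
``.!?`` followed by whitespace and an upper-case/digit start, guarded by a
fixed biomedical abbreviation stop-list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("Gene", "Disease", "Chemical", "Species", "Mutation", "MeSH")


class PubTatorFormatError(ValueError):
    """Unrecoverable malformation in a PubTator-dialect file."""


@dataclass(frozen=True)
class EntityAnnotation:
    """A normalized entity mention with half-open character offsets."""

    start: int
    end: int
    mention: str
    etype: str
    concept_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"annotation span [{self.start},{self.end}) is empty")

    def overlaps(self, other: "EntityAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedAbstract:
    """One document: title, abstract, optional year, annotations, sentences.

    ``text`` is the concatenation ``title + " " + abstract``; all offsets
    (annotation spans and sentence intervals) index into it.
    """

    doc_id: str
    title: str
    abstract: str
    year: int | None = None
    annotations: list[EntityAnnotation] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title

    @property
    def has_gene(self) -> bool:
        return any(a.etype == "Gene" for a in self.annotations)

    def ensure_sentences(self) -> list[tuple[int, int]]:
        if not self.sentences:
            self.sentences = split_sentences(self.text)
        return self.sentences

    def sentence_of(self, offset: int) -> int:
        """Index of the sentence interval containing character ``offset``."""
        for i, (lo, hi) in enumerate(self.ensure_sentences()):
            if lo <= offset < hi:
                return i
        # offsets that fall in inter-sentence whitespace attach to the
        # following sentence (or the last one at end of text)
        for i, (lo, _hi) in enumerate(self.sentences):
            if offset < lo:
                return i
        return len(self.sentences) - 1


@dataclass(frozen=True)
class GenePanel:
    """A named, curated set of gene identifiers (e.g. a clinical assay)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


# sentence splitting ---------------------------------------------------------

#: Tokens whose trailing period never ends a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "cf.", "vs.", "etc.", "ca.", "approx.",
        "fig.", "figs.", "eq.", "ref.", "refs.", "no.", "al.", "et al.",
        "dr.", "prof.", "st.", "inc.", "ltd.", "resp.",
    }
)

_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Segment ``text`` into sorted, non-overlapping half-open intervals.

    Every non-whitespace character belongs to exactly one interval.  A
    candidate boundary is sentence-final punctuation followed by whitespace
    and an upper-case letter or digit, unless the token carrying the
    punctuation is a known abbreviation (or a single letter, as in initials).
    Whitespace-only text yields an empty list.
    """
    intervals: list[tuple[int, int]] = []
    cuts = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # token holding the punctuation, e.g. "al." in "et al."
        tok_start = end
        while tok_start > 0 and not text[tok_start - 1].isspace():
            tok_start -= 1
        token = text[tok_start:end].lower()
        if token in ABBREVIATIONS:
            continue
        # require a sentence-looking start after the whitespace
        rest = text[end:].lstrip()
        if rest and not (rest[0].isupper() or rest[0].isdigit()):
            continue
        cuts.append(end)
    prev = 0
    for cut in cuts + [len(text)]:
        chunk = text[prev:cut]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            intervals.append((prev + lead, cut - trail))
        prev = cut
    return intervals


# PubTator dialect -----------------------------------------------------------

def read_pubtator(path: str | Path) -> list[AnnotatedAbstract]:
    """Parse a PubTator-dialect file into :class:`AnnotatedAbstract` objects.

    Documents with no gene annotation are retained (``has_gene`` is False).
    A mention that disagrees with the text slice at its offsets is kept with
    the mention recomputed from the text (offsets are trusted), logging a
    warning.  Malformed offsets raise :class:`PubTatorFormatError` with the
    line number.
    """
    path = Path(path)
    docs: list[AnnotatedAbstract] = []
    cur: AnnotatedAbstract | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            cur.ensure_sentences()
            docs.append(cur)
            cur = None

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            m = re.match(r"^([^\t|]+)\|([tay])\|(.*)$", line)
            if m:
                doc_id, kind, payload = m.groups()
                if kind == "t":
                    flush()
                    cur = AnnotatedAbstract(doc_id=doc_id, title=payload, abstract="")
                elif cur is None or cur.doc_id != doc_id:
                    raise PubTatorFormatError(
                        f"{path}:{lineno}: '|{kind}|' line for {doc_id} before its title"
                    )
                elif kind == "a":
                    cur.abstract = payload
                else:  # year extension
                    try:
                        cur.year = int(payload)
                    except ValueError as exc:
                        raise PubTatorFormatError(
                            f"{path}:{lineno}: non-integer year {payload!r}"
                        ) from exc
                continue
            parts = line.split("\t")
            if len(parts) < 6 or cur is None or parts[0] != cur.doc_id:
                raise PubTatorFormatError(f"{path}:{lineno}: unrecognized line {line!r}")
            _, s_start, s_end, mention, etype, concept_id = parts[:6]
            try:
                astart, aend = int(s_start), int(s_end)
            except ValueError as exc:
                raise PubTatorFormatError(
                    f"{path}:{lineno}: non-integer offsets {s_start!r},{s_end!r}"
                ) from exc
            text = cur.text
            if not (0 <= astart < aend <= len(text)):
                raise PubTatorFormatError(
                    f"{path}:{lineno}: span [{astart},{aend}) outside text of length {len(text)}"
                )
            actual = text[astart:aend]
            if actual != mention:
                logger.warning(
                    "%s:%d: mention %r != text slice %r; trusting offsets",
                    path, lineno, mention, actual,
                )
                mention = actual
            cur.annotations.append(
                EntityAnnotation(astart, aend, mention, etype, concept_id)
            )
    flush()
    return docs


def write_pubtator(abstracts: Iterable[AnnotatedAbstract], path: str | Path) -> None:
    """Serialize documents in the canonical PubTator dialect (with ``|y|``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in abstracts:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            if doc.year is not None:
                fh.write(f"{doc.doc_id}|y|{doc.year}\n")
            for a in sorted(doc.annotations, key=lambda a: (a.start, a.end, a.concept_id)):
                fh.write(
                    f"{doc.doc_id}\t{a.start}\t{a.end}\t{a.mention}\t{a.etype}\t{a.concept_id}\n"
                )
            fh.write("\n")


# year filtering -------------------------------------------------------------

class YearFilterResult(list):
    """List of kept abstracts, annotated with drop counts.

    ``n_no_year`` documents lacked a year; ``n_out_of_range`` had one outside
    the requested interval.  ``len(result) + n_no_year + n_out_of_range``
    equals the input size.
    """

    n_no_year: int = 0
    n_out_of_range: int = 0


def filter_by_year(
    abstracts: Sequence[AnnotatedAbstract], year_lo: int, year_hi: int
) -> YearFilterResult:
    """Keep abstracts whose year lies in ``[year_lo, year_hi]``.

    Abstracts without a year are dropped and counted in the result's
    ``n_no_year`` attribute.
    """
    if year_lo > year_hi:
        raise ValueError(f"inverted year range [{year_lo}, {year_hi}]")
    out = YearFilterResult()
    for doc in abstracts:
        if doc.year is None:
            out.n_no_year += 1
        elif year_lo <= doc.year <= year_hi:
            out.append(doc)
        else:
            out.n_out_of_range += 1
    return out


# panels and thesaurus tables ------------------------------------------------

def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a one-identifier-per-line panel file (duplicates collapse)."""
    path = Path(path)
    genes = {line.strip() for line in path.read_text(encoding="utf-8").splitlines()}
    genes.discard("")
    if not genes:
        raise ValueError(f"panel file {path} contains no gene identifiers")
    return GenePanel(name=name or path.stem, genes=frozenset(genes))


def write_panel(panel: GenePanel, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(panel.genes)), encoding="utf-8"
    )


def read_mesh_table(path: str | Path):
    """Read the thesaurus TSV into a :class:`~genecontext.mesh_tagger.MeshThesaurus`.

    Columns: descriptor_id, preferred name, pipe-separated tree numbers,
    pipe-separated entry terms.  Duplicate descriptor ids are an error.
    """
    from genecontext.mesh_tagger import MeshDescriptor, MeshThesaurus

    path = Path(path)
    descriptors: dict[str, MeshDescriptor] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 TSV columns, got {len(parts)}")
        did, name, trees, entries = parts
        if did in descriptors:
            raise ValueError(f"{path}:{lineno}: duplicate descriptor id {did!r}")
        entry_terms = {t for t in entries.split("|") if t}
        entry_terms.add(name)
        descriptors[did] = MeshDescriptor(
            descriptor_id=did,
            name=name,
            tree_numbers=frozenset(t for t in trees.split("|") if t),
            entry_terms=frozenset(entry_terms),
        )
    return MeshThesaurus(descriptors=descriptors)


def write_mesh_table(thesaurus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for did in sorted(thesaurus.descriptors):
            d = thesaurus.descriptors[did]
            trees = "|".join(sorted(d.tree_numbers))
            entries = "|".join(sorted(d.entry_terms - {d.name}))
            fh.write(f"{did}\t{d.name}\t{trees}\t{entries}\n")


def read_indexing(path: str | Path) -> dict[str, set[str]]:
    """Read the per-article MeSH indexing TSV: doc_id, pipe-separated ids."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        doc_id, _, ids = line.partition("\t")
        out[doc_id] = {i for i in ids.split("|") if i}
    return out


def write_indexing(indexing: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc_id in sorted(indexing):
            fh.write(f"{doc_id}\t{'|'.join(sorted(indexing[doc_id]))}\n")
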