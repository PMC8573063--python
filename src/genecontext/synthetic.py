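"""Self-contained synthetic corpora with planted co-occurrence structure.

The generator emits everything the pipeline consumes — a PubTator-dialect
corpus, a toy MeSH thesaurus, per-document MeSH indexing, and a gene panel
— plus a ground-truth manifest.  Documents are templated natural-language
sentences ("Study of GENE12 and cancerterm3 in patients.") so sentence
splitting, offset arithmetic, and entry-term matching are genuinely
exercised; the vocabulary is synthetic.

Planted structure: each document is about one focal gene and contains one
gene mention.  Term features are planted only inside the gene's
three-sentence window: a designated set of *signal* features co-occurs
with panel genes at rate ``p_signal`` per document and with all other
genes at the baseline ``p_background``; every other feature occurs at the
baseline everywhere.  Disease/chemical/mutation mentions carry PubTator
entity lines; MeSH-branch features (and a configurable fraction of
disease mentions) are emitted untagged but entry-term-matchable, so the
MeSH tagger must recover them.  An optional era switch suppresses chosen
features in documents published before a cutoff year, emulating
time-sliced corpus contrasts.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from genecontext import corpus_io
from genecontext.corpus_io import AnnotatedAbstract, EntityAnnotation, GenePanel
from genecontext.mesh_tagger import (
    MeshDescriptor,
    MeshIndexing,
    MeshThesaurus,
    tag_with_mesh,
)

CATEGORY_BRANCHES = {
    "cancer": "C04",
    "genetic_phenomena": "G05",
    "phenotype": "F01",
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_genes: int = 120
    n_panel: int = 30
    n_features_per_category: dict[str, int] = field(
        default_factory=lambda: {
            "cancer": 12,
            "drug": 8,
            "genetic_phenomena": 8,
            "mutation": 8,
            "phenotype": 8,
        }
    )
    n_signal_features: int = 8
    docs_per_gene: int = 3
    sentences_per_doc: int = 5
    p_signal: float = 0.5
    p_background: float = 0.1
    untagged_fraction: float = 0.25  # disease mentions left for the MeSH tagger
    year_lo: int = 2011
    year_hi: int = 2019
    era_split_year: int | None = None
    n_era_features: int = 0  # features emitted only from era_split_year on
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_background < self.p_signal <= 1):
            raise ValueError(
                f"need 0 <= p_background < p_signal <= 1, got "
                f"{self.p_background}, {self.p_signal}"
            )
        if self.n_signal_features > sum(self.n_features_per_category.values()):
            raise ValueError("more signal features than features")
        if min(self.n_genes, self.n_panel, self.docs_per_gene,
               self.sentences_per_doc) <= 0 or self.n_panel > self.n_genes:
            raise ValueError("invalid counts in synthetic spec")
        if self.n_era_features and self.era_split_year is None:
            raise ValueError("era features require era_split_year")


class NullSpec(SyntheticSpec):
    """A spec with no panel enrichment (p_signal treated equal to baseline).

    Bypasses the p_background < p_signal guard so null calibration of the
    selection test can be studied.
    """

    def __post_init__(self) -> None:  # relax only the rate ordering
        self.p_signal = self.p_background
        if not (0 <= self.p_background <= 1):
            raise ValueError("invalid p_background")


@dataclass(frozen=True)
class FeatureDef:
    feature_id: str
    category: str
    etype: str  # PubTator type used when tagged: Disease/Chemical/Mutation/MeSH
    mention: str  # surface form for tagged emissions (preferred term)
    synonym: str  # entry-term surface form for untagged emissions
    signal: bool
    era: bool


@dataclass
class TruthManifest:
    """Ground truth for every planted object in the corpus."""

    panel: list[str]
    genes: list[str]
    features: dict[str, dict]  # feature_id -> {category, signal, era}
    docs: dict[str, dict]  # doc_id -> {gene_id, year, n_sentences,
    #                         center_sentence, mentions: [(fid, cat, sent, tagged, mult)]}

    def expected_window_counts(self) -> dict[str, Counter]:
        """Per-gene multiset of planted (feature_id, category) co-occurrences."""
        out: dict[str, Counter] = {}
        for doc in self.docs.values():
            c = out.setdefault(doc["gene_id"], Counter())
            for fid, cat, _sent, _tagged, mult in doc["mentions"]:
                c[(fid, cat)] += mult
        return out

    def planted_cancer_counts(self) -> dict[str, float]:
        """Per-gene total cancer-feature mentions (landscape ground truth)."""
        out: dict[str, float] = {}
        for doc in self.docs.values():
            out.setdefault(doc["gene_id"], 0.0)
            for fid, cat, _s, _t, mult in doc["mentions"]:
                if cat == "cancer":
                    out[doc["gene_id"]] += mult
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "panel": self.panel,
                    "genes": self.genes,
                    "features": self.features,
                    "docs": self.docs,
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    abstracts: list[AnnotatedAbstract]
    thesaurus: MeshThesaurus
    indexing: dict[str, set[str]]
    panel: GenePanel
    manifest: TruthManifest
    feature_defs: list[FeatureDef]


def _make_features(spec: SyntheticSpec) -> list[FeatureDef]:
    defs: list[FeatureDef] = []
    for cat, n in sorted(spec.n_features_per_category.items()):
        for i in range(n):
            if cat == "cancer":
                defs.append(FeatureDef(f"D1{i:03d}", cat, "Disease",
                                       f"cancerterm{i}", f"tumorterm{i}", False, False))
            elif cat == "drug":
                defs.append(FeatureDef(f"CHEM{i:03d}", cat, "Chemical",
                                       f"drugterm{i}", f"drugterm{i}", False, False))
            elif cat == "mutation":
                mut = f"V{600 + i}E"
                defs.append(FeatureDef(mut, cat, "Mutation", mut, mut, False, False))
            elif cat == "genetic_phenomena":
                defs.append(FeatureDef(f"D2{i:03d}", cat, "MeSH",
                                       f"genterm{i}", f"allelterm{i}", False, False))
            elif cat == "phenotype":
                defs.append(FeatureDef(f"D3{i:03d}", cat, "MeSH",
                                       f"phenterm{i}", f"traitterm{i}", False, False))
            else:
                raise ValueError(f"unknown category {cat!r}")
    # signal features: cancer first (the panel's characteristic category),
    # then the remaining categories in order
    order = sorted(range(len(defs)), key=lambda i: (defs[i].category != "cancer", i))
    signal_idx = set(order[: spec.n_signal_features])
    era_idx = set(order[: spec.n_era_features]) if spec.n_era_features else set()
    out = []
    for i, d in enumerate(defs):
        out.append(
            FeatureDef(d.feature_id, d.category, d.etype, d.mention, d.synonym,
                       i in signal_idx, i in era_idx)
        )
    return out


def build_thesaurus(feature_defs: list[FeatureDef]) -> MeshThesaurus:
    """Toy thesaurus: one root per MeSH branch plus one leaf per feature."""
    descriptors: dict[str, MeshDescriptor] = {}
    for cat, branch in CATEGORY_BRANCHES.items():
        descriptors[f"ROOT{branch}"] = MeshDescriptor(
            descriptor_id=f"ROOT{branch}",
            name=f"{cat} root",
            tree_numbers=frozenset({branch}),
            entry_terms=frozenset({f"{cat} root"}),
        )
    by_cat_counter: Counter = Counter()
    for d in feature_defs:
        branch = CATEGORY_BRANCHES.get(d.category)
        if branch is None:  # drugs/mutations are not MeSH descriptors here
            continue
        by_cat_counter[d.category] += 1
        leaf = by_cat_counter[d.category]
        descriptors[d.feature_id] = MeshDescriptor(
            descriptor_id=d.feature_id,
            name=d.mention,
            tree_numbers=frozenset({f"{branch}.{leaf:03d}"}),
            entry_terms=frozenset({d.mention, d.synonym}),
        )
    return MeshThesaurus(descriptors=descriptors)


def _render_doc(
    doc_id: str,
    gene_id: str,
    gene_mention: str,
    year: int,
    n_sentences: int,
    center: int,
    mentions: list[tuple[FeatureDef, int, bool, int]],  # (feature, sentence, tagged, mult)
) -> tuple[AnnotatedAbstract, set[str]]:
    """Assemble sentence strings, tracking character offsets of every mention.

    Returns the document plus the set of MeSH branch roots that must be in
    its indexing (one per untagged mention category).
    """
    # tokens per sentence: list of (surface, etype|None, concept_id|None)
    per_sentence: list[list[tuple[str, str | None, str | None]]] = [
        [] for _ in range(n_sentences)
    ]
    per_sentence[center].append((gene_mention, "Gene", gene_id))
    roots_needed: set[str] = set()
    for fdef, sent, tagged, mult in mentions:
        for _ in range(mult):
            if tagged:
                per_sentence[sent].append((fdef.mention, fdef.etype, fdef.feature_id))
            else:
                per_sentence[sent].append((fdef.synonym, None, None))
                roots_needed.add(f"ROOT{CATEGORY_BRANCHES[fdef.category]}")

    sentence_strings: list[str] = []
    annotations: list[tuple[int, int, str, str, str]] = []
    # build each sentence, remembering token offsets relative to sentence start
    offsets: list[list[tuple[int, int, str | None, str | None, str]]] = []
    for si in range(n_sentences):
        toks = per_sentence[si]
        if toks:
            prefix = "Study of " if si == 0 else "This work observed "
            parts = [prefix]
            pos = len(prefix)
            local = []
            for t, (surface, etype, cid) in enumerate(toks):
                if t > 0:
                    parts.append(" and ")
                    pos += 5
                parts.append(surface)
                local.append((pos, pos + len(surface), etype, cid, surface))
                pos += len(surface)
            suffix = " in patients." if si == 0 else " in this cohort."
            parts.append(suffix)
            sentence_strings.append("".join(parts))
            offsets.append(local)
        else:
            sentence_strings.append("No additional findings were noted.")
            offsets.append([])

    title = sentence_strings[0]
    abstract = " ".join(sentence_strings[1:])
    # absolute offset of each sentence start within title + " " + abstract
    starts = []
    cursor = 0
    for si, s in enumerate(sentence_strings):
        starts.append(cursor)
        cursor += len(s) + 1  # single joining space
    doc = AnnotatedAbstract(doc_id=doc_id, title=title, abstract=abstract, year=year)
    for si, local in enumerate(offsets):
        for lo, hi, etype, cid, surface in local:
            if etype is None:
                continue
            doc.annotations.append(
                EntityAnnotation(starts[si] + lo, starts[si] + hi, surface, etype, cid)
            )
    doc.annotations.sort(key=lambda a: (a.start, a.end, a.concept_id))
    doc.ensure_sentences()
    return doc, roots_needed


def generate_corpus(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate the corpus, thesaurus, indexing, panel, and truth manifest.

    Deterministic given ``spec.seed``; when ``out_dir`` is given the four
    input files plus the manifest are written there and re-reading them
    reproduces the in-memory objects exactly.
    """
    rng = np.random.default_rng(spec.seed)
    feature_defs = _make_features(spec)
    thesaurus = build_thesaurus(feature_defs)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    gene_mentions = {g: f"GENE{i}" for i, g in enumerate(genes)}
    panel_genes = sorted(rng.choice(genes, size=spec.n_panel, replace=False))
    panel = GenePanel(name="synthetic_panel", genes=frozenset(panel_genes))

    abstracts: list[AnnotatedAbstract] = []
    indexing: dict[str, set[str]] = {}
    docs_truth: dict[str, dict] = {}
    doc_no = 0
    for g in genes:
        for _ in range(spec.docs_per_gene):
            doc_no += 1
            doc_id = str(1_000_000 + doc_no)
            year = int(rng.integers(spec.year_lo, spec.year_hi + 1))
            center = int(rng.integers(0, spec.sentences_per_doc))
            w_lo = max(0, center - 1)
            w_hi = min(spec.sentences_per_doc - 1, center + 1)
            window = list(range(w_lo, w_hi + 1))
            mentions: list[tuple[FeatureDef, int, bool, int]] = []
            for fdef in feature_defs:
                p = (
                    spec.p_signal
                    if (fdef.signal and g in panel)
                    else spec.p_background
                )
                if fdef.era and spec.era_split_year and year < spec.era_split_year:
                    p = 0.0
                if rng.random() >= p:
                    continue
                sent = int(window[rng.integers(0, len(window))])
                if fdef.etype == "MeSH":
                    tagged = False
                elif fdef.etype == "Disease":
                    tagged = bool(rng.random() >= spec.untagged_fraction)
                else:
                    tagged = True
                mentions.append((fdef, sent, tagged, 1))
            doc, roots = _render_doc(
                doc_id, g, gene_mentions[g], year,
                spec.sentences_per_doc, center, mentions,
            )
            abstracts.append(doc)
            indexing[doc_id] = roots
            docs_truth[doc_id] = {
                "gene_id": g,
                "year": year,
                "n_sentences": spec.sentences_per_doc,
                "center_sentence": center,
                "mentions": [
                    (f.feature_id, f.category, s, t, m) for f, s, t, m in mentions
                ],
            }

    manifest = TruthManifest(
        panel=list(panel_genes),
        genes=genes,
        features={
            d.feature_id: {"category": d.category, "signal": d.signal, "era": d.era}
            for d in feature_defs
        },
        docs=docs_truth,
    )
    corpus = SyntheticCorpus(
        spec=spec,
        abstracts=abstracts,
        thesaurus=thesaurus,
        indexing=indexing,
        panel=panel,
        manifest=manifest,
        feature_defs=feature_defs,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        corpus_io.write_pubtator(abstracts, out_dir / "corpus.pubtator")
        corpus_io.write_mesh_table(thesaurus, out_dir / "mesh.tsv")
        corpus_io.write_indexing(indexing, out_dir / "indexing.tsv")
        corpus_io.write_panel(panel, out_dir / "panel.txt")
        manifest.to_json(out_dir / "manifest.json")
    return corpus


# pipeline harness -----------------------------------------------------------

def run_pipeline(
    abstracts: list[AnnotatedAbstract],
    thesaurus: MeshThesaurus,
    indexing: dict[str, set[str]],
    panel: GenePanel,
    *,
    alpha: float = 0.05,
    n_random: int = 500,
    min_features: int = 10,
    seed: int = 0,
    k_topics: int | None = None,
    models: tuple[str, ...] = ("linear_svm",),
    year_range: tuple[int, int] | None = None,
):
    """Ingest -> tag -> windows -> matrix -> select -> (topics, classify)."""
    from genecontext.feature_matrix import (
        build_tfidf,
        count_cooccurrence,
        filter_min_features,
    )
    from genecontext.gene_windows import collect_windows
    from genecontext.panel_classifier import benchmark_models, make_labels
    from genecontext.panel_selection import category_proportions, select_features
    from genecontext.topics import fit_nmf, topic_summaries

    if year_range is not None:
        abstracts = corpus_io.filter_by_year(abstracts, *year_range)
    for doc in abstracts:
        tag_with_mesh(
            doc, thesaurus,
            MeshIndexing(doc.doc_id, frozenset(indexing.get(doc.doc_id, set()))),
        )
    windows = collect_windows(abstracts, thesaurus)
    matrix = count_cooccurrence(windows)
    matrix = filter_min_features(matrix, k=min_features)
    matrix = build_tfidf(matrix)
    filtered, table = select_features(
        matrix, panel, alpha=alpha, n_random=n_random, seed=seed
    )
    result = {
        "matrix": matrix,
        "filtered": filtered,
        "selection_table": table,
        "category_proportions": category_proportions(table),
    }
    if k_topics:
        model = fit_nmf(filtered, k=k_topics, seed=seed)
        result["topics"] = model
        result["topic_summaries"] = topic_summaries(model)
    if models:
        y = make_labels(filtered, panel)
        result["labels"] = y
        result["reports"] = benchmark_models(filtered, y, models=models, seed=seed)
    return result


def end_to_end_check(
    spec: SyntheticSpec,
    alpha: float = 0.05,
    k: int | None = None,
    models: tuple[str, ...] = ("linear_svm",),
    min_features: int = 10,
) -> dict:
    """Run the full pipeline on a generated corpus and score recovery.

    Reports the fraction of planted signal features selected, the overall
    selected fraction (the type-I rate under a null spec), classifier
    accuracy/AUC per requested model, the cancer-category proportion before
    and after selection, and the cosine similarity between the text-mined
    gene frequency and the planted per-gene cancer mention counts.
    """
    from genecontext.landscape import (
        cosine_similarity,
        gene_cancer_matrix,
        gene_frequency,
    )

    corpus = generate_corpus(spec)
    res = run_pipeline(
        corpus.abstracts, corpus.thesaurus, corpus.indexing, corpus.panel,
        alpha=alpha, seed=spec.seed, k_topics=k, models=models,
        min_features=min_features,
    )
    table = res["selection_table"]
    signal_ids = {
        fid for fid, meta in corpus.manifest.features.items() if meta["signal"]
    }
    in_matrix = table["feature_id"].isin(signal_ids)
    n_signal = int(in_matrix.sum())
    recall = (
        float(table.loc[in_matrix, "selected"].mean()) if n_signal else float("nan")
    )
    props = res["category_proportions"]
    summary = {
        "n_genes": res["matrix"].n_gene,
        "n_features": len(res["matrix"].features),
        "n_selected": int(table["selected"].sum()),
        "selected_fraction": float(table["selected"].mean()),
        "signal_recall": recall,
        "n_signal_in_matrix": n_signal,
        "p_values": table["p_value"].to_numpy(),
        "cancer_proportion_before": float(props["before"].get("cancer", 0.0)),
        "cancer_proportion_after": float(props["after"].get("cancer", 0.0)),
    }
    if "reports" in res:
        summary["reports"] = res["reports"]
    if k:
        summary["nmf_loss"] = res["topics"].loss
    try:
        gcm = gene_cancer_matrix(res["matrix"])
        freq = gene_frequency(gcm)
        truth = corpus.manifest.planted_cancer_counts()
        summary["cosine_vs_truth"] = cosine_similarity(freq, truth)
    except ValueError:
        summary["cosine_vs_truth"] = float("nan")
    return summary
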