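# genecontext

Contextualize genes with text-mined co-occurrence features for gene panel
discovery.

Clinical sequencing assays (MSK-IMPACT, Oncomine, cardiovascular panels)
are curated gene sets, and deciding which genes belong on a panel requires
synthesizing an enormous biomedical literature. `genecontext` implements a
literature-mining pipeline that characterizes each gene by the biomedical
concepts — diseases, chemicals, mutations, MeSH descriptors — that co-occur
with it in article abstracts, and uses those term-feature profiles to
describe and predict panel membership.

## The pipeline

1. **Corpus ingestion** (`corpus_io`). Annotated abstracts are read in the
   PubTator tab-delimited exchange format and segmented into sentences with
   a deterministic rule-based splitter. Offsets are 0-based half-open over
   `title + " " + abstract`; a `PMID|y|YYYY` line extends the dialect with
   a publication year for time-sliced analyses.
2. **MeSH tagging** (`mesh_tagger`). Each article's indexed MeSH descriptors
   are expanded to their full descendant closure in the tree-number
   hierarchy, and every entry term (synonym) of the closure is
   string-matched in the text (case-insensitive, whole-token,
   hyphen/space-tolerant, longest match wins), recovering concept mentions
   the upstream NER missed. Concepts are merged by descriptor id.
3. **Gene windows** (`gene_windows`). Each gene mention contributes a
   three-sentence window — the mentioning sentence plus its neighbours,
   clipped at document bounds — and every other annotation inside the
   window becomes a term feature of that gene (multiset counts).
4. **TF-IDF matrix** (`feature_matrix`). The gene × term-feature matrix is
   scored as

   ```
   TF(g,t) = log(1 + tf_{g,t})          IDF(t) = log(1 + n_gene / df_t)
   score(g,t) = TF(g,t) · IDF(t)
   ```

   where `tf` is the co-occurrence count and `df_t` the number of genes
   containing feature `t`. Genes with fewer than 10 distinct features are
   dropped.
5. **Hypergeometric feature selection** (`panel_selection`). Against a
   background S′ of the panel S plus 500 randomly sampled non-panel genes,
   each feature's panel concentration is scored by the upper-tail
   hypergeometric p-value

   ```
   p = Σ_{y=Nst}^{min(Ns,Nt)}  C(Nt,y) C(N−Nt, Ns−y) / C(N, Ns)
   ```

   and features with p ≤ α (default 0.05) are retained. Features fall into
   five groups — cancer, drug, genetic phenomena, mutation, phenotype —
   and selection shifts the group proportions toward the panel's
   characteristic categories.
6. **Topics** (`topics`). NMF factorizes the selected score matrix
   X ≈ WH (squared-Frobenius objective, multiplicative updates, monotone
   loss trace), and each topic is summarized by its top-20 genes and
   features.
7. **Classification** (`panel_classifier`). Genes are labeled
   target/non-target by panel membership and seven classifier families
   (nearest neighbors, linear SVM, Gaussian process, decision tree, random
   forest, neural net, naive Bayes) are benchmarked with stratified 5-fold
   cross-validation: pooled out-of-fold accuracy, per-class
   precision/recall/F1, ROC and trapezoidal AUC.
8. **Landscape** (`landscape`). The cancer-feature submatrix yields a
   gene × cancer-type association table and a per-gene literature
   frequency, validated against an external frequency vector by cosine
   similarity; year-sliced corpora give era contrasts.

A fully synthetic data generator (`synthetic`) emits PubTator corpora, a
toy MeSH thesaurus, per-article indexing, panels, and a ground-truth
manifest with planted co-occurrence structure; every stage of the pipeline
is tested against that ground truth.

## Worked example

```python
from genecontext import SyntheticSpec, generate_corpus
from genecontext.synthetic import run_pipeline

spec = SyntheticSpec(n_genes=60, n_panel=15, seed=42)
corpus = generate_corpus(spec)
res = run_pipeline(
    corpus.abstracts, corpus.thesaurus, corpus.indexing, corpus.panel,
    alpha=0.05, seed=42, k_topics=3, models=("linear_svm",),
)
m = res["matrix"]
print(f"matrix: {m.n_gene} genes x {len(m.features)} term features")
table = res["selection_table"]
print(f"selected {int(table['selected'].sum())} of {len(table)} features")
rep = res["reports"]["linear_svm"]
print(f"linear SVM: accuracy={rep.accuracy:.3f}, AUC={rep.auc:.3f}")
```

prints

```
matrix: 53 genes x 44 term features
selected 10 of 44 features
linear SVM: accuracy=1.000, AUC=1.000
```

53 of the 60 genes survive the 10-feature minimum; of the 44 term
features, the selection keeps 10 — the 8 planted panel-enriched "signal"
features (all cancer-category, e.g. `D1000` with Nt=21 genes containing
it of which Nst=12 are panel genes, p ≈ 2.5e-4) plus 2 borderline noise
features — and the resulting profiles separate panel from non-panel genes
perfectly under 5-fold cross-validation.

The same flow is available from the shell:

```bash
genecontext synth --out data/ --seed 42
genecontext pipeline --pubtator data/corpus.pubtator --mesh data/mesh.tsv \
    --indexing data/indexing.tsv --panel data/panel.txt \
    --out results/ --seed 42 --topics 3 --models linear_svm
```

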