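# Methods

## Model and procedure

The pipeline treats each gene as a "document" whose tokens are the
biomedical concepts co-occurring with it in the literature. The unit of
co-occurrence is the three-sentence gene window: the sentence containing a
gene mention, its predecessor, and its successor, clipped at document
boundaries. Windows of the same gene centered on the same sentence are
counted once; overlapping windows from adjacent centers are both kept and
counted independently. A feature mentioned twice inside one window
contributes count 2 (multiset semantics — the co-occurrence frequency is a
mention count, not a presence flag). Other genes inside a window are
legitimate features of the focal gene and are grouped with phenotype
features by default.

Genes are keyed by normalized concept id, not surface form, so synonymous
mentions aggregate. Term features are keyed by (concept id, category),
with five categories: cancer, drug, genetic phenomena, mutation,
phenotype. Category assignment is deterministic: mutation annotations →
mutation; chemicals → drug; disease/MeSH concepts whose tree numbers fall
under the neoplasms branch (default root `C04`) → cancer; MeSH concepts
under the genetic-phenomena branch (default root `G05`) →
genetic_phenomena; everything else → phenotype. The branch roots are
configuration, not hard-coded ontology; disease identifiers that cannot
be resolved in the thesaurus default to cancer, unresolvable MeSH ids to
phenotype with a warning.

### MeSH tagging

The tagger starts from the article's curator-indexed descriptors, expands
each to its descendant closure (a descriptor is a descendant when one of
its dot-delimited tree numbers strictly extends a tree number of the
ancestor), and matches every entry term of every closure descriptor in
the text. Matching is case-insensitive, whole-token, hyphen/space
equivalent ("non small cell" ≡ "non-small cell"), and confined to a
single sentence: we take the view that a multi-word term spanning a
sentence boundary is a segmentation artifact, not a mention. Spans
already covered by an upstream annotation are never double-tagged; among
overlapping candidates the longest span wins, ties broken by smallest
descriptor id. These rules make tagging idempotent.

### Scoring

TF(g,t) = ln(1 + tf), IDF(t) = ln(1 + n_gene/df). Natural logarithms:
any fixed base rescales every score by the same constant, so rankings and
downstream selection are base-invariant. df is recomputed whenever the
gene set changes (after the minimum-feature filter) so the matrix is
always self-consistent; the filter drops genes with fewer than 10
distinct features, then drops features left with df = 0. Rows and columns
are sorted lexicographically so serialization is deterministic.

### Feature selection

The background S′ is the panel ∩ matrix genes plus 500 non-panel matrix
genes sampled without replacement under a recorded seed (all of them,
with a warning, when fewer exist). Presence (count > 0), not score
magnitude, defines Nt and Nst. P-values are exact upper-tail
hypergeometric sums evaluated in log space (log-gamma binomials +
log-sum-exp), accurate to ~1e-12 against rational enumeration and immune
to underflow at corpus scale. The selection threshold is α = 0.05 on raw
p-values; no multiple-testing correction is applied by default because
selection here is a ranking/enrichment device, not an inference claim —
a Benjamini–Hochberg mode exists behind a flag. By default all matrix
genes survive into the column-filtered matrix (downstream classification
labels every gene); restricting rows to S′ is a flag.

### Topics

NMF minimizes ‖X − WH‖²_F with multiplicative updates, which are monotone
(the per-iteration loss trace is non-increasing to within 1e-9 relative
per step — the property the unit tests assert). Initialization is
non-negative double SVD with zeros filled at √(mean(X)/k), which is
deterministic and makes the whole fit equivariant under X → cX
(loss scales by c²); a seeded random init is available. Defaults:
tol = 1e-4 relative loss change, max_iter = 500, k = 30 for a
full-size panel analysis (configurable; small studies use smaller k).
Topics are fit on TF-IDF scores rather than raw counts, since the
selected score matrix is the object the rest of the analysis consumes.

### Classification

Stratified 5-fold cross-validation with a fixed seed; metrics are
computed on pooled out-of-fold predictions (each gene predicted exactly
once), which is the variant we label in all outputs. Model
hyperparameters are scikit-learn defaults — the benchmark is a
feature-set evaluation, not a model-tuning exercise. ROC curves use each
model's continuous decision score (decision function when available,
positive-class probability otherwise); AUC is the trapezoidal area, which
equals the normalized Mann–Whitney rank statistic. No class reweighting
by default.

### Landscape

"Gene frequency" from text mining is defined as the normalized row sums
of the gene × cancer-type TF-IDF submatrix — a definition, not a derived
fact, and external comparisons (cosine similarity against a clinical
frequency vector) depend on it. Vectors are aligned on the union of gene
ids with zero fill. Cancer-descriptor → display-type mappings are
user-supplied configuration.

## Synthetic study conditions

The generator emulates a PubTator-annotated abstract corpus: each
document is about one focal gene, with templated sentences, planted
entity offsets, and a publication year. Signal features co-occur with
panel genes at rate `p_signal` per document and with all genes at
`p_background`; signal features are drawn from the cancer category first,
so successful selection visibly shifts category proportions. MeSH-branch
features (and a 25% fraction of disease mentions) are emitted untagged
but entry-term-matchable, so the tagger is genuinely load-bearing in
every end-to-end run. An era switch suppresses chosen features before a
cutoff year to emulate time-sliced contrasts.

Default conditions: 120 genes, 30-gene panel, 3 documents per gene, 5
sentences per document, 8 signal features among 44, p_signal = 0.5,
p_background = 0.1, years 2011–2019. The null study used for calibration
raises the feature count to 200 (40 per category) and sets both rates to
0.2, which keeps per-gene presence probabilities mid-range so the
discreteness of the hypergeometric null does not dominate the selection
rate. At these sizes the whole pipeline runs in seconds; they are chosen
as the smallest corpus in which every stage (splitting, tagging,
windowing, selection, classification) operates away from degenerate
boundaries.

What the generator does not emulate: realistic token distributions,
polysemous entry terms, multi-gene documents (each synthetic document
mentions one gene, so gene–gene co-occurrence features are exercised only
in unit tests), annotation noise beyond offset-drift cases, and corpus
scale. Passing tests therefore demonstrate correctness of the machinery
and calibration of the statistics under controlled conditions — not
performance on real PubMed text.

## Numerical and degenerate-input choices

- Sentence splitting is rule-based with a fixed biomedical abbreviation
  stop-list; deterministic, no model download. Single-letter tokens
  ("A.") do end sentences.
- Mention/offset disagreement in input files trusts the offsets and
  recomputes the mention, with a warning (real corpora contain drifted
  offsets); non-integer or out-of-bounds offsets are hard errors with
  line numbers.
- An empty panel file, a duplicate MeSH descriptor id, an inverted year
  range, α ∉ (0,1], df = 0, k outside [1, min(m,n)], a matrix left empty
  by the minimum-feature filter, and single-class label vectors are all
  explicit errors rather than silent degradations.
- Ties everywhere break lexicographically by identifier, making every
  output deterministic given seeds.

## Known limitations

- Co-occurrence in a three-sentence window is not a relation: related
  entities that never co-occur are invisible, and co-occurrence does not
  imply mechanism.
- TF-IDF weights common diseases heavily; rare-disease features are
  systematically under-weighted.
- The hypergeometric background resamples once per run; selection near
  the α boundary can differ across background seeds (the seed is recorded
  in run manifests).
- The in-house NMF is dense; matrices far beyond ~10⁴ × 10⁴ would need a
  sparse update path.
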