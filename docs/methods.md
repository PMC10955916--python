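# Methods

## The model

`stressclust` treats a cohort of interview transcripts (one document per
respondent) as a document × term TF-IDF matrix `V` and asks whether the
cohort splits into two groups by vocabulary use alone. The working
assumption is that respondents under different stress burdens dwell on
different themes and therefore use partially disjoint sets of content
words, while sharing a large background vocabulary of function-like
words that carries no group signal.

The clustering is a two-phase ensemble:

**Phase 1 — ensemble member generation.** Non-negative matrix
factorization `V ≈ WH` (`W`: documents × k loadings, `H`: k × terms
topics) is fit with the Frobenius objective by the classical
multiplicative updates, starting from a seeded uniform-(0, 1]
initialization. Because NMF is non-convex, different seeds land in
different local minima and produce genuinely different topic sets; the
method exploits this instead of suppressing it, fitting `S` independent
runs and pooling all `S × k` L2-normalized rows of `H` as ensemble
members. Defaults are k = 10 topics and S = 70 seeds, i.e. 700 members.

**Phase 2 — consensus.** The pooled topic vectors are merged by
agglomerative hierarchical clustering with complete linkage on cosine
distance, and the tree is cut at 2 clusters. Cosine is the natural
metric here because NMF factors are scale-indeterminate and the topic
rows have been normalized; complete linkage keeps clusters compact, so
the two topic clusters correspond to the two recurring vocabulary
blocks across runs.

**Document assignment.** The consensus step clusters *topics*, not
documents, so an explicit assignment rule is needed. Within each run,
`W` columns are first rescaled by the Euclidean norm of the matching
`H` row (this keeps the product `WH` unchanged, removing the per-factor
scale ambiguity) and then each document's loading row is L1-normalized,
so every run contributes exactly one unit of loading mass per document.
A document's score for cluster `c` is the sum of its normalized
loadings over all pooled topics assigned to `c`; assignment is argmax,
with exact ties going to the lower cluster index. Summed over clusters
a document's scores therefore equal S, a conservation property the
tests assert. This rule uses all 700 members symmetrically and reduces
to "majority topic mass".

**Evaluation.** Cluster ids are arbitrary, so evaluation tries both
cluster→label permutations and keeps the accuracy-maximizing one
(identity on ties). Reported rates follow the convention of the
screening literature this package targets: *positive = low stress*,
*negative = high stress* — the reverse of the usual clinical
convention, which is why the fields are named `tpr_low` / `tnr_high`
rather than bare TPR/TNR.

## TF-IDF and the pruning rules

TF is the raw within-document count; IDF is the smoothed variant
`idf(t) = ln((1+N)/(1+df(t))) + 1`; rows are L2-normalized. This is the
scikit-learn reference formulation (and the package indeed delegates to
`TfidfTransformer`), chosen because the pruning thresholds below are
only meaningful relative to a fixed variant; both thresholds are
configurable for that reason.

Two rules prune the vocabulary, evaluated on the normalized weights,
once, before any modeling, with no renormalization afterwards:

* **Rule (i), rare words** — total weight `Σ_d w[d,t] ≥ tau_total`
  (default 0.5). A word occurring once or twice corpus-wide cannot
  discriminate anything.
* **Rule (ii), common words** — `max_d w[d,t] / Σ_d w[d,t] ≥ tau_ratio`
  (default 0.1). A word spread evenly over n documents has ratio
  ≈ 1/n, so the rule removes words appearing uniformly in more than
  ~10 documents while keeping words concentrated in a few.

The mutual-information ranking used by the word-fraction experiment
binarizes each term to presence/absence and applies the plug-in
(maximum-likelihood) estimator on the 2×2 term × label table, in bits.
Binarization is the most defensible choice for 100 documents — a
continuous or binned estimator would be dominated by estimation noise
at this sample size. Ties in score break lexicographically so rankings
are reproducible.

## Numerical choices

* **NMF:** multiplicative updates with a `1e-12` additive guard in the
  denominators; initialization `1 − U[0,1)` so factors are strictly
  positive; convergence when the relative Frobenius-error improvement
  drops below `tol` (default `1e-5`) or after `max_iter` (default 300)
  iterations. The recorded error sequence is non-increasing (the
  update's monotonicity property), which the tests assert to
  floating-point tolerance. Seeds are `seed_base + run_index`.
* **Complete linkage** is implemented directly (O(n³) in the naive
  form, fast enough for 700 members): merge the active pair with the
  smallest maximum inter-member distance; among exactly tied pairs the
  one with the smallest member indices merges first, making the
  partition deterministic. Tests check equivalence with SciPy's
  implementation on random pools.
* **Degenerate inputs:** an all-identical topic pool cannot be cut into
  2 clusters and raises; a filter configuration that discards every
  term raises with advice to relax the thresholds; a document with an
  all-zero consensus profile makes cosine distance undefined and raises
  with the document id.
* **Classical MDS** (Torgerson): eigendecomposition of the
  double-centered `−D²/2`, top-2 eigenpairs, each axis's sign fixed so
  its largest-magnitude coordinate is positive. Chosen over iterative
  stress majorization because it is deterministic and exact on
  Euclidean inputs (the planar round-trip test reproduces distances to
  1e-6). With fewer than two positive eigenvalues the embedding is
  padded with a zero column under a warning — this happens naturally
  when the two clusters are near-perfectly separated and the profiles
  are effectively one-dimensional.
* **Word-fraction experiment:** the restricted vocabulary at small
  fractions can contain fewer terms than `n_topics`; the topic count is
  clamped to the slice size so the protocol remains runnable at every
  fraction. A fraction leaving fewer documents with nonzero weight
  than clusters is recorded as NaN rather than aborting the curve.

## The synthetic generator

`generate_corpus` emulates the corpus structure the method assumes:
two groups of 50 respondents, 200 tokens per document, drawn
token-by-token from three word roles — shared background words
(probability 0.5, 60 words), group topic words (probability 0.45, 40
words per group), and rare words (probability 0.05, 30 singleton words
that are each used at most once corpus-wide and then retired, falling
back to background words when exhausted).

Two structural choices deserve emphasis:

* **Per-document topic subsets.** Each document draws its topic words
  from a personal random subset of 8 of its group's 40 words rather
  than the full group vocabulary. This models respondents dwelling on
  a handful of personal themes, and it is what gives discriminative
  words the concentrated profile (present in ~10 documents with high
  weight) that rule (ii) is designed to *keep*. Without it every group
  word would be spread near-uniformly over ~45 documents, and rule (ii)
  would remove the entire vocabulary — the filter's premise is
  concentration, and a generator without concentration exercises
  nothing.
* **Separation semantics.** `separation ∈ [0, 1]` scales exclusivity:
  a topic-word draw uses the document's own group vocabulary with
  probability `0.5 + separation/2`. At 1.0 groups are fully exclusive;
  at 0.0 both groups draw from one shared distribution and matched
  accuracy sits at chance — the negative control the tests check.

Within-role distributions are uniform by default; a Zipf weight
(`zipf_exponent`) is available for heavier-tailed word frequencies but
is not part of the default conditions.

**What passing tests do and do not show.** The generator produces
balanced groups, equal-length documents, exact singleton rare words and
cleanly disjoint topic vocabularies. Real transcripts have none of
these luxuries: unbalanced classes, varying document lengths,
correlated themes across groups, segmentation errors and
speech-recognition noise. Perfect recovery on the synthetic benchmark
therefore validates the *mechanics* (filtering keeps the right word
class, the ensemble consensus finds the planted structure, the
arithmetic is right) — it does not predict accuracy on real cohorts,
where the separation between groups is far weaker.

## Problem sizes

The test suite and the acceptance script run the full default
configuration (100 documents, 70 × 10 ensemble, 5 generator seeds per
condition); nothing is scaled down, since a full pipeline run takes on
the order of a second. The word-fraction unit tests use a reduced
ensemble (6 seeds × 5 topics) because the protocol reruns the pipeline
once per fraction; the full-size protocol is exercised through the CLI
and acceptance script.

## Known limitations

* The document-assignment rule and the MDS input (consensus score
  profiles) are this package's own design choices; other reasonable
  choices (e.g. co-association matrices, embedding documents in TF-IDF
  space) exist and may differ on weakly separated data.
* The filter thresholds are tied to the TF-IDF variant; with a
  different normalization the defaults 0.5 / 0.1 are not transferable.
* Binary consensus only: `n_clusters` is configurable but the
  evaluation and label matching assume two classes.
* No statistical uncertainty is attached to the accuracy numbers; the
  method is deterministic given `seed_base`, and variability across
  seed bases is not summarized.
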