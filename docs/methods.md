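# Methods

## Scope

littrends implements a literature-mining workflow: corpus ingestion
(MEDLINE flat files or delimited tables), text preprocessing, LDA topic
modeling by collapsed Gibbs sampling, four-metric selection of the topic
count, four-phase Topic Significance Ranking (TSR) with temporal tracking,
and MeSH-term / gene-mention trend analyses. A synthetic-corpus generator
with full ground truth backs every statistical claim. Bibliometric network
analyses (collaboration, co-citation, keyword bursts) and visualization
aesthetics are out of scope; the package exports the matrices behind such
figures as TSV.

## Preprocessing

Cleaning lower-cases text and replaces every character outside
`[a-z0-9 -]` with a space (hyphens are kept inside tokens because
biomedical compounds such as "hpv-positive" carry meaning). Stemming is the
Porter (1980) algorithm, implemented in-package from the published rule
tables; hyphenated parts are stemmed separately. Phrase detection merges an
adjacent bigram (a, b) into one token when count(a,b) ≥ min_count and

    score(a,b) = (count(a,b) − min_count) · V / (count(a) · count(b))

reaches a threshold (defaults min_count = 5, threshold = 10), in a single
greedy left-to-right pass per document. Pruning removes a fixed, versioned
English stopword list (shipped in `_stopwords.py`; user lists are appended,
and stems of stopwords are also removed) and terms with document frequency
below min_df = 5 or above max_df_frac = 0.5 of the corpus; both thresholds
are config-overridable and echoed into the run manifest. Pruning is a
single pass: thresholds are judged on the input document-frequency table,
then emptied documents are dropped. Because the surviving terms appear in
no dropped document, re-pruning changes nothing whenever min_df alone is
binding; the max_df_frac bound is relative to the document count, so
re-pruning after document drops can in principle remove more (an iterated
fixpoint variant was rejected: on small corpora it can cascade to an empty
corpus).

## LDA and sampling choices

Symmetric hyperparameters, defaults α = 50/K and β = 0.1, both overridable
and logged. Token assignments are initialized uniformly at random from the
run seed; the sweep kernel is numba-JIT-compiled and fully deterministic
given the seed. Point estimates come from the final Gibbs state — samples
are not averaged across iterations because topic labels can switch between
modes. The complete-data log likelihood
log P(W|Z, β) + log P(Z|α) is recorded every post-burn-in sweep via the
collapsed Dirichlet-multinomial closed form.

Single chains occasionally freeze in a mode where two planted topics are
merged and a third is split; the complete-data log likelihood of such modes
sits far (thousands of nats) below the dominant mode. `fit(...,
n_restarts=R)` therefore runs R independent chains and keeps the best final
log likelihood. The default remains a single chain; validation paths use
R = 3.

For tiny corpora the sampler can also accumulate the posterior pairwise
co-assignment matrix P(z_s = z_t). This is the label-permutation-invariant
posterior summary: with symmetric priors every token's marginal topic
probability is exactly 1/K by label exchangeability, so marginals cannot
distinguish a correct sampler from a broken one, while co-assignments can
be compared against exact enumeration.

## Topic-number selection

Arun2010: symmetric KL divergence (sum of both directions) between the
L1-normalized singular values of φ and the L1-normalized vector of topic
masses (document lengths · θ), both sorted descending. CaoJuan2009: mean
pairwise cosine similarity of φ rows. Deveaud2014: mean pairwise
symmetrized KL divergence ½[KL(p‖q) + KL(q‖p)] of smoothed φ rows.
Griffiths2004: harmonic-mean estimator of log P(W|K) computed in log space
from the recorded complete-data log-likelihood trace. All logs are guarded
by ε = 1e-12 smoothing so sparse or junk rows cannot produce infinities.
`select_k` fits one model per candidate (seed policy: seed + K) and reports
each metric's optimum; it never auto-commits a K, since the final choice
also weighs domain knowledge and corpus size.

## Topic Significance Ranking

Raw distances C_{k,m,c} compare topic k to criterion c's benchmark under
metric m ∈ {KL, COR, COS}. Criteria U (uniformity, benchmark uniform over
words) and V (vacuousness, benchmark = empirical corpus word marginal) are
computed in word space against φ_k; criterion B (background) in document
space between the topic's normalized θ column and the uniform-over-documents
reference. COR against a constant vector (the uniform benchmarks) is
undefined; the correlation is treated as 0, giving distance 1. Tiny
negative self-distances from floating-point cancellation are clamped to 0.

Total standardization is implemented exactly as the source prints it,
C′₁ = C·(T − C)/T with T the cross-topic sum — not a conventional
normalization, but fidelity wins; a plain share mode C/T is available
behind `total_mode="share"` for sensitivity analysis. Range standardization
is min-max with the degenerate (constant) case mapped to 0.5. Within each
criterion the three metric scores are averaged (Ψ_m uniform); across
criteria Ŝ_k = S1_k^b(Ψ′_u S1_k^u + Ψ′_v S1_k^v) and
Ψ̂_k = Ψ_u S2_k^u + Ψ_v S2_k^v + Ψ_b S2_k^b, with TSR_k = Ψ̂_k Ŝ_k. Default
weights are neutral: Ψ′_u = Ψ′_v = 1/2, Ψ_u = Ψ_v = Ψ_b = 1/3, recorded in
the manifest. Larger distance from junk means larger TSR; rank 1 is most
significant, ties broken by lower topic index.

Orientation note: because significance is distance from background-like
references, a topic that dominates a period moves toward that period's
word marginal and document background and *loses* rank there, while a topic
absent from a period has a near-uniform residual document column and also
scores low on the background criterion. Temporal trajectories therefore
reward topics that are present but specific, not merely voluminous.

Temporal TSR fixes topics from the global model (the trajectories track the
same topics across periods); each period's θ rows are restricted to its
documents and the benchmarks are recomputed from the period's tokens.
Default periods: 2013–2015, 2016–2018, 2019–2022. Periods must be disjoint
and non-empty.

## Trend analyses

Documents are pooled by dominant topic (argmax of the θ row, ties to the
lower index). "Significant differences across topics" is operationalized as
a chi-square goodness-of-fit test of the term's per-topic counts against
the documents-per-topic margin, default α-level 0.05, no multiple-testing
correction; when only one topic holds documents the test is vacuous and the
term passes. Threshold semantics are locked by tests: term-topic matrix
keeps totals strictly greater than 5; annual tables keep per-year counts of
at least 6; gene tables keep totals of at least 2. Term counting is
per-document presence (a heading is a set member); gene counting is
per-mention by default. Gene recognition is case-sensitive whole-token
matching against a user lexicon — not learned NER — with an optional
corpus-level TF-IDF floor (total term frequency × ln(M/df)); the default
floor of 0 passes all matches so headline counts do not depend on an
undocumented cutoff. Emergence tables record each term's first corpus year
regardless of frequency; terms first seen in the corpus's minimum year are
flagged left-censored because the collection window truncates their
history, and reporting starts the following year by default.

## Synthetic-data generator

The generator draws corpora from the standard LDA process: θ_j ~ Dir(α)
(default α = 0.1, near-pure documents as in focused research abstracts),
φ_k ~ Dir(β) (default β = 0.05 wide-support topics, or disjoint uniform
blocks via `separated_spec` for the maximally recoverable case), document
lengths Poisson(60) truncated at ≥ 5 tokens (abstract-sized documents;
truncation avoids degenerate θ estimates), years uniform over 2013–2022 so
period sub-corpora are balanced. Junk plants occupy the last topic indices:
a uniform plant has φ row = 1/V; a vacuous plant copies the expected
word marginal of the non-junk topics. Tags ("tagNNN") are drawn with
probability `tag_enrichment` (default 0.8) from the dominant topic's
preferred tags, else uniformly; gene mentions are literal upper-case
symbols appended to the text so the lexicon matcher finds them without an
NER model. An optional year skew concentrates one topic's documents in the
final third of the year range for temporal tests. The generator reproduces
none of the surface statistics of real abstracts (Zipfian token
frequencies, sentence structure, correlated headings), so passing tests
demonstrate correctness of the algorithms under the stated generative
assumptions, not performance on real PubMed text.

A planted vacuous topic is identifiable to the ranking stage but not to the
fitting stage: its word distribution is exactly a convex combination of the
real topics, so the likelihood always prefers explaining its documents as
mixtures. Junk-suppression validation therefore scores the planted topic
set itself (`synthetic.truth_model` views the ground truth as a fitted
model); sampler recovery is validated separately on separated-support
corpora, where every topic is identifiable.

## Validation problem sizes and numerical choices

Junk suppression: 20 corpora, 6 topics (uniform + vacuous plants), M = 300,
mean length 50. Recovery: 10 corpora from `separated_spec(5, 200)`,
M = 400, mean length 60, fitted at α = 0.1, β = 0.01, 300 sweeps, 3
restarts; topics matched greedily by total-variation distance. Posterior
agreement: 10-token two-document corpus, K = 2, exhaustive enumeration of
all 1024 assignments vs 5000 Gibbs sweeps. K selection: grid 2–9 on the
recovery corpora, 200 sweeps, 2 restarts. These sizes make every check
reproducible on a laptop in minutes; the statistical conclusions are not
sensitive to them in either direction (larger corpora only sharpen the
margins).

Degenerate inputs have fixed policies: all-zero score vectors standardize
to zeros with a logged warning; constant vectors range-standardize to 0.5;
K = 1 models skip pairwise selection metrics (they require K ≥ 2); empty
corpora, empty lexicons, zero-record files, and overlapping or empty year
periods raise hard errors naming the offender.

## Known limitations

The sampler is single-machine and in-memory; no variational or online
inference. Hyperparameters are not optimized during sampling. Gene
recognition misses synonyms, aliases, and case variants by design. The
chi-square association test is unadjusted for multiple testing, mirroring
common practice in descriptive literature analyses; users comparing many
terms should apply their own correction. Real-corpus claims (which topics a
field contains, their names, their clinical meaning) require human review
of the keyword tables and are outside what the package can validate.
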