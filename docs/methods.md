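# Methods

`reportfit` implements a lightweight, data-driven strategy for deciding
how well candidate language models "fit" the free text of patient-safety
incident reports. The corpus is reduced to a small, category-balanced
probe set — discriminative target tokens, then a minimal set of target
sentences containing them — and each candidate model is judged by the
perplexity it assigns to those sentences, compared per event category
with a one-way ANOVA. This note records the models, parameters, and
design choices, and what the synthetic test bed does and does not show.

## Text conventions (corpus)

Analysis tokenization is lowercase, split on every non-alphanumeric
character, dropping pure-number tokens and single characters. Target
tokens in this domain are ordinary lowercase words; digit runs are
record identifiers and dosages that would otherwise flood the
statistics. Hyphenated compounds split into their components. No
stopword removal is applied: the selection inequality plus the expert
deny-list are responsible for ubiquitous words.

Sentence segmentation is rule-based and versioned
(`SEGMENTER_VERSION = "1.0"`): split after `.`/`!`/`?` followed by
whitespace, unless the preceding word is a known abbreviation
(honorifics, Latinisms such as "e.g.") or a single letter (initials).
Joining a report's sentences with single spaces reproduces its
whitespace-normalized text, so segmentation never loses narrative. A
rule-based segmenter was chosen over a statistical one because the cover
stage needs bit-reproducible sentence identities.

## Target-token selection

For token *t* and category *n*, p(t|n) is estimated by relative token
frequency: occurrences of *t* in category *n* divided by the total token
count of *n* (rows sum to 1 per category). A `report` estimator
(document frequency per report) is available behind a switch for users
who prefer report-level prevalence; the token-frequency reading is the
default because the quantity being modelled is the probability of a
token occurring.

Token *t* is assigned to category *j* when

    p(t | n_j) > Σ_{k ≠ j} p(t | n_k)

The winning probability must exceed half of the token's total
conditional mass, so at most one category can win: the per-category sets
are disjoint by construction, and the implementation only needs to test
the argmax category. Ties (exact equality) select nothing. A minimum
raw count in the winning category (default 3) suppresses hapax
artifacts; it is the mechanizable sliver of the human curation step.
The expert-review step itself is file-driven — per-category deny/allow
lists, one token per line — never interactive, so pipelines are
reproducible end to end.

## Target-sentence cover

Per category, the cover problem is: select sentences so that every
target token appears in at least one selected sentence, visiting **at
most one sentence per report** (to avoid oversampling a single
narrative). The solver is a greedy depth-first search with
backtracking: order candidate sentences by the number of still-uncovered
tokens they contain (ties broken by `(report_id, sent_index)`), take the
best sentence from an unvisited report, and on a dead end undo the most
recent selection and forbid it at that depth. A memo of
already-explored selection sets prunes permutations of the same state,
and an optimistic coverage bound (tokens reachable through unvisited
reports) prunes branches that cannot beat the best coverage found. The
search therefore terminates, and on small instances it provably attains
maximal coverage; a node-expansion cap (default 10 000 per category)
bounds worst-case work, freezing the best solution found and reporting
the remainder uncovered with a `search_cap` reason code.

Infeasibility is data, not an exception: tokens contained in no
candidate sentence are reported `no_candidate`; tokens that the search
could not place are reported `not_covered`. When no full cover exists
the maximal-coverage token *set* need not be unique — two correct
solvers can cover the same number but not the same tokens — so the
guarantee tested against the exhaustive oracle is equality of coverage
size, plus set equality whenever a full cover is feasible.

`exact_cover` is an exhaustive reference solver (one sentence or none
per report, maximize coverage then minimize cardinality, deterministic
tie-breaks) limited to small instances; it exists to validate the greedy
search and is not a pipeline stage.

## Perplexity

Perplexity of a sentence with backend tokens w_1..w_n is

    PPL = exp( −(1/n) Σ_i log p(w_i | w_<i) )

computed in natural log. A start-of-sequence context is always supplied
so that the first token receives a proper conditional probability and
every scored token has positive probability; perplexity is therefore ≥ 1
for any proper model. Sequences beyond the backend's
`max_sequence_length` keep their prefix (single sentences virtually
never truncate). Batching (default size 16) is throughput-only and
bit-identical to sentence-by-sentence scoring.

The reference backend is an additive-smoothed n-gram model (orders 1–3,
default smoothing 0.1) over a closed training vocabulary plus an
explicit unknown class:

    p(w | ctx) = (c(ctx, w) + a) / (c(ctx) + a·(|V| + 1))

Probabilities sum to one over V ∪ {unk} for every context, unknown
tokens stay finite, and as a → ∞ the model tends to uniform over
V ∪ {unk}. An adapter for Hugging Face causal-LM checkpoints (scoring
under each checkpoint's own tokenizer, which is part of the method) is
provided as an optional extra; it raises a clear environment error when
`torch`/`transformers` or the checkpoint are absent, and nothing else in
the package depends on it. Sub-word tokens are scored directly, without
aggregation to words.

## Model comparison

Per category, only sentences scored by every model enter the summary, so
n is identical across models. Reported per model: mean perplexity and
SEM = sample sd / √n. The omnibus test is a one-way fixed-effects ANOVA
with model as the factor and sentence-level perplexity as the response,
run per category on raw perplexities; a `log` switch is available
because perplexity is right-skewed, and raw is the default for fidelity
to how mean perplexities are conventionally reported. Sentences are
treated as independent observations (a simplification: sentences from
the same report share an author and context); no post-hoc pairwise tests
are run. Degenerate inputs (all values identical) return F = 0, p = 1.
The significance threshold for textual reports is 0.05.

`null_calibration` pushes simulated Gaussian perplexity tables through
the same summarize/ANOVA path: under the null the p-values are uniform
(checked by KS distance and the rejection rate at 0.05), and a planted
one-sd location shift at n = 60 per group is detected essentially
always. It is a self-check of the statistical wiring, not a pipeline
stage.

## Synthetic test bed

Real incident-report corpora are protected, so the test bed generates
per-category unigram mixtures: a shared Zipf-weighted background
vocabulary plus, for each category, a disjoint set of signal tokens
whose sampling weight is multiplied by `signal_boost` in their home
category. Defaults: 4 categories × 200 reports, ~3 sentences/report and
~8 tokens/sentence (Poisson with floors 1 and 3), 300 vocabulary types
of which 10 per category are signal tokens, boost 20, Zipf exponent 0.3,
signal base weight equal to the median background weight. Everything is
deterministic given the seed; `category_distribution` exposes the exact
distribution each category samples from, so empirical-convergence tests
have a closed-form target.

The vocabulary size and Zipf exponent are sized together from an
explicit failure analysis. A background token is falsely selected
exactly when one category collects a strict majority of its occurrences
by chance, and for a token with expected per-category count λ that
probability is roughly 4·P(Poisson(λ) > Poisson(3λ)), which decays
exponentially in λ. Summing this over the designed background (300
types, exponent 0.3, ~19 000 corpus tokens, minimum expected count ≈ 35)
gives < 1 expected false selection corpus-wide; a heavier tail (more
types or a steeper exponent) floods the selector with low-count
artifacts instead. An earlier draft of the generator (500 types,
exponent 0.7) failed its own recoverability contract for exactly this
reason and was redesigned from this computation.

What the synthetic bed shows: the selection inequality, cover
feasibility and backtracking, matched-vs-mismatched perplexity
discrimination (per-category n-gram models standing in for
clinical-vs-general pretrained models), and ANOVA behaviour, all at
realistic corpus shapes. What it does not show: real clinical syntax,
misspellings, abbreviation density, reporter-role register differences,
or sub-word tokenizer effects — passing tests here says the machinery is
correct, not that any particular pretrained model fits any particular
hospital's reports.

A 40-report fixture generated at these defaults
(`reports_per_category=10`) is versioned in the package data for fast
deterministic tests; regenerating from `FIXTURE_CONFIG` reproduces it
byte for byte.

## Problem sizes used in the automated checks

The bundled checks run the generator at its default conditions (800
reports), 300 fuzzed cover instances of ≤ 10 reports against the
exhaustive oracle, 1000 fuzzed count tables for the disjointness
property, 40 matched/mismatched trials over 10 generated corpora, and
500/200 ANOVA calibration replicates — sizes at which every property has
comfortable statistical margin while the whole suite runs in seconds.

## Known limitations

* The conditional-probability estimator ignores category prior
  imbalance; only within-category normalization enters the inequality.
* The greedy cover minimizes cardinality only heuristically; the
  exhaustive solver is exponential and capped at 10 reports.
* Independence of sentence-level perplexities within a category is
  assumed by the ANOVA, as is conventional for this design.
* The n-gram reference backend has no backoff or interpolation; it is a
  correctness oracle and discrimination test bed, not a competitive
  language model.
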