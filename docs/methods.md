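# Methods

This note records the models, the default parameters and the reasoning
behind the design choices that were genuinely open, in the order the
pipeline runs them.

## Corpus construction

An export is one CSV row per accession. The configured free-text columns
are merged, in column order, into a single document body; the separator is
a **newline**, which the tokeniser treats as a punctuation token, so the
phrase-detection rule used by negation detection can never join the tail of
one findings section to the head of the next. All remaining columns become
document-level metadata: columns mapped to a role keep the role name,
unmapped columns keep their own name. Empty metadata cells are recorded as
the explicit level `"Not recorded"` rather than dropped — records missing a
sex or age classification are themselves data that the describe stage must
display. Duplicate accession ids abort the load (ids are unique by
construction in a register; silent deduplication would hide an upstream
export fault), and rows with an empty id are rejected.

`write_records` emits the merged body as a single `text` column (the
original section boundaries are not recoverable after merging) plus the
metadata columns; reading that file back with the corresponding mapping
reproduces every document exactly, which the round-trip tests assert.

## Describe

Frequency tables, month/year period tables and two-factor cross-tabs are
straight tallies of the raw levels. **No automatic consolidation of levels
is ever performed** — typographic redundancy is deliberately surfaced, and
merging is left to the user via filters. Ordering is deterministic: count
descending, then level lexicographic (periods chronologically, with
`"Not recorded"` last). Month periods carry the year (`YYYY-MM`) so a
multi-year corpus does not alias its Januaries together.

Filters combine as AND across roles and OR within a role, mirroring a set
of simultaneous drop-down selections; they are applied once at load time
and the filtered corpus is what every later stage consumes. Provenance on
the corpus object records each applied filter, and an empty filter result
is legal — downstream operations raise explicit empty-corpus errors rather
than crash.

## Tokenisation and the document-term matrix

Word tokens are alphanumeric runs with **internal hyphens preserved**
(`plasmodium-like` must exist as one searchable term); slash is punctuation
(`freeze/thaw` is two words), as are `. , ; : ! ? ( )` and newline.
Punctuation tokens are retained, flagged and offset-tracked because the
negation phrase rule needs them. Tokenisation is deterministic and
idempotent on its own surface output.

The default stop list is a bundled snowball-style English list
(overridable via a one-term-per-line file). Stop-word removal applies to
everything the document-term matrix backs — correlations, LDA, TF-IDF —
but **not** to the token streams used for keyword-in-context negation
detection: the cues (`no`, `not`, `nor`) are themselves stop words, and the
canonical negated phrase *no evidence of pneumonia* must survive intact for
the rule to see it. Pure-numeral tokens are likewise excluded from the
matrix vocabulary (they dominate TF-IDF tables without carrying findings)
while remaining visible to context windows; the exclusion is toggleable.
No stemming anywhere: trialled Porter-style stemming reduces clinical and
pathologic vocabulary to unrecognisable fragments, and partial-word
substring search over intact terms recovers variants instead.

## Word correlations

The association statistic is the **phi coefficient** on binary
document-presence indicators — algebraically the Pearson correlation of
the two indicator vectors, which is exactly how the tests oracle-check it.
Terms must occur in at least `min_count` documents (default **5**) to
enter: hapax terms otherwise produce spurious perfect correlations. Only
edges with φ ≥ `min_corr` are returned (the user-facing threshold, the
analogue of the dashboard slider); pairs with a zero marginal (e.g. a term
present in every document) have undefined φ and are skipped. The edge set
is antitone in both thresholds. The emitted network figure uses a seeded
force-directed layout with edge darkness linear in φ over
[`min_corr`, 1], so re-runs are structurally reproducible.

## Latent Dirichlet allocation

Documents are mixtures over k topics; topics are distributions over the
vocabulary; both have symmetric Dirichlet priors. The fit is a **collapsed
Gibbs sampler written in this package** (the inner sweep JIT-compiled with
numba) rather than a delegated library call, so that seeding, per-sweep
token-count conservation and the final assignment state are all directly
testable. Per-sweep uniform variates are drawn in Python from a seeded
PCG64 generator, making the chain bitwise reproducible for a given seed
regardless of compilation details.

Defaults, all CLI-settable and recorded in the run manifest:

| parameter | default | rationale |
|---|---|---|
| α (doc–topic) | 50/k | keeps total prior mass per document constant in k |
| β (topic–word) | 0.1 | mildly sparse topics, standard for small corpora |
| iterations | 1000 | comfortably past burn-in at register scale |
| estimate | last sample | no averaging; matches the exploratory, single-chain use |

Documents left with zero tokens after stop-word removal are excluded with
a warning; k must lie in [2, V]. Estimates are smoothed final-state counts:
φ̂ₜ = (nₜw + β)/(nₜ + Vβ), θ̂d = (ndt + α)/(nd + kα).

The word-cloud structure lists the top-n words per topic by φ̂ and
assigns each vocabulary word to its argmax topic, so every rendered word
has exactly one colour even when it ranks highly under several topics.

Recovery behaviour is validated on planted benchmarks: 200 documents of 50
tokens drawn from k ∈ {2, 3} disjoint theme vocabularies, where the
best-permutation mean cosine between fitted and planted topic-word
distributions exceeds 0.9 (observed ≈ 0.999). These sizes are the
package's benchmark conditions; larger corpora only improve identifiability
of disjoint topics.

## Examine

**TF-IDF.** tf is the raw count divided by the document's filtered token
total; idf is ln(N/nₜ) with no smoothing, so a term in every document
scores exactly zero. This is the plain ratio definition, chosen over the
many weighting variants because the table is a ranking device, not a
feature space. Per document the top `words_per_document` (default **40**)
entries are kept, ties broken lexicographically; the collated table is
sorted by tf·idf descending. A brute-force explicit-loop oracle reproduces
the table to 1e-12 in the tests.

**Search** over the table is case-insensitive substring match at any
position in the term — the replacement for stemming ("an" matches
*anaerobic* and *animal* but also *organism* and *avian*; the user curates
the hits).

**KWIC and negation.** Term matching for recognition is exact on the
normalised token (never substring — variants like *plasmodial* are selected
individually; substring lives only in table search). The context window is
read as up to ten **word tokens on each side** of the hit (the common
keyword-in-context convention; the alternative reading, ten tokens total,
is available by setting `window=5`… the parameter is exposed precisely
because the convention is ambiguous). Tokens are collected outward until
the word budget is filled, keeping punctuation encountered on the way; the
*phrase* is the sub-span between the punctuation tokens nearest the hit,
falling back to the window edge when there is none. A hit is negated iff
any word in its phrase is in the negation lexicon; default cues:

    no not without absent absence free negative non neither nor unremarkable

The list is deliberately small, overridable per run, and recorded in the
manifest. The scope rule is phrase-level, not precedence-ordered, so
pseudo-negations ("not only…") are mis-flagged; this is an accepted
imperfection of rule-based negation on natural text, and the matched-record
export exists exactly so a subject-matter expert can apply a sharper case
definition downstream.

A record is **positive** for a term when at least one occurrence is
non-negated; the findings report accumulates per-term positive-record sets
incrementally and the unique-record total is their union, so a record
matching several terms counts once.

## Synthetic data

The generator emulates the shape of a register export: weighted species
pools with typographic variants (8% by default), age-conditional sex
weights (a plantable demographic skew), 5% missing sex/age, uniform
submission dates over 2019–2021, and free text assembled from three parts —
theme sentences (words drawn uniformly from per-theme vocabularies:
a blood-parasite theme, a freeze–thaw artifact theme, a poor-body-condition
theme), finding sentences from affirm/negation templates, and neutral
filler. Default per-record finding rates: pneumonia 25% affirmed / 15%
negated-only, nephritis 15/10, plasmodium 20/5, hepatitis 10/10; 30% of
positive records additionally carry a negated mention of the same term so
that "one non-negated hit suffices" is exercised. Every template keeps its
cue and term inside one punctuation-bounded phrase, and a self-check pass
at generation time re-detects each planted mention with the package's own
KWIC rule, failing loudly if a template ever drifts out of grammar.

What the generator does **not** emulate — and hence what passing tests do
not show about real registers: misspelled finding terms, negation phrasings
outside the template grammar (scope crossing a clause boundary,
pre-punctuation cues like "pneumonia: none"), uncertainty language
("suspect", "possible"), section headers inside text fields, and
multi-pathologist stylistic drift. Exactness results (sensitivity =
specificity = 1 on synthetic corpora) are properties of the
grammar-conforming construction, not claims about field data.

`topic_benchmark_config` produces the planted-topic corpora: k disjoint
vocabularies, exactly one theme per record, no filler or findings, 50
tokens per record — the cleanest case for recovery testing.

## Numerical and degenerate-input choices

- Phi is computed from exact integer contingency tables in double
  precision; undefined (zero-marginal) values are skipped, not clamped.
- Cross-tab proportions normalise within each frequency level and are
  asserted to sum to 1 ± 1e-9.
- Ties in every ranking (frequency levels, TF-IDF entries, word-cloud
  words) break lexicographically, making all outputs deterministic.
- Empty corpora, empty filter results, terms absent corpus-wide and
  zero-token documents each have a defined behaviour (error, legal empty,
  zero count, exclusion with warning respectively) — never a crash.

## Known limitations

- The negation rule is syntactic and phrase-local; it does not resolve
  scope, handle double negation, or distinguish negation from absence of
  mention.
- Phi on binary presence ignores term frequency and position; it is a
  hypothesis-generating view, not a document-similarity measure.
- LDA topic count k is a user choice by design; no model-selection
  criterion is provided, matching the exploratory intent.
- The CLI is a batch replacement for an interactive dashboard: each panel
  corresponds to a named output file, so a thin UI could be layered on
  without touching the library.
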