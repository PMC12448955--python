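"""Examine stage: TF-IDF keyword retrieval and negation-aware finding counts.

The quantification workflow mirrors a pathologist's close reading.  A
"table of important words" ranks, per record, the terms with the highest
term-frequency × inverse-document-frequency ratio

    tf(t, d) = count(t, d) / tokens(d)        (stop-word-filtered tokens)
    idf(t)   = ln(N / n_t)                    (N documents, n_t contain t)

so a term used heavily in one record but rarely elsewhere surfaces at the
top.  The user picks terms of interest from that table (partial-word search
helps find variants: "plas" → plasmodium, plasmodial, plasmodium-like); a
keyword-in-context pass then decides, occurrence by occurrence, whether the
term is affirmed or negated.  The rule: a "phrase" is the span between the
punctuation marks nearest the hit within a ten-word window, and a negation
cue anywhere in that phrase ("no evidence of pneumonia") negates the hit.
A record counts as positive for a term if at least one occurrence is not
negated; a record positive for several selected terms is counted once in
the unique-record total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import corpus_io
from .corpus_io import Corpus
from .errors import ConfigurationError, EmptyCorpusError
from .text_prep import DocumentTermMatrix, Token, TokenStream, tokenize

#: Default negation cues.  The clinical-note convention ("no evidence of
#: X", "free of X", "X not seen") drives the choice; the list is
#: deliberately small, lowercase, and overridable per report.
DEFAULT_NEGATION_LEXICON: frozenset[str] = frozenset({
    "no", "not", "without", "absent", "absence", "free",
    "negative", "non", "neither", "nor", "unremarkable",
})


@dataclass(frozen=True)
class NegationLexicon:
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigurationError("negation lexicon must not be empty")
        if any(t != t.lower() for t in self.terms):
            raise ConfigurationError("negation cues must be lowercase")

    @classmethod
    def default(cls) -> "NegationLexicon":
        return cls(terms=DEFAULT_NEGATION_LEXICON)

    @classmethod
    def from_file(cls, path) -> "NegationLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(terms=frozenset(
                line.strip().lower() for line in fh if line.strip()
            ))


# ---------------------------------------------------------------------------
# TF-IDF table
# ---------------------------------------------------------------------------

def top_tfidf_table(
    dtm: DocumentTermMatrix, words_per_document: int = 40
) -> pd.DataFrame:
    """Collate the top TF-IDF terms of every document into one table.

    Per document, entries are ranked by tf·idf descending (ties broken by
    term, lexicographic) and the top *words_per_document* kept; the collated
    table is sorted by tf·idf descending.  Columns: ``accession_id, term,
    tf, idf, tfidf``.  Natural log, no smoothing: a term present in every
    document has idf = ln(1) = 0 and never outranks a document-specific one.
    """
    if words_per_document < 1:
        raise ConfigurationError("words_per_document must be >= 1")
    if dtm.n_docs == 0:
        raise EmptyCorpusError("empty corpus")
    counts = dtm.toarray()
    doc_len = counts.sum(axis=1)
    doc_freq = dtm.doc_freq
    rows = []
    for i, doc_id in enumerate(dtm.doc_ids):
        if doc_len[i] == 0:
            continue
        entries = []
        for j in counts[i].nonzero()[0]:
            tf = counts[i, j] / doc_len[i]
            idf = math.log(dtm.n_docs / doc_freq[j])
            entries.append((dtm.vocabulary[j], tf, idf, tf * idf))
        entries.sort(key=lambda e: (-e[3], e[0]))
        for term, tf, idf, tfidf in entries[:words_per_document]:
            rows.append((doc_id, term, tf, idf, tfidf))
    table = pd.DataFrame(rows, columns=["accession_id", "term", "tf", "idf", "tfidf"])
    return table.sort_values(
        ["tfidf", "accession_id", "term"], ascending=[False, True, True]
    ).reset_index(drop=True)


def search_table(table: pd.DataFrame, query: str) -> pd.DataFrame:
    """Case-insensitive substring filter on the ``term`` column.

    Partial matching at any position inside the term stands in for
    stemming: "plas" finds plasmodium, plasmodial and plasmodium-like;
    "an" finds anaerobic and animal but also organism and avian.
    """
    if not query:
        raise ConfigurationError("search query must be non-empty")
    mask = table["term"].str.contains(query.lower(), case=False, regex=False)
    return table[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# keyword in context + negation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KwicHit:
    """One occurrence of a search term with its context window.

    ``window`` spans up to ``window`` word tokens each side of the hit
    (punctuation tokens inside the span retained); ``phrase`` is the
    sub-span bounded by the punctuation nearest the hit, or the window edge
    where there is none; ``negated`` is true iff any word in the phrase is
    a negation cue.
    """

    accession_id: str
    term: str
    token_position: int
    window: tuple[Token, ...]
    phrase: tuple[Token, ...]
    negated: bool

    def phrase_text(self) -> str:
        return " ".join(t.norm for t in self.phrase if not t.is_punct)


def kwic(
    stream: TokenStream,
    term: str,
    window: int = 10,
    lexicon: NegationLexicon | None = None,
) -> list[KwicHit]:
    """All occurrences of *term* with window, phrase bounds and negation flag.

    Matching is exact on the normalised token form (never substring — a
    search for "plasmodium" does not hit "plasmodium-like"; variants are
    selected individually).  The window collects tokens outward from the
    hit until *window* word tokens are gathered on each side, keeping the
    punctuation encountered on the way.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    if lexicon is None:
        lexicon = NegationLexicon.default()
    term = term.lower()
    tokens = stream.tokens
    hits = []
    for pos, token in enumerate(tokens):
        if token.is_punct or token.norm != term:
            continue
        # walk left, then right, until `window` word tokens collected
        start = pos
        words = 0
        while start > 0 and words < window:
            start -= 1
            if not tokens[start].is_punct:
                words += 1
        end = pos
        words = 0
        while end < len(tokens) - 1 and words < window:
            end += 1
            if not tokens[end].is_punct:
                words += 1
        span = tokens[start:end + 1]
        hit_in_span = pos - start
        # phrase: between the punctuation tokens nearest the hit
        p_start = 0
        for i in range(hit_in_span - 1, -1, -1):
            if span[i].is_punct:
                p_start = i + 1
                break
        p_end = len(span)
        for i in range(hit_in_span + 1, len(span)):
            if span[i].is_punct:
                p_end = i
                break
        phrase = span[p_start:p_end]
        negated = any(
            (not t.is_punct) and t.norm in lexicon.terms for t in phrase
        )
        hits.append(
            KwicHit(
                accession_id=stream.accession_id,
                term=term,
                token_position=pos,
                window=tuple(span),
                phrase=tuple(phrase),
                negated=negated,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# positive-record counting
# ---------------------------------------------------------------------------

@dataclass
class FindingsReport:
    """Accumulating per-term positive-record counts with a unique-record set.

    A record is positive for a term when at least one occurrence of that
    term is not negated.  Adding a term extends the report without
    recomputing the earlier ones; the unique-record set is always the union
    of the per-term positive sets, so a record positive for several terms
    is counted once.
    """

    window: int
    lexicon: NegationLexicon
    positive_ids: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.positive_ids)

    @property
    def per_term_counts(self) -> dict[str, int]:
        return {t: len(ids) for t, ids in self.positive_ids.items()}

    @property
    def unique_records(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.positive_ids.values():
            out |= ids
        return frozenset(out)

    def histogram_spec(self) -> list[tuple[str, int]]:
        """Bar per selected term, in selection order — the counts table's twin."""
        return [(t, len(ids)) for t, ids in self.positive_ids.items()]

    def add_term(self, corpus: Corpus, term: str) -> "FindingsReport":
        term = term.lower()
        positives = set()
        for doc in corpus:
            stream = tokenize(doc.text, doc.accession_id)
            if any(
                not h.negated
                for h in kwic(stream, term, window=self.window, lexicon=self.lexicon)
            ):
                positives.add(doc.accession_id)
        self.positive_ids[term] = frozenset(positives)
        return self


def positive_records(
    corpus: Corpus,
    terms: list[str],
    lexicon: NegationLexicon | None = None,
    window: int = 10,
) -> FindingsReport:
    """Count records with at least one non-negated use of each selected term.

    A term absent corpus-wide simply counts zero.  Negation detection runs
    on the raw token streams (stop words intact), since the cues themselves
    are function words.
    """
    if not terms:
        raise ConfigurationError("at least one term must be selected")
    report = FindingsReport(
        window=window,
        lexicon=lexicon if lexicon is not None else NegationLexicon.default(),
    )
    for term in terms:
        report.add_term(corpus, term)
    return report


def export_positive(corpus: Corpus, report: FindingsReport, path) -> int:
    """Write the unique positive records to CSV; returns rows written."""
    return corpus_io.write_records(corpus, report.unique_records, path)
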