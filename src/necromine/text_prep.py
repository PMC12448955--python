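"""Tokenisation, stop-word removal and document-term matrix construction.

These primitives are shared by the exploration stage (word correlations,
topic modelling) and the examination stage (TF-IDF, keyword-in-context).
Two properties matter to the downstream consumers and shape the design:

* Punctuation tokens are first-class and keep their character offsets —
  the negation rule defines a "phrase" as the span between the punctuation
  marks nearest a hit, so throwing punctuation away at tokenisation time
  would destroy the phrase bounds.
* Internal hyphens are preserved within a token, so a compound like
  "plasmodium-like" survives as a single searchable term instead of
  dissolving into its halves.

No stemming is performed anywhere: on clinical and pathologic vocabulary,
Porter-style stemmers produce unrecognisable partial words, and partial-word
(substring) search over the intact terms recovers tense and typographic
variants instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .corpus_io import Corpus
from .errors import EmptyCorpusError
from .stopwords import DEFAULT_STOPWORDS

#: Word tokens: alphanumeric runs, with internal hyphens kept.  Punctuation
#: tokens: sentence punctuation plus slash and newline (a slash separates
#: alternatives like "freeze/thaw", which are distinct words).
_TOKEN_RE = re.compile(r"(?P<word>[^\W_]+(?:-[^\W_]+)*)|(?P<punct>[.,;:!?()/\n])")

_NUMERAL_RE = re.compile(r"[0-9]+(?:[-.,][0-9]+)*")


@dataclass(frozen=True)
class Token:
    surface: str
    norm: str
    is_punct: bool
    offset: int


@dataclass(frozen=True)
class TokenStream:
    """Ordered tokens of one document, punctuation retained and flagged."""

    accession_id: str
    tokens: tuple[Token, ...]

    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if not t.is_punct]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


def tokenize(text: str, accession_id: str = "") -> TokenStream:
    """Split *text* into word and punctuation tokens with offsets.

    Words are lowercased into the normalised form; hyphens internal to a
    word are kept ("plasmodium-like" is one token) while slashes split
    ("freeze/thaw" gives two word tokens and a punctuation token).
    Characters that are neither word material nor sentence punctuation
    (stray dashes, quotes) are skipped.
    """
    tokens = []
    for match in _TOKEN_RE.finditer(text):
        surface = match.group(0)
        tokens.append(
            Token(
                surface=surface,
                norm=surface.lower(),
                is_punct=match.lastgroup == "punct",
                offset=match.start(),
            )
        )
    return TokenStream(accession_id=accession_id, tokens=tuple(tokens))


def remove_stopwords(stream: TokenStream, stoplist=DEFAULT_STOPWORDS) -> TokenStream:
    """Drop word tokens whose normalised form is a stop word.

    Punctuation tokens are untouched; an empty stop list is the identity.
    """
    kept = tuple(
        t for t in stream.tokens if t.is_punct or t.norm not in stoplist
    )
    return TokenStream(accession_id=stream.accession_id, tokens=kept)


def is_numeral(term: str) -> bool:
    return bool(_NUMERAL_RE.fullmatch(term))


@dataclass(frozen=True)
class DocumentTermMatrix:
    """Per-document term counts over a stop-word-filtered vocabulary.

    The vocabulary is lexicographic and excludes stop words, punctuation
    and (by default at build time) pure numerals.  ``doc_freq[t]`` is the
    number of documents containing term ``t`` — the n_t of the TF-IDF
    ratio; ``n_docs`` is its N.
    """

    doc_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    counts: sp.csr_matrix  # n_docs × n_terms, non-negative ints

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)

    @property
    def doc_freq(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def term_index(self, term: str) -> int:
        idx = dict(zip(self.vocabulary, range(len(self.vocabulary))))
        return idx[term]

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()


def build_dtm(
    corpus: Corpus,
    stoplist=DEFAULT_STOPWORDS,
    include_numerals: bool = False,
) -> DocumentTermMatrix:
    """Count normalised, stop-word-filtered word tokens per document.

    Pure-numeral tokens are excluded from the vocabulary by default — they
    dominate TF-IDF tables without carrying findings — but remain available
    to keyword-in-context windows, which re-tokenise the raw text.
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot build a document-term matrix from an empty corpus")
    per_doc: list[dict[str, int]] = []
    vocab: set[str] = set()
    for doc in corpus:
        stream = remove_stopwords(tokenize(doc.text, doc.accession_id), stoplist)
        counts: dict[str, int] = {}
        for token in stream.word_tokens():
            if not include_numerals and is_numeral(token.norm):
                continue
            counts[token.norm] = counts.get(token.norm, 0) + 1
        per_doc.append(counts)
        vocab.update(counts)
    vocabulary = tuple(sorted(vocab))
    index = {term: j for j, term in enumerate(vocabulary)}
    matrix = sp.lil_matrix((len(per_doc), len(vocabulary)), dtype=np.int64)
    for i, counts in enumerate(per_doc):
        for term, n in counts.items():
            matrix[i, index[term]] = n
    return DocumentTermMatrix(
        doc_ids=tuple(corpus.ids()),
        vocabulary=vocabulary,
        counts=matrix.tocsr(),
    )
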