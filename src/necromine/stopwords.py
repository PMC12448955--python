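"""Default English stop-word list.

A snowball-style list of high-frequency function words, shipped so the
statistical stages work out of the box; user-overridable via a one-term-per-
line file.  Note that negation cues ("no", "not", "nor") are stop words —
this is why negation detection operates on unfiltered token streams, not on
the stop-word-filtered matrix (see docs/methods.md).
"""

from __future__ import annotations

DEFAULT_STOPWORDS: frozenset[str] = frozenset("""
i me my myself we our ours ourselves you your yours yourself yourselves
he him his himself she her hers herself it its itself they them their
theirs themselves what which who whom this that these those am is are was
were be been being have has had having do does did doing would should
could ought a an the and but if or because as until while of at by for
with about against between into through during before after above below
to from up down in out on off over under again further then once here
there when where why how all any both each few more most other some such
no nor not only own same so than too very will can just
""".split())


def load_stoplist(path) -> frozenset[str]:
    """Read a stop list: one term per line, UTF-8, blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower() for line in fh if line.strip()
        )
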