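"""Describe stage: signalment summaries and persistent corpus filtering.

Frequency tables and two-factor cross-tabulations are computed on the raw
metadata levels, deliberately without consolidating typographic variants or
near-duplicate levels: redundancy in recording (two spellings of the same
species, sexes entered as both "unknown" and "indeterminate") is itself a
finding about the register, and automatic merging would bias downstream
views.  Consolidation is left to the user via filters.

Filters applied here are meant to persist: downstream stages operate on the
filtered corpus, and the corpus provenance records every filter applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

from .corpus_io import MISSING, Corpus
from .errors import ConfigurationError, UnknownVariableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-level counts of one metadata variable, count-descending."""

    variable: str
    rows: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.rows)

    def total(self) -> int:
        return sum(count for _, count in self.rows)


@dataclass(frozen=True)
class CrossTab:
    """Two-factor table: counts and within-bar proportions.

    ``freq_variable`` drives the bar heights; ``prop_variable`` is shown as
    proportions within each bar.  ``cells`` holds
    ``(freq_level, prop_level, count, proportion_within_freq_level)``.
    """

    freq_variable: str
    prop_variable: str
    cells: tuple[tuple[str, str, int, float], ...]

    def total(self) -> int:
        return sum(c for _, _, c, _ in self.cells)


@dataclass(frozen=True)
class FilterSpec:
    """Retained levels per metadata role; AND across roles, OR within one."""

    clauses: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for role, levels in self.clauses.items():
            levels = frozenset(levels)
            if not levels:
                raise ConfigurationError(f"empty retained set for role {role!r}")
            clean[role] = levels
        object.__setattr__(self, "clauses", clean)

    def matches(self, metadata: dict[str, str]) -> bool:
        return all(metadata[role] in levels for role, levels in self.clauses.items())

    def describe(self) -> str:
        parts = [
            f"{role}∈{{{', '.join(sorted(levels))}}}"
            for role, levels in sorted(self.clauses.items())
        ]
        return " AND ".join(parts)


def _require_role(corpus: Corpus, variable: str) -> None:
    roles = corpus.metadata_roles()
    if variable not in roles:
        raise UnknownVariableError(
            f"unknown metadata variable {variable!r}; available: {', '.join(roles)}"
        )


def frequency_table(corpus: Corpus, variable: str) -> FrequencyTable:
    """Tally the raw levels of *variable*, count-descending then lexicographic."""
    _require_role(corpus, variable)
    counts: dict[str, int] = {}
    for doc in corpus:
        level = doc.metadata[variable]
        counts[level] = counts.get(level, 0) + 1
    rows = sorted(counts.items(), key=lambda lc: (-lc[1], lc[0]))
    return FrequencyTable(variable=variable, rows=tuple(rows))


def extract_period(date_value: str, granularity: str, format: str = "%Y-%m-%d") -> str:
    """Reduce a submission-date string to a month ("YYYY-MM") or year ("YYYY") label.

    Month labels keep the year so multi-year corpora do not alias the same
    calendar month.  The missing sentinel passes through; an unparseable
    value is logged and binned as missing rather than aborting the run.
    """
    if granularity not in ("month", "year"):
        raise ValueError(f"granularity must be 'month' or 'year', got {granularity!r}")
    if date_value == MISSING or not date_value.strip():
        return MISSING
    try:
        parsed = datetime.strptime(date_value.strip(), format)
    except ValueError:
        logger.warning(
            "unparseable submission date %r (format %r); recorded as %r",
            date_value, format, MISSING,
        )
        return MISSING
    return f"{parsed.year:04d}" if granularity == "year" else f"{parsed.year:04d}-{parsed.month:02d}"


def period_table(
    corpus: Corpus,
    granularity: str,
    variable: str = "submission_date",
    format: str | None = None,
) -> FrequencyTable:
    """Frequency of submissions per month or year, chronological order."""
    _require_role(corpus, variable)
    if format is None:
        format = corpus.provenance.mapping.date_format
    counts: dict[str, int] = {}
    for doc in corpus:
        label = extract_period(doc.metadata[variable], granularity, format)
        counts[label] = counts.get(label, 0) + 1
    # "Not recorded" sorts after the date labels
    rows = sorted(counts.items(), key=lambda lc: (lc[0] == MISSING, lc[0]))
    return FrequencyTable(variable=f"{variable}:{granularity}", rows=tuple(rows))


def cross_tab(corpus: Corpus, freq_variable: str, prop_variable: str) -> CrossTab:
    """Two-way contingency tally with proportions normalised per freq level."""
    if freq_variable == prop_variable:
        raise ConfigurationError("cross_tab needs two distinct variables")
    _require_role(corpus, freq_variable)
    _require_role(corpus, prop_variable)
    counts: dict[tuple[str, str], int] = {}
    freq_totals: dict[str, int] = {}
    for doc in corpus:
        pair = (doc.metadata[freq_variable], doc.metadata[prop_variable])
        counts[pair] = counts.get(pair, 0) + 1
        freq_totals[pair[0]] = freq_totals.get(pair[0], 0) + 1
    cells = [
        (f, p, n, n / freq_totals[f])
        for (f, p), n in sorted(counts.items())
    ]
    return CrossTab(
        freq_variable=freq_variable,
        prop_variable=prop_variable,
        cells=tuple(cells),
    )


def apply_filter(corpus: Corpus, spec: FilterSpec) -> Corpus:
    """Retain documents matching every clause; provenance records the filter.

    Document order is preserved (the result is a subsequence of the input).
    An empty result is legal — downstream operations raise their own
    empty-corpus errors.
    """
    roles = set(corpus.metadata_roles())
    unknown = set(spec.clauses) - roles
    if unknown:
        raise UnknownVariableError(
            f"filter on unknown role(s): {', '.join(sorted(unknown))}"
        )
    retained = tuple(doc for doc in corpus if spec.matches(doc.metadata))
    return Corpus(
        documents=retained,
        provenance=corpus.provenance.with_filter(spec.describe()),
        roles=tuple(corpus.metadata_roles()),
    )
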