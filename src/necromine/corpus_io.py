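"""Reading and writing necropsy-record CSV exports.

A pathology-register export carries one row per accession: a unique
accession number, several free-text findings sections (gross pathology,
histopathology, ancillary diagnostics, diagnoses, ...) and structured
signalment columns (species, sex, age classification, submission date).
Loading merges the free-text sections into a single document body per
accession and keeps every other column as document-level metadata, so the
downstream stages see a corpus of ``(id, text, metadata)`` triples.

Because register schemas differ between installations, the column layout is
supplied as a :class:`ColumnMapping` rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .errors import ConfigurationError, CorpusLoadError

#: Level recorded for metadata cells that are empty in the export.  Missing
#: values are data here (e.g. records with no sex classification entered),
#: so they are kept as an explicit level instead of being dropped.
MISSING = "Not recorded"

#: Separator used when merging the free-text sections of one accession.
#: A newline is itself a punctuation token downstream, so phrase detection
#: never bridges two sections accidentally.
SECTION_SEPARATOR = "\n"


@dataclass(frozen=True)
class ColumnMapping:
    """Maps the roles the pipeline needs onto the columns of one export.

    Parameters
    ----------
    id_column:
        Column holding the unique accession number.
    text_columns:
        Ordered free-text findings columns; their contents are merged, in
        this order, into the document body.
    metadata_columns:
        Role name (``species``, ``sex``, ``age_class``, ``submission_date``,
        ...) to column name.  Columns not mentioned anywhere are still kept
        as metadata under their own column name.
    date_format:
        :func:`~datetime.datetime.strptime` pattern for submission dates.
    """

    id_column: str
    text_columns: tuple[str, ...]
    metadata_columns: dict[str, str] = field(default_factory=dict)
    date_format: str = "%Y-%m-%d"

    def __post_init__(self) -> None:
        if not self.text_columns:
            raise ConfigurationError("text_columns must not be empty")
        object.__setattr__(self, "text_columns", tuple(self.text_columns))
        mapped = list(self.metadata_columns.values())
        groups = [self.id_column, *self.text_columns, *mapped]
        if len(set(groups)) != len(groups):
            raise ConfigurationError(
                "id_column, text_columns and metadata_columns must be disjoint"
            )

    def validate_header(self, header: list[str]) -> None:
        """Raise :class:`ConfigurationError` naming any mapped column absent
        from *header*."""
        wanted = [self.id_column, *self.text_columns, *self.metadata_columns.values()]
        missing = [c for c in wanted if c not in header]
        if missing:
            raise ConfigurationError(
                f"mapped column(s) not in file header: {', '.join(sorted(missing))}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                id_column=raw["id_column"],
                text_columns=tuple(raw["text_columns"]),
                metadata_columns=dict(raw.get("metadata_columns", {})),
                date_format=raw.get("date_format", "%Y-%m-%d"),
            )
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise ConfigurationError(f"mapping file missing key: {exc}") from exc


#: Mapping matching the synthetic generator's schema; serves as the default
#: for the command-line interface.
DEFAULT_MAPPING = ColumnMapping(
    id_column="accession",
    text_columns=("gross_pathology", "histopathology", "ancillary_diagnostics"),
    metadata_columns={
        "species": "species",
        "sex": "sex",
        "age_class": "age_class",
        "submission_date": "submission_date",
    },
)


@dataclass(frozen=True)
class NecropsyDocument:
    """One accession: merged free-text body plus document-level metadata."""

    accession_id: str
    text: str
    metadata: dict[str, str]


@dataclass(frozen=True)
class Provenance:
    """Where a corpus came from and which filters produced it."""

    source: str
    mapping: ColumnMapping
    filters: tuple[str, ...] = ()

    def with_filter(self, description: str) -> "Provenance":
        return replace(self, filters=self.filters + (description,))


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of necropsy documents with shared metadata roles."""

    documents: tuple[NecropsyDocument, ...]
    provenance: Provenance
    #: metadata roles, kept explicitly so an empty (filtered-out) corpus
    #: still knows its schema; derived from the documents when omitted
    roles: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def ids(self) -> list[str]:
        return [d.accession_id for d in self.documents]

    def metadata_roles(self) -> list[str]:
        if self.roles:
            return list(self.roles)
        if not self.documents:
            return []
        return list(self.documents[0].metadata)

    def get(self, accession_id: str) -> NecropsyDocument:
        for doc in self.documents:
            if doc.accession_id == accession_id:
                return doc
        raise KeyError(accession_id)


def read_export(path, mapping: ColumnMapping) -> Corpus:
    """Load a register CSV export into a :class:`Corpus`.

    One document is produced per data row; the configured text columns are
    joined in order with :data:`SECTION_SEPARATOR`; every non-id, non-text
    column is kept as metadata (mapped columns under their role name,
    unmapped ones under the column name).  Empty metadata cells become the
    :data:`MISSING` level.  Rows with an empty accession id are rejected.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CorpusLoadError(f"could not parse {path}: {exc}") from exc
    mapping.validate_header(list(frame.columns))

    column_roles: list[tuple[str, str]] = []  # (role, column)
    reverse = {col: role for role, col in mapping.metadata_columns.items()}
    for col in frame.columns:
        if col == mapping.id_column or col in mapping.text_columns:
            continue
        column_roles.append((reverse.get(col, col), col))

    ids = frame[mapping.id_column].str.strip()
    kept = ids != ""
    dup = ids[kept][ids[kept].duplicated()].unique()
    if len(dup):
        raise CorpusLoadError(
            f"duplicate accession id(s): {', '.join(sorted(dup))}"
        )

    documents = []
    for _, row in frame[kept].iterrows():
        text = SECTION_SEPARATOR.join(row[c] for c in mapping.text_columns)
        metadata = {
            role: (row[col].strip() or MISSING) for role, col in column_roles
        }
        documents.append(
            NecropsyDocument(
                accession_id=row[mapping.id_column].strip(),
                text=text,
                metadata=metadata,
            )
        )
    return Corpus(
        documents=tuple(documents),
        provenance=Provenance(source=str(path), mapping=mapping),
        roles=tuple(role for role, _ in column_roles),
    )


def export_mapping(corpus: Corpus) -> ColumnMapping:
    """Mapping under which :func:`write_records` output re-loads identically."""
    source_mapping = corpus.provenance.mapping
    return ColumnMapping(
        id_column=source_mapping.id_column,
        text_columns=("text",),
        metadata_columns={role: role for role in corpus.metadata_roles()},
        date_format=source_mapping.date_format,
    )


def write_records(corpus: Corpus, ids, path) -> int:
    """Write the selected accessions back out as CSV; returns rows written.

    The merged text sections are written as a single ``text`` column (the
    original section boundaries are not recoverable after merging); metadata
    columns are reconstituted under their role names.  Reading the file back
    with :func:`export_mapping` reproduces the documents exactly.
    """
    ids = set(ids)
    known = set(corpus.ids())
    unknown = ids - known
    if unknown:
        raise KeyError(
            f"unknown accession id(s): {', '.join(sorted(unknown))}"
        )
    roles = corpus.metadata_roles()
    id_column = corpus.provenance.mapping.id_column
    rows = [
        {id_column: d.accession_id, "text": d.text, **d.metadata}
        for d in corpus.documents
        if d.accession_id in ids
    ]
    frame = pd.DataFrame(rows, columns=[id_column, "text", *roles])
    frame.to_csv(path, index=False, encoding="utf-8")
    return len(rows)
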