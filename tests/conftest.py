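"""Shared fixtures: in-memory corpora, synthetic register exports, random
document-term matrices for oracle checks."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from necromine.corpus_io import (
    ColumnMapping, Corpus, NecropsyDocument, Provenance, read_export,
)
from necromine.synthetic_data import GeneratorConfig, generate
from necromine.text_prep import DocumentTermMatrix

GENERATOR_MAPPING = ColumnMapping(
    id_column="accession",
    text_columns=("gross_pathology", "histopathology", "ancillary_diagnostics"),
    metadata_columns={
        "species": "species",
        "sex": "sex",
        "age_class": "age_class",
        "submission_date": "submission_date",
    },
)


def make_corpus(rows, mapping: ColumnMapping = GENERATOR_MAPPING) -> Corpus:
    """Build a corpus directly from (id, text, metadata) triples."""
    return Corpus(
        documents=tuple(
            NecropsyDocument(accession_id=i, text=t, metadata=dict(m))
            for i, t, m in rows
        ),
        provenance=Provenance(source="memory", mapping=mapping),
    )


def random_dtm(rng: np.random.Generator, n_docs: int, n_terms: int,
               binary: bool = False, density: float = 0.3) -> DocumentTermMatrix:
    """Random count matrix with a lexicographic synthetic vocabulary."""
    counts = (rng.random((n_docs, n_terms)) < density).astype(np.int64)
    if not binary:
        counts *= rng.integers(1, 5, size=(n_docs, n_terms))
    return DocumentTermMatrix(
        doc_ids=tuple(f"D{i:03d}" for i in range(n_docs)),
        vocabulary=tuple(f"t{j:04d}" for j in range(n_terms)),
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def default_mapping() -> ColumnMapping:
    return GENERATOR_MAPPING


@pytest.fixture(scope="session")
def synth_export(tmp_path_factory):
    """A 120-record synthetic export with its ground truth and loaded corpus."""
    out = tmp_path_factory.mktemp("synth")
    csv_path = out / "records.csv"
    truth_path = out / "truth.json"
    config = GeneratorConfig(n_records=120, seed=7)
    frame, truth = generate(config, csv_path=csv_path, truth_path=truth_path)
    corpus = read_export(csv_path, GENERATOR_MAPPING)
    return {
        "config": config, "frame": frame, "truth": truth,
        "csv_path": csv_path, "truth_path": truth_path, "corpus": corpus,
    }


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Four hand-written records exercising negation, themes and variants."""
    return make_corpus([
        ("A1", "No evidence of pneumonia.\nLiver pale.",
         {"species": "Tui", "sex": "Male", "age_class": "Adult",
          "submission_date": "2019-07-14"}),
        ("A2", "Severe pneumonia. No nephritis.\nSpleen enlarged.",
         {"species": "Tui", "sex": "Male", "age_class": "Juvenile",
          "submission_date": "2019-08-02"}),
        ("A3", "Plasmodium-like organisms seen.\nFreeze/thaw artifact present.",
         {"species": "Kereru", "sex": "Female", "age_class": "Adult",
          "submission_date": "2020-01-20"}),
        ("A4", "Poor body condition.\nMarked emaciation.",
         {"species": "kereru", "sex": "Not recorded", "age_class": "Adult",
          "submission_date": "2020-02-11"}),
    ])
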