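"""TF-IDF table, partial-word search, KWIC negation, positive-record counts."""

import math
import inspect

import numpy as np
import pytest

from necromine.errors import ConfigurationError
from necromine.examine import (
    NegationLexicon, export_positive, kwic, positive_records, search_table,
    top_tfidf_table,
)
from necromine.corpus_io import export_mapping, read_export
from necromine.synthetic_data import truth_report
from necromine.text_prep import build_dtm, tokenize

from conftest import make_corpus, random_dtm


def brute_force_tfidf(dtm, words_per_document):
    """Independent oracle: explicit loops over the count matrix."""
    counts = dtm.toarray()
    n_docs = counts.shape[0]
    doc_freq = [(counts[:, j] > 0).sum() for j in range(counts.shape[1])]
    rows = []
    for i in range(n_docs):
        total = counts[i].sum()
        if total == 0:
            continue
        entries = []
        for j in range(counts.shape[1]):
            if counts[i, j] == 0:
                continue
            tf = counts[i, j] / total
            idf = math.log(n_docs / doc_freq[j])
            entries.append((dtm.vocabulary[j], tf, idf, tf * idf))
        entries.sort(key=lambda e: (-e[3], e[0]))
        rows.extend((dtm.doc_ids[i], *e) for e in entries[:words_per_document])
    return rows


class TestTopTfidfTable:
    def test_hand_example(self):
        corpus = make_corpus([
            ("d1", "plasmodium liver liver", {}), ("d2", "liver firm", {}),
        ])
        table = top_tfidf_table(build_dtm(corpus))
        by_key = {(r.accession_id, r.term): r.tfidf for r in table.itertuples()}
        assert by_key[("d1", "plasmodium")] == \
            pytest.approx((1 / 3) * math.log(2), abs=1e-12)
        assert by_key[("d1", "liver")] == 0.0
        assert by_key[("d2", "liver")] == 0.0
        assert by_key[("d2", "firm")] == pytest.approx(0.5 * math.log(2))

    def test_ubiquitous_term_never_outranks_specific_ones(self, synth_export):
        dtm = build_dtm(synth_export["corpus"])
        table = top_tfidf_table(dtm)
        everywhere = [t for t, n in zip(dtm.vocabulary, dtm.doc_freq)
                      if n == dtm.n_docs]
        zero_rows = table[table.term.isin(everywhere)]
        assert (zero_rows.tfidf == 0.0).all()
        assert (table.tfidf.values[:-1] >= table.tfidf.values[1:] - 1e-15).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            dtm = random_dtm(rng, n_docs=8, n_terms=40)
            table = top_tfidf_table(dtm, words_per_document=15)
            expected = brute_force_tfidf(dtm, 15)
            got = [(r.accession_id, r.term, r.tf, r.idf, r.tfidf)
                   for r in table.itertuples()]
            assert len(got) == len(expected)
            for row in expected:
                match = [g for g in got if g[:2] == row[:2]]
                assert len(match) == 1
                assert match[0][2:] == pytest.approx(row[2:], abs=1e-12)

    def test_shrinking_slider_preserves_ranking_prefix(self, synth_export):
        dtm = build_dtm(synth_export["corpus"])
        wide = top_tfidf_table(dtm, words_per_document=40)
        narrow = top_tfidf_table(dtm, words_per_document=10)
        for doc_id in dtm.doc_ids:
            wide_terms = wide[wide.accession_id == doc_id].term.tolist()
            narrow_terms = narrow[narrow.accession_id == doc_id].term.tolist()
            assert len(narrow_terms) <= 10
            assert narrow_terms == wide_terms[:len(narrow_terms)]

    def test_default_keeps_forty_words_per_document(self):
        signature = inspect.signature(top_tfidf_table)
        assert signature.parameters["words_per_document"].default == 40


class TestSearchTable:
    @pytest.fixture
    def table(self):
        corpus = make_corpus([
            ("d1", "plasmodium plasmodial plasmodium-like malaria", {}),
            ("d2", "anaerobic animal organism avian pneumonia", {}),
        ])
        return top_tfidf_table(build_dtm(corpus))

    def test_partial_match_finds_all_variants(self, table):
        assert set(search_table(table, "plas").term) == \
            {"plasmodium", "plasmodial", "plasmodium-like"}

    def test_match_at_any_position_in_term(self, table):
        assert set(search_table(table, "an").term) == \
            {"anaerobic", "animal", "organism", "avian"}

    def test_case_insensitive_self_match(self, table):
        assert "malaria" in set(search_table(table, "MALARIA").term)

    def test_no_match_is_empty_not_error(self, table):
        assert len(search_table(table, "zzz")) == 0

    def test_empty_query_rejected(self, table):
        with pytest.raises(ConfigurationError):
            search_table(table, "")


class TestKwic:
    def test_negated_phrase(self):
        hits = kwic(tokenize("No evidence of pneumonia.", "a"), "pneumonia")
        assert len(hits) == 1
        assert hits[0].phrase_text() == "no evidence of pneumonia"
        assert hits[0].negated

    def test_punctuation_bounds_exclude_following_negation(self):
        hits = kwic(tokenize("Severe pneumonia. No nephritis.", "a"), "pneumonia")
        assert len(hits) == 1
        assert hits[0].phrase_text() == "severe pneumonia"
        assert not hits[0].negated

    def test_absent_term_gives_no_hits(self):
        assert kwic(tokenize("Severe hepatitis.", "a"), "pneumonia") == []

    def test_exact_token_match_not_substring(self):
        hits = kwic(tokenize("plasmodium-like organisms", "a"), "plasmodium")
        assert hits == []

    def test_unpunctuated_text_phrase_degrades_to_window(self):
        text = " ".join(["w"] * 5 + ["target"] + ["w"] * 5)
        hits = kwic(tokenize(text, "a"), "target", window=50)
        assert len(hits) == 1
        assert hits[0].phrase == hits[0].window
        assert len(hits[0].window) == 11

    def test_window_limits_word_tokens_each_side(self):
        text = " ".join([f"l{i}" for i in range(15)] + ["target"]
                        + [f"r{i}" for i in range(15)])
        hits = kwic(tokenize(text, "a"), "target", window=10)
        words = [t for t in hits[0].window if not t.is_punct]
        assert len(words) == 21  # 10 each side plus the hit

    def test_hit_inside_phrase_inside_window(self, synth_export):
        for doc in list(synth_export["corpus"])[:20]:
            stream = tokenize(doc.text, doc.accession_id)
            for term in ("pneumonia", "plasmodium"):
                for hit in kwic(stream, term):
                    assert hit.term in [t.norm for t in hit.phrase]
                    window = list(hit.window)
                    start = window.index(hit.phrase[0])
                    assert tuple(window[start:start + len(hit.phrase)]) == hit.phrase


class TestPositiveRecords:
    def test_record_with_only_negated_mention_not_counted(self):
        corpus = make_corpus([("r1", "No evidence of pneumonia.", {})])
        report = positive_records(corpus, ["pneumonia"])
        assert report.per_term_counts == {"pneumonia": 0}
        assert report.unique_records == frozenset()

    def test_one_non_negated_hit_suffices(self):
        corpus = make_corpus([
            ("r1", "No nephritis seen. Severe pneumonia throughout.", {}),
        ])
        report = positive_records(corpus, ["pneumonia", "nephritis"])
        assert report.per_term_counts == {"pneumonia": 1, "nephritis": 0}

    def test_absent_term_counts_zero_not_error(self, tiny_corpus):
        report = positive_records(tiny_corpus, ["aspergillosis"])
        assert report.per_term_counts == {"aspergillosis": 0}

    def test_counts_match_generator_truth_exactly(self, synth_export):
        corpus, truth = synth_export["corpus"], synth_export["truth"]
        terms = sorted(synth_export["config"].findings)
        report = positive_records(corpus, terms)
        expected = truth_report(truth, terms)
        assert report.per_term_counts == expected["per_term"]
        assert len(report.unique_records) == expected["unique_records"]
        for term in terms:
            assert report.positive_ids[term] == truth.positive_ids(term)

    def test_unique_records_is_union_and_monotone(self, synth_export):
        corpus = synth_export["corpus"]
        terms = sorted(synth_export["config"].findings)
        report = positive_records(corpus, [terms[0]])
        previous = set()
        for term in terms[1:]:
            report.add_term(corpus, term)
            union = set().union(*report.positive_ids.values())
            assert report.unique_records == union
            assert len(report.unique_records) >= len(previous)
            assert len(report.unique_records) <= \
                sum(report.per_term_counts.values())
            previous = report.unique_records

    def test_empty_term_list_rejected(self, tiny_corpus):
        with pytest.raises(ConfigurationError):
            positive_records(tiny_corpus, [])

    def test_custom_lexicon(self):
        corpus = make_corpus([("r1", "pneumonia ruledout entirely.", {})])
        default = positive_records(corpus, ["pneumonia"])
        custom = positive_records(
            corpus, ["pneumonia"],
            lexicon=NegationLexicon(terms=frozenset({"ruledout"})),
        )
        assert default.per_term_counts["pneumonia"] == 1
        assert custom.per_term_counts["pneumonia"] == 0


class TestExportPositive:
    def test_no_positives_writes_zero_rows(self, tmp_path):
        corpus = make_corpus([("r1", "No evidence of pneumonia.", {})])
        report = positive_records(corpus, ["pneumonia"])
        assert export_positive(corpus, report, tmp_path / "out.csv") == 0

    def test_reanalysing_export_reproduces_counts(self, synth_export, tmp_path):
        corpus = synth_export["corpus"]
        terms = sorted(synth_export["config"].findings)
        report = positive_records(corpus, terms)
        out = tmp_path / "matched.csv"
        written = export_positive(corpus, report, out)
        assert written == len(report.unique_records)
        back = read_export(out, export_mapping(corpus))
        report2 = positive_records(back, terms)
        assert report2.per_term_counts == report.per_term_counts
        assert report2.unique_records == report.unique_records
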