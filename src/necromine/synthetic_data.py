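"""Seeded generator of register-shaped necropsy CSVs with known ground truth.

Real necropsy exports are semi-structured and messy: drop-down signalment
fields accumulate typographic variants over the years, optional fields are
left blank, and the findings sections are free text in which the same
condition may be affirmed in one record and explicitly ruled out in the
next.  This module emits synthetic corpora with exactly those features —
weighted species pools with variant spellings, missing-value rates, dated
submissions, theme vocabularies that colour the free text, and finding
terms planted as affirmed or negated mentions — together with a machine-
readable ground truth, so every downstream stage can be tested against
known answers without touching any real record.

The negation templates are constructed to conform to the phrase grammar the
examination stage assumes (cue and finding inside one punctuation-bounded
phrase within the context window); a self-check pass at generation time
re-detects every planted mention and fails loudly if a template drifts out
of grammar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import examine
from .corpus_io import MISSING
from .errors import ConfigurationError

__all__ = [
    "Theme", "FindingSpec", "GeneratorConfig", "RecordTruth", "GroundTruth",
    "generate", "truth_report", "topic_benchmark_config",
    "true_topic_distributions", "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class Theme:
    """A recurring concept: a vocabulary that co-occurs within records."""

    name: str
    vocabulary: tuple[str, ...]
    inclusion_prob: float


@dataclass(frozen=True)
class FindingSpec:
    """Rates at which a clinicopathologic term is planted per record.

    ``positive_rate``: affirmed at least once; ``negated_rate``: mentioned
    only under negation; the remainder of the probability mass leaves the
    term absent.  ``mixed_rate`` is the chance a *positive* record carries
    an additional negated mention of the same term (one non-negated use
    must still suffice for detection).
    """

    positive_rate: float
    negated_rate: float
    mixed_rate: float = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    n_records: int = 200
    #: (canonical name, sampling weight, typographic variants)
    species: tuple[tuple[str, float, tuple[str, ...]], ...] = (
        ("Little Blue Penguin", 0.20, ("Little blue penguin",)),
        ("Fiordland Crested Penguin", 0.15,
         ("Fiordland crested penguin", "Fiordland Crested penguin")),
        ("North Island Brown Kiwi", 0.25, ("NI Brown Kiwi",)),
        ("Kereru", 0.15, ("kereru",)),
        ("Tui", 0.25, ("tui",)),
    )
    typo_variant_rate: float = 0.08
    age_classes: tuple[tuple[str, float], ...] = (
        ("Adult", 0.60), ("Juvenile", 0.25), ("Subadult", 0.15),
    )
    #: conditional sex weights per age class (a plantable age×sex skew)
    sex_by_age: dict[str, tuple[tuple[str, float], ...]] = field(
        default_factory=lambda: {
            "Adult": (("Male", 0.50), ("Female", 0.40), ("Unknown", 0.10)),
            "Juvenile": (("Male", 0.25), ("Female", 0.65), ("Unknown", 0.10)),
            "Subadult": (("Male", 0.25), ("Female", 0.65), ("Unknown", 0.10)),
        }
    )
    missing_sex_rate: float = 0.05
    missing_age_rate: float = 0.05
    date_start: str = "2019-01-01"
    date_end: str = "2021-12-31"
    themes: tuple[Theme, ...] = (
        Theme("avian_malaria", (
            "schizonts", "erythrocytes", "haemosiderin", "kupffer", "spleen",
            "pigment", "parasitaemia", "merozoites", "splenomegaly", "blood",
        ), 0.35),
        Theme("freeze_thaw", (
            "freeze", "thaw", "artifact", "autolysis", "ice", "crystal",
            "frozen", "storage",
        ), 0.30),
        Theme("body_condition", (
            "poor", "body", "condition", "emaciation", "pectoral", "muscle",
            "atrophy", "keel", "fat", "stores",
        ), 0.40),
    )
    #: exactly one theme per record (for topic-recovery benchmarks) instead
    #: of independent inclusion
    exclusive_themes: bool = False
    theme_sentences_per_record: int = 2
    theme_sentence_length: int = 6
    findings: dict[str, FindingSpec] = field(
        default_factory=lambda: {
            "pneumonia": FindingSpec(0.25, 0.15),
            "nephritis": FindingSpec(0.15, 0.10),
            "plasmodium": FindingSpec(0.20, 0.05),
            "hepatitis": FindingSpec(0.10, 0.10),
        }
    )
    negation_templates: tuple[str, ...] = (
        "No evidence of {term}.",
        "No {term} seen.",
        "{term} not detected.",
        "Negative for {term}.",
        "Without evidence of {term}.",
    )
    affirm_templates: tuple[str, ...] = (
        "Severe {term} present.",
        "Evidence of {term} observed.",
        "Marked {term} in multiple sections.",
        "Moderate {term} identified.",
    )
    filler_sentences: tuple[str, ...] = (
        "Carcass in fair postmortem state.",
        "Tissues examined microscopically.",
        "Sections of liver kidney and lung reviewed.",
        "Standard necropsy protocol followed.",
        "Samples collected for further testing.",
    )
    ancillary_blank_rate: float = 0.5
    kwic_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [
            self.typo_variant_rate, self.missing_sex_rate,
            self.missing_age_rate, self.ancillary_blank_rate,
        ]
        rates += [p for _, p, _ in self.species]
        rates += [t.inclusion_prob for t in self.themes]
        for spec in self.findings.values():
            rates += [spec.positive_rate, spec.negated_rate, spec.mixed_rate]
            if spec.positive_rate + spec.negated_rate > 1.0:
                raise ConfigurationError(
                    "positive_rate + negated_rate must not exceed 1"
                )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigurationError("all probabilities must lie in [0, 1]")


DEFAULT_CONFIG = GeneratorConfig()


@dataclass(frozen=True)
class RecordTruth:
    """What was actually planted in one record.

    ``metadata`` holds the emitted values (typo variants included, blanks
    as the missing sentinel) — the levels the describe stage will see;
    ``canonical`` holds the pre-typo, pre-missing levels.
    """

    accession: str
    metadata: dict[str, str]
    canonical: dict[str, str]
    themes: tuple[str, ...]
    findings: dict[str, str]  # term -> positive | negated-only | absent


@dataclass(frozen=True)
class GroundTruth:
    records: tuple[RecordTruth, ...]

    def frequency(self, variable: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            level = rec.metadata[variable]
            counts[level] = counts.get(level, 0) + 1
        return counts

    def cross_counts(self, var_a: str, var_b: str) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for rec in self.records:
            key = (rec.metadata[var_a], rec.metadata[var_b])
            counts[key] = counts.get(key, 0) + 1
        return counts

    def positive_ids(self, term: str) -> frozenset[str]:
        return frozenset(
            r.accession for r in self.records if r.findings.get(term) == "positive"
        )

    def to_json(self, path) -> None:
        payload = [asdict(rec) for rec in self.records]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(records=tuple(
            RecordTruth(
                accession=r["accession"],
                metadata=dict(r["metadata"]),
                canonical=dict(r["canonical"]),
                themes=tuple(r["themes"]),
                findings=dict(r["findings"]),
            )
            for r in payload
        ))


def truth_report(truth: GroundTruth, terms) -> dict:
    """Expected per-term positive counts and unique-record count.

    Accepts one term or a list.  Raises on a term no record was labelled
    for (i.e. absent from the generator's finding config).
    """
    if isinstance(terms, str):
        terms = [terms]
    known = set()
    for rec in truth.records:
        known.update(rec.findings)
    unknown = [t for t in terms if t not in known]
    if unknown:
        raise KeyError(f"term(s) not in generator config: {', '.join(unknown)}")
    per_term = {t: len(truth.positive_ids(t)) for t in terms}
    unique = frozenset().union(*(truth.positive_ids(t) for t in terms))
    return {"per_term": per_term, "unique_records": len(unique)}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _weighted(rng: np.random.Generator, pairs):
    labels = [p[0] for p in pairs]
    weights = np.array([p[1] for p in pairs], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _theme_sentence(rng: np.random.Generator, theme: Theme, length: int) -> str:
    words = rng.choice(len(theme.vocabulary), size=length, replace=True)
    return " ".join(theme.vocabulary[i] for i in words) + "."


def _self_check(accession: str, text: str, findings: dict[str, str], window: int) -> None:
    """Re-detect every planted mention; fail if a template broke the grammar."""
    stream = examine.tokenize(text, accession)
    lexicon = examine.NegationLexicon.default()
    for term, status in findings.items():
        hits = examine.kwic(stream, term, window=window, lexicon=lexicon)
        detected_positive = any(not h.negated for h in hits)
        if status == "positive" and not detected_positive:
            raise ConfigurationError(
                f"{accession}: planted positive {term!r} not detected — "
                "affirm template violates the phrase grammar"
            )
        if status == "negated-only" and (detected_positive or not hits):
            raise ConfigurationError(
                f"{accession}: planted negated-only {term!r} mis-detected — "
                "negation template violates the phrase grammar"
            )
        if status == "absent" and hits:
            raise ConfigurationError(
                f"{accession}: term {term!r} leaked into text marked absent"
            )


def generate(
    config: GeneratorConfig = DEFAULT_CONFIG,
    csv_path=None,
    truth_path=None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a synthetic register export and its ground truth.

    Deterministic given the seed (``config.seed`` unless overridden): the
    same seed produces a byte-identical CSV.  If *csv_path* / *truth_path*
    are given the table and truth sidecar are written there as well.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    start = date.fromisoformat(config.date_start)
    end = date.fromisoformat(config.date_end)
    n_days = (end - start).days
    if n_days < 0:
        raise ConfigurationError("date_end precedes date_start")

    theme_weights = np.array([t.inclusion_prob for t in config.themes], dtype=float)
    rows = []
    truths = []
    for i in range(config.n_records):
        accession = f"WB{i + 1:05d}"

        # --- signalment -------------------------------------------------
        species_pool = [(name, w) for name, w, _ in config.species]
        species_true = _weighted(rng, species_pool)
        variants = next(v for n, _, v in config.species if n == species_true)
        species_out = species_true
        if variants and rng.random() < config.typo_variant_rate:
            species_out = variants[int(rng.integers(len(variants)))]
        age_true = _weighted(rng, config.age_classes)
        sex_true = _weighted(rng, config.sex_by_age[age_true])
        sex_out = "" if rng.random() < config.missing_sex_rate else sex_true
        age_out = "" if rng.random() < config.missing_age_rate else age_true
        when = (start + timedelta(days=int(rng.integers(n_days + 1)))).isoformat()

        # --- themes -----------------------------------------------------
        if config.exclusive_themes:
            pick = rng.choice(len(config.themes), p=theme_weights / theme_weights.sum())
            included = [config.themes[pick]]
        else:
            included = [
                t for t, p in zip(config.themes, theme_weights)
                if rng.random() < p
            ]
        theme_sentences = [
            _theme_sentence(rng, t, config.theme_sentence_length)
            for t in included
            for _ in range(config.theme_sentences_per_record)
        ]

        # --- findings ---------------------------------------------------
        finding_sentences = []
        statuses: dict[str, str] = {}
        for term, spec in config.findings.items():
            u = rng.random()
            if u < spec.positive_rate:
                statuses[term] = "positive"
                template = config.affirm_templates[
                    int(rng.integers(len(config.affirm_templates)))
                ]
                finding_sentences.append(template.format(term=term))
                if rng.random() < spec.mixed_rate:
                    negation = config.negation_templates[
                        int(rng.integers(len(config.negation_templates)))
                    ]
                    finding_sentences.append(negation.format(term=term))
            elif u < spec.positive_rate + spec.negated_rate:
                statuses[term] = "negated-only"
                template = config.negation_templates[
                    int(rng.integers(len(config.negation_templates)))
                ]
                finding_sentences.append(template.format(term=term))
            else:
                statuses[term] = "absent"

        # --- assemble text columns --------------------------------------
        filler = list(config.filler_sentences)

        def pick_filler() -> list[str]:
            return [filler[int(rng.integers(len(filler)))]] if filler else []

        gross = pick_filler() + theme_sentences
        histo = finding_sentences or pick_filler()
        ancillary = (
            "" if (not filler or rng.random() < config.ancillary_blank_rate)
            else filler[int(rng.integers(len(filler)))]
        )
        gross_text = " ".join(gross)
        histo_text = " ".join(histo)
        full_text = "\n".join([gross_text, histo_text, ancillary])
        _self_check(accession, full_text, statuses, config.kwic_window)

        rows.append({
            "accession": accession,
            "species": species_out,
            "sex": sex_out,
            "age_class": age_out,
            "submission_date": when,
            "gross_pathology": gross_text,
            "histopathology": histo_text,
            "ancillary_diagnostics": ancillary,
        })
        truths.append(RecordTruth(
            accession=accession,
            metadata={
                "species": species_out,
                "sex": sex_out or MISSING,
                "age_class": age_out or MISSING,
                "submission_date": when,
            },
            canonical={
                "species": species_true,
                "sex": sex_true,
                "age_class": age_true,
                "submission_date": when,
            },
            themes=tuple(t.name for t in included),
            findings=statuses,
        ))

    frame = pd.DataFrame(rows)
    truth = GroundTruth(records=tuple(truths))
    if csv_path is not None:
        frame.to_csv(csv_path, index=False, encoding="utf-8")
    if truth_path is not None:
        truth.to_json(truth_path)
    return frame, truth


# ---------------------------------------------------------------------------
# topic-recovery benchmark
# ---------------------------------------------------------------------------

def topic_benchmark_config(
    k: int,
    n_records: int = 200,
    tokens_per_record: int = 50,
    seed: int = 0,
) -> GeneratorConfig:
    """Config for planted-topic recovery: k disjoint-vocabulary themes,
    one theme per record, no findings or filler noise in the theme text."""
    extra = (
        Theme("renal", (
            "kidney", "tubules", "nephrosis", "urates", "glomeruli",
            "casts", "ureter", "medulla",
        ), 1.0),
        Theme("respiratory", (
            "airsac", "lung", "parabronchi", "exudate", "congestion",
            "trachea", "syrinx", "plaques",
        ), 1.0),
        Theme("trauma", (
            "fracture", "haemorrhage", "bruising", "laceration", "impact",
            "rupture", "contusion", "wing",
        ), 1.0),
    )
    pool = DEFAULT_CONFIG.themes + extra
    if k > len(pool):
        raise ConfigurationError(f"at most {len(pool)} benchmark themes available")
    themes = tuple(
        Theme(t.name, t.vocabulary, 1.0 / k) for t in pool[:k]
    )
    sentence_length = 10
    return GeneratorConfig(
        n_records=n_records,
        themes=themes,
        exclusive_themes=True,
        theme_sentences_per_record=max(1, tokens_per_record // sentence_length),
        theme_sentence_length=sentence_length,
        findings={},
        filler_sentences=(),
        ancillary_blank_rate=1.0,
        seed=seed,
    )


def true_topic_distributions(config: GeneratorConfig, vocabulary) -> np.ndarray:
    """The planted topic-word distributions aligned to a DTM vocabulary.

    Theme words are drawn uniformly, so each true topic is uniform over its
    theme's vocabulary (restricted to terms the matrix actually contains).
    """
    index = {term: j for j, term in enumerate(vocabulary)}
    out = np.zeros((len(config.themes), len(vocabulary)))
    for t, theme in enumerate(config.themes):
        cols = [index[w] for w in theme.vocabulary if w in index]
        if not cols:
            raise ConfigurationError(
                f"theme {theme.name!r} has no words in the vocabulary"
            )
        out[t, cols] = 1.0 / len(cols)
    return out
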