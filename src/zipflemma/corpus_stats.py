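"""Frequency statistics for annotated corpora.

Reads token-per-line TSV corpora (surface form, lemma, morphological tag),
builds type-frequency tables under several unit definitions (word form,
lemma, lemma+POS, word+lemma+tag), and computes the descriptive statistics
used when comparing word-form and lemma frequency distributions: dictionary
coverage, the word-to-lemma association map, words-per-lemma counts, the
density of lemma/word frequency ratios, and the rank-frequency sequence.

A *type* is a distinct symbol (word form or lemma); a *token* is one
occurrence of it. ``V`` counts types, ``L`` counts tokens, so ``V <= L`` and
the mean type frequency is ``<n> = L/V``.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Unit",
    "TokenRecord",
    "FrequencyTable",
    "LemmaMap",
    "CorpusFormatError",
    "read_annotated_corpus",
    "read_lexicon",
    "count_frequencies",
    "coverage",
    "build_lemma_map",
    "words_per_lemma",
    "frequency_ratio_density",
    "rank_frequency",
    "naive_tokenize",
]


class CorpusFormatError(ValueError):
    """A corpus line violates the token-per-line TSV contract."""


class Unit(str, Enum):
    """Counting unit: what string identifies a type."""

    WORD = "word"
    LEMMA = "lemma"
    LEMMA_POS = "lemma_pos"
    WORD_LEMMA_TAG = "word_lemma_tag"


class TokenRecord(NamedTuple):
    surface: str
    lemma: str | None = None
    tag: str | None = None
    in_lexicon: bool = True


@dataclass(frozen=True)
class FrequencyTable:
    """Mapping from type label to its absolute frequency ``n``.

    Derived quantities follow the standard type/token definitions:
    ``L`` (tokens), ``V`` (types), ``n_m`` (largest frequency), ``V1``
    (hapax legomena, types with n = 1), ``mean_n = L/V`` and
    ``mean_n2 = sum(n^2)/V``.
    """

    unit: Unit
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty frequency table")
        for label, n in self.counts.items():
            if n < 1 or n != int(n):
                raise ValueError(f"count for {label!r} must be a positive integer, got {n}")

    @property
    def L(self) -> int:
        return sum(self.counts.values())

    @property
    def V(self) -> int:
        return len(self.counts)

    @property
    def n_m(self) -> int:
        return max(self.counts.values())

    @property
    def V1(self) -> int:
        return sum(1 for n in self.counts.values() if n == 1)

    @property
    def mean_n(self) -> float:
        return self.L / self.V

    @property
    def mean_n2(self) -> float:
        return sum(n * n for n in self.counts.values()) / self.V

    def values(self) -> np.ndarray:
        """Frequencies as an integer array (one entry per type)."""
        return np.fromiter(self.counts.values(), dtype=np.int64, count=self.V)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for label, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{label}\t{n}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, unit: Unit = Unit.WORD) -> "FrequencyTable":
        counts: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CorpusFormatError(f"line {i}: expected 'label<TAB>count', got {line!r}")
                counts[parts[0]] = int(parts[1])
        return cls(unit=Unit(unit), counts=counts)


@dataclass
class LemmaMap:
    """Observed word-type/lemma-type association with both frequency sides.

    ``word_to_lemmas`` collects every distinct (surface, lemma) pairing seen
    in the records; a word mapped to more than one lemma is *ambiguous* (the
    reason a word's frequency can exceed that of each of its lemmas).
    ``ell1`` counts lemmas associated with exactly one word form, for which
    necessarily ``n_l = n_w`` when the word is unambiguous.
    """

    word_to_lemmas: dict[str, set[str]] = field(default_factory=dict)
    lemma_to_words: dict[str, set[str]] = field(default_factory=dict)
    word_freqs: Counter = field(default_factory=Counter)
    lemma_freqs: Counter = field(default_factory=Counter)

    @property
    def ell1(self) -> int:
        return sum(1 for words in self.lemma_to_words.values() if len(words) == 1)

    def pairs(self) -> Iterable[tuple[str, str]]:
        for word, lemmas in self.word_to_lemmas.items():
            for lemma in lemmas:
                yield word, lemma

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tlemma\tn_w\tn_l\n")
            for word, lemma in sorted(self.pairs()):
                fh.write(f"{word}\t{lemma}\t{self.word_freqs[word]}\t{self.lemma_freqs[lemma]}\n")


def read_annotated_corpus(
    path: str | Path, lexicon: set[str] | None = None
) -> list[TokenRecord]:
    """Read a token-per-line TSV corpus into TokenRecords.

    Each non-blank, non-comment line carries 1-3 tab-separated fields:
    ``surface[<TAB>lemma[<TAB>tag]]``. Blank lines (sentence breaks) and
    lines starting with ``#`` are skipped. ``in_lexicon`` flags membership
    of the surface form in *lexicon* (all true when no lexicon is given).
    """
    records: list[TokenRecord] = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) > 3:
                raise CorpusFormatError(f"line {i}: expected 1-3 tab-separated fields, got {len(fields)}")
            surface = fields[0].strip()
            if not surface:
                raise CorpusFormatError(f"line {i}: empty surface form")
            lemma = fields[1].strip() if len(fields) > 1 and fields[1].strip() else None
            tag = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
            in_lex = True if lexicon is None else surface in lexicon
            records.append(TokenRecord(surface, lemma, tag, in_lex))
    return records


def read_lexicon(path: str | Path) -> set[str]:
    """Read a lexicon file: one surface form per line, extra columns ignored."""
    lexicon: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lexicon.add(line.split("\t")[0])
    return lexicon


def _label(record: TokenRecord, unit: Unit, index: int) -> str:
    if unit is Unit.WORD:
        return record.surface
    if record.lemma is None:
        raise ValueError(f"record {index} ({record.surface!r}) lacks a lemma, required for unit={unit.value}")
    if unit is Unit.LEMMA:
        return record.lemma
    if record.tag is None:
        raise ValueError(f"record {index} ({record.surface!r}) lacks a tag, required for unit={unit.value}")
    if unit is Unit.LEMMA_POS:
        # main part of speech = first character of the tag
        return f"{record.lemma}|{record.tag[0]}"
    return f"{record.surface}|{record.lemma}|{record.tag}"


def count_frequencies(
    records: Sequence[TokenRecord], unit: Unit | str, lexicon_filter: bool = False
) -> FrequencyTable:
    """Count type frequencies over *records* under the given unit definition.

    With ``lexicon_filter`` set, only tokens whose surface form was found in
    the lexicon contribute — the restriction used to keep lemmatization
    reliable (lemmas are trusted only for in-dictionary words).
    """
    unit = Unit(unit)
    counts: Counter = Counter()
    for i, rec in enumerate(records):
        if lexicon_filter and not rec.in_lexicon:
            continue
        counts[_label(rec, unit, i)] += 1
    if not counts:
        raise ValueError("empty frequency table")
    return FrequencyTable(unit=unit, counts=dict(counts))


def coverage(records: Sequence[TokenRecord], lexicon: set[str]) -> tuple[float, float]:
    """Token- and type-level coverage of the corpus by a lexicon."""
    if not records:
        raise ValueError("empty record sequence")
    n_tokens = len(records)
    in_tokens = sum(1 for r in records if r.surface in lexicon)
    types = {r.surface for r in records}
    in_types = sum(1 for t in types if t in lexicon)
    return in_tokens / n_tokens, in_types / len(types)


def build_lemma_map(records: Sequence[TokenRecord]) -> LemmaMap:
    """Collect the observed word/lemma association and both frequency sides."""
    m = LemmaMap()
    for i, rec in enumerate(records):
        if rec.lemma is None:
            raise ValueError(f"record {i} ({rec.surface!r}) lacks a lemma")
        m.word_freqs[rec.surface] += 1
        m.lemma_freqs[rec.lemma] += 1
        m.word_to_lemmas.setdefault(rec.surface, set()).add(rec.lemma)
        m.lemma_to_words.setdefault(rec.lemma, set()).add(rec.surface)
    return m


def words_per_lemma(lemma_map: LemmaMap) -> list[tuple[int, int]]:
    """(lemma frequency n_l, number of distinct word forms) per lemma."""
    if not lemma_map.lemma_to_words:
        raise ValueError("empty lemma map")
    return [
        (lemma_map.lemma_freqs[lemma], len(words))
        for lemma, words in lemma_map.lemma_to_words.items()
    ]


def frequency_ratio_density(
    lemma_map: LemmaMap, bins_per_decade: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-binned probability density of the frequency ratio n_l / n_w.

    One ratio per observed (word, lemma) pair. Pairs with ``n_l < n_w`` are
    excluded: they arise from words associated with more than one lemma, for
    which the lemma's frequency is not the sum of its words' frequencies.

    Returns ``(edges, centers, density)`` with geometric bin edges; the
    density is normalized so that ``sum(density * diff(edges)) == 1``.
    """
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    ratios = [
        lemma_map.lemma_freqs[lemma] / lemma_map.word_freqs[word]
        for word, lemma in lemma_map.pairs()
        if lemma_map.lemma_freqs[lemma] >= lemma_map.word_freqs[word]
    ]
    if not ratios:
        raise ValueError("no qualifying (word, lemma) pairs with n_l >= n_w")
    r = np.asarray(ratios, dtype=float)
    # right-open geometric bins: a ratio sitting exactly on an edge belongs
    # to the bin starting there
    lo = math.floor(math.log10(r.min()) * bins_per_decade)
    hi = math.floor(math.log10(r.max()) * bins_per_decade) + 1
    edges = 10.0 ** (np.arange(lo, hi + 1) / bins_per_decade)
    hist, edges = np.histogram(r, bins=edges)
    widths = np.diff(edges)
    density = hist / (r.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return edges, centers, density


def rank_frequency(table: FrequencyTable) -> list[tuple[int, int]]:
    """Rank-frequency pairs ``(r, n(r))``, ties broken by type label."""
    ordered = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(r, n) for r, (_, n) in enumerate(ordered, start=1)]


def naive_tokenize(text: str) -> list[TokenRecord]:
    """Crude whitespace/punctuation splitter for demos only.

    Real corpora are expected to be pre-tokenized and lemmatized by external
    NLP tools; this helper exists so the examples can run on plain strings.
    """
    out = []
    for token in text.split():
        token = token.strip(".,;:!?\"'()[]{}«»—–").lower()
        if token:
            out.append(TokenRecord(surface=token))
    return out
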