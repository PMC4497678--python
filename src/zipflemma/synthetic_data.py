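"""Seeded generator of lemma/word frequency structures and token streams.

Emulates the statistical skeleton the analysis assumes, so the whole
pipeline is testable without any real (copyrighted) novels:

* lemma type frequencies drawn iid from a discrete power law with exponent
  gamma (near 2 for Zipf-like text) above a lower cutoff ``a``;
* each lemma splitting into word forms by a broken-stick rule — a lemma of
  frequency n breaks into parts (m, n - m) with m uniform on {1..n-1}, a
  mechanism under which the word-frequency distribution keeps the lemma
  exponent;
* optionally, a minority of word types linked to a second lemma (word-form
  ambiguity, the reason a word's frequency can exceed its lemma's);
* a shuffled token stream realizing the counts as an annotated corpus file.

No morphology, POS structure, or word order is modeled: every pipeline
statistic is order-invariant and the placeholder tag column only exercises
the parsers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .corpus_stats import FrequencyTable, LemmaMap, Unit
from .powerlaw import DiscretePowerLaw

__all__ = [
    "SyntheticSpec",
    "sample_lemma_table",
    "broken_stick_split",
    "derive_word_table",
    "write_corpus",
    "generate_corpus_files",
    "read_spec_file",
]

SPLITTINGS = ("identity", "broken_stick")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults model a Zipf-like single-author text: lemma exponent 2.0 with
    cutoff 1, a five-thousand-lemma vocabulary, two-part broken-stick
    splitting and a 5% minority of ambiguous word types.
    """

    gamma: float = 2.0
    a: int = 1
    V_lemmas: int = 5000
    splitting: str = "broken_stick"
    parts: int = 2
    ambiguity_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.V_lemmas < 1:
            raise ValueError("V_lemmas must be >= 1")
        if not 0 <= self.ambiguity_rate < 1:
            raise ValueError("ambiguity_rate must be in [0, 1)")
        if self.splitting not in SPLITTINGS:
            raise ValueError(f"splitting must be one of {SPLITTINGS}")
        if self.parts < 2:
            raise ValueError("parts must be >= 2")


def sample_lemma_table(spec: SyntheticSpec) -> FrequencyTable:
    """Draw V_lemmas iid lemma frequencies from the spec's power law."""
    model = DiscretePowerLaw(spec.gamma, spec.a)
    draws = model.sample(spec.V_lemmas, seed=np.random.default_rng(spec.seed))
    width = max(6, len(str(spec.V_lemmas)))
    counts = {f"lemma_{i:0{width}d}": int(n) for i, n in enumerate(draws, start=1)}
    return FrequencyTable(unit=Unit.LEMMA, counts=counts)


def broken_stick_split(n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Break n into (m, n - m) with m uniform on {1, ..., n-1}.

    Both parts are nonzero — the degenerate endpoints would silently
    recreate the unsplit lemma — so frequencies below 2 are indivisible.
    """
    if n < 2:
        raise ValueError("cannot split a frequency below 2 into two nonzero parts")
    m = int(rng.integers(1, n))
    return m, n - m


def _broken_stick_parts(n: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Up to ``parts`` nonzero parts via distinct uniform cut points on {1..n-1}."""
    k = min(parts - 1, n - 1)
    if k <= 0:
        return [n]
    if parts == 2:
        m, rest = broken_stick_split(n, rng)
        return [m, rest]
    cuts = np.sort(rng.choice(np.arange(1, n), size=k, replace=False))
    edges = np.concatenate(([0], cuts, [n]))
    return np.diff(edges).astype(int).tolist()


def derive_word_table(
    lemma_table: FrequencyTable, spec: SyntheticSpec
) -> tuple[FrequencyTable, LemmaMap]:
    """Split lemma frequencies into word-form frequencies.

    ``identity`` copies the table (one word per lemma). ``broken_stick``
    splits every divisible lemma into up to ``spec.parts`` word forms whose
    frequencies sum to the lemma's, conserving the total token count L.
    Afterwards a fraction ``ambiguity_rate`` of word types is linked to a
    second lemma in the map only (frequencies unchanged).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    lmap = LemmaMap()
    word_counts: dict[str, int] = {}
    for lemma, n in lemma_table.counts.items():
        if spec.splitting == "identity":
            pieces = [n]
        else:
            pieces = _broken_stick_parts(n, spec.parts, rng)
        for j, m in enumerate(pieces):
            if spec.splitting == "identity":
                word = lemma  # identity lemmatization: surface == lemma
            elif len(pieces) == 1:
                word = lemma.replace("lemma", "word", 1)
            else:
                word = f"{lemma.replace('lemma', 'word', 1)}.{j}"
            word_counts[word] = m
            lmap.word_to_lemmas.setdefault(word, set()).add(lemma)
            lmap.lemma_to_words.setdefault(lemma, set()).add(word)
            lmap.word_freqs[word] = m
        lmap.lemma_freqs[lemma] = n
    words = sorted(word_counts)
    lemmas = sorted(lemma_table.counts)
    n_ambiguous = int(spec.ambiguity_rate * len(words))
    if n_ambiguous and len(lemmas) > 1:
        chosen = rng.choice(len(words), size=n_ambiguous, replace=False)
        for wi in chosen:
            word = words[wi]
            other = lemmas[int(rng.integers(len(lemmas)))]
            while other in lmap.word_to_lemmas[word]:
                other = lemmas[int(rng.integers(len(lemmas)))]
            lmap.word_to_lemmas[word].add(other)
            lmap.lemma_to_words[other].add(word)
    word_table = FrequencyTable(unit=Unit.WORD, counts=word_counts)
    return word_table, lmap


def write_corpus(
    word_table: FrequencyTable,
    lemma_map: LemmaMap,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Realize the counts as a shuffled annotated token stream.

    Emits exactly n_w lines per word type (surface, lemma, placeholder tag),
    order shuffled under the seed. Unambiguous words carry their single
    lemma on every token, so re-counting reproduces both tables exactly;
    tokens of an ambiguous word draw among its lemmas uniformly, which
    realizes the ambiguity in the stream at the price of approximate lemma
    counts.
    """
    rng = np.random.default_rng(seed)
    surfaces: list[str] = []
    lemmas: list[str] = []
    for word, n in word_table.counts.items():
        lset = sorted(lemma_map.word_to_lemmas[word])
        surfaces.extend([word] * n)
        if len(lset) == 1:
            lemmas.extend([lset[0]] * n)
        else:
            lemmas.extend(lset[int(i)] for i in rng.integers(len(lset), size=n))
    order = rng.permutation(len(surfaces))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic corpus: power-law lemma frequencies, broken-stick word forms\n")
        for i in order:
            fh.write(f"{surfaces[i]}\t{lemmas[i]}\tX\n")


def generate_corpus_files(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate corpus, word/lemma tables and map TSVs into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lemma_table = sample_lemma_table(spec)
    word_table, lmap = derive_word_table(lemma_table, spec)
    paths = {
        "corpus": out / "corpus.tsv",
        "word_table": out / "word_freqs.tsv",
        "lemma_table": out / "lemma_freqs.tsv",
        "map": out / "lemma_map.tsv",
    }
    write_corpus(word_table, lmap, paths["corpus"], seed=spec.seed)
    word_table.write_tsv(paths["word_table"])
    lemma_table.write_tsv(paths["lemma_table"])
    lmap.write_tsv(paths["map"])
    return paths


_SPEC_TYPES = {
    "gamma": float,
    "a": int,
    "V_lemmas": int,
    "splitting": str,
    "parts": int,
    "ambiguity_rate": float,
    "seed": int,
}


def read_spec_file(path: str | Path) -> SyntheticSpec:
    """Read a ``key = value`` spec file; keys match SyntheticSpec fields."""
    spec = SyntheticSpec()
    overrides = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {i}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in _SPEC_TYPES:
                raise ValueError(f"line {i}: unknown spec key {key!r}")
            overrides[key] = _SPEC_TYPES[key](value.strip())
    return replace(spec, **overrides)
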