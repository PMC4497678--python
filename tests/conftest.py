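import numpy as np
import pytest

from zipflemma import (
    SyntheticSpec,
    TokenRecord,
    load_reference_fits,
    reference_tail_fits,
)


@pytest.fixture(scope="session")
def ref_df():
    """Bundled ten-novel reference table of published tail-fit parameters."""
    return load_reference_fits()


@pytest.fixture(scope="session")
def ref_fits():
    """Reference table as aligned (word, lemma) TailFit lists."""
    return reference_tail_fits()


@pytest.fixture
def house_records():
    """Three tokens of one lemma, the classic lemmatization example."""
    return [
        TokenRecord("houses", "house", "NNS"),
        TokenRecord("house", "house", "NN"),
        TokenRecord("housed", "house", "VBD"),
    ]


@pytest.fixture
def found_records():
    """The ambiguous word form: one surface, two lemmas."""
    return [
        TokenRecord("found", "find", "VBD"),
        TokenRecord("found", "found", "VBD"),
    ]


@pytest.fixture
def tiny_corpus_file(tmp_path):
    path = tmp_path / "corpus.tsv"
    path.write_text(
        "# demo corpus\n"
        "houses\thouse\tNNS\n"
        "ran\trun\tVBD\n"
        "\n"
        "word\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture(scope="session")
def small_synth_tables():
    """One synthetic lemma/word table pair shared across tests."""
    from zipflemma import derive_word_table, sample_lemma_table

    spec = SyntheticSpec(gamma=2.0, a=1, V_lemmas=2000, ambiguity_rate=0.0, seed=11)
    lemma_table = sample_lemma_table(spec)
    word_table, lmap = derive_word_table(lemma_table, spec)
    return spec, lemma_table, word_table, lmap
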