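import pytest

from belex.bel import parse_statement
from belex.corpus import AnnotatedSentence, EntityMention, tokenize
from belex.model import ModelConfig
from belex.pipeline import train_fd, train_re
from belex.simulate import GeneratorConfig, generate_corpus

# The worked-example sentence: AKAP220 (HGNC:AKAP11) competitively inhibits
# the activity of PP1c (HGNC:PPP1CC).
EXAMPLE_TEXT = (
    "We now demonstrate that AKAP220 fragment is a competive inhibitor of "
    "PP1c activity (K(i) = 2.9 +/- 0.7 micrometer)"
)
EXAMPLE_STATEMENT = "p(HGNC:AKAP11) decreases act(p(HGNC:PPP1CC))"


@pytest.fixture
def example_sentence() -> AnnotatedSentence:
    tokens = tokenize(EXAMPLE_TEXT)
    i_akap = tokens.index("AKAP220")
    i_pp1c = tokens.index("PP1c")
    return AnnotatedSentence(
        sentence_id="ex-a",
        tokens=tokens,
        mentions=[
            EntityMention(i_akap, i_akap + 1, "AKAP220", "gene_protein", "HGNC:AKAP11"),
            EntityMention(i_pp1c, i_pp1c + 1, "PP1c", "gene_protein", "HGNC:PPP1CC"),
        ],
        gold_statements=[parse_statement(EXAMPLE_STATEMENT)],
        text=EXAMPLE_TEXT,
    )


@pytest.fixture(scope="session")
def small_corpus():
    sentences, lexicon = generate_corpus(GeneratorConfig(n_sentences=120, seed=7))
    return sentences, lexicon


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(
        word_dim=16, position_dim=4, lstm_units=24, epochs=6, batch_size=32, seed=5
    )


@pytest.fixture(scope="session")
def tiny_models(small_corpus, tiny_config):
    """A quickly trained RE/FD model pair for pipeline-level tests."""
    sentences, _ = small_corpus
    return train_re(sentences, tiny_config), train_fd(sentences, tiny_config)
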