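import numpy as np
import pytest

from modpep.generator import GeneratorConfig, generate_corpus
from modpep.mlm import ModelConfig, TrainConfig, train_mlm
from modpep.residues import default_library
from modpep.tokenizer import train_vocabulary


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def corpus_path(tmp_path_factory, library):
    """A small generated SMILES corpus shared across tokenizer/MLM tests."""
    path = tmp_path_factory.mktemp("corpus") / "corpus.txt"
    generate_corpus(300, library, GeneratorConfig(seed=7, max_length=12), path)
    return path


@pytest.fixture(scope="session")
def corpus_lines(corpus_path):
    return [l for l in corpus_path.read_text().splitlines() if l]


@pytest.fixture(scope="session")
def vocab(corpus_path):
    return train_vocabulary(corpus_path)


@pytest.fixture(scope="session")
def tiny_model(corpus_path, vocab):
    """A briefly pretrained tiny encoder for API-level downstream tests."""
    config = ModelConfig(
        vocab_size=len(vocab), layers=1, heads=2, hidden=32, intermediate=64, context=160
    )
    model, _ = train_mlm(
        corpus_path, vocab, config, TrainConfig(steps=30, batch_size=16, lr=1e-3, seed=0)
    )
    return model
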