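import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from otitext.corpus import GeneratorConfig, generate_corpus
from otitext.embeddings import EmbeddingConfig, train_embeddings
from otitext.preprocessing import (
    PreprocessConfig,
    build_vocabulary,
    encode_corpus,
    merge_fields,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def clean_config(**overrides) -> GeneratorConfig:
    """Zero-noise generator config: no confounders, no typos."""
    base = dict(
        n_visits=400,
        n_pediatricians=8,
        negation_rate=0.0,
        other_doctor_rate=0.0,
        atypical_term_rate=0.0,
        typo_rate=0.0,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def clean_corpus():
    """400 zero-noise visits used across modules."""
    return generate_corpus(clean_config())


@pytest.fixture(scope="session")
def small_preprocess_config():
    return PreprocessConfig(max_length=64)


@pytest.fixture(scope="session")
def encoded_clean(clean_corpus, small_preprocess_config):
    """(vocab, embedding table, encoded records) for the clean corpus."""
    streams = [merge_fields(r, small_preprocess_config) for r in clean_corpus]
    vocab = build_vocabulary(streams)
    table = train_embeddings(
        streams, EmbeddingConfig(dimension=16, window=3, epochs=2, seed=5), vocab
    )
    encoded = encode_corpus(clean_corpus, vocab, small_preprocess_config)
    return vocab, table, encoded


def make_dated_record(
    visit_id: str,
    pediatrician: str,
    date: dt.date,
    patient: str | None = None,
    sex: str = "male",
):
    """Minimal valid record for split/selection tests (single-token field)."""
    from otitext.classes import VisitRecord

    return VisitRecord(
        visit_id=visit_id,
        patient_id=patient or f"pt_{visit_id}",
        pediatrician_id=pediatrician,
        visit_date=date,
        sex=sex,
        fields={"diagnosis": "otite"},
    )
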