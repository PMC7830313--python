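"""Shared fixtures: synthetic corpora and models, built once per session."""

import numpy as np
import pytest

from slcau import au
from slcau.fitting import FitOptions
from slcau.model import MorphableModel, TrainingSet
from slcau.synthetic import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def train_corpus():
    """Registered training corpus: 12 subjects x (neutral + 4 AUs)."""
    return generate_corpus(SyntheticConfig(seed=11, n_subjects=12))


@pytest.fixture(scope="session")
def training_set(train_corpus):
    return TrainingSet.from_shapes(
        train_corpus.registered_shapes(),
        [e.subject_id for e in train_corpus.scans],
        [e.label for e in train_corpus.scans],
    )


@pytest.fixture(scope="session")
def slc_model(train_corpus, training_set):
    return MorphableModel.from_training_set(
        training_set, kind="slc", k=50, seed=11, template_faces=train_corpus.template.faces
    )


@pytest.fixture(scope="session")
def pca_model(train_corpus, training_set):
    return MorphableModel.from_training_set(
        training_set, kind="pca", k=50, template_faces=train_corpus.template.faces
    )


@pytest.fixture(scope="session")
def test_corpus():
    """Raw-scan corpus of 10 unseen subjects for the AU pipeline."""
    return generate_corpus(SyntheticConfig(seed=99, n_subjects=10))


@pytest.fixture(scope="session")
def extraction(slc_model, test_corpus):
    """Two-step extraction over the raw corpus: AU records + neutral controls."""
    by_subject = {}
    for entry in test_corpus.scans:
        by_subject.setdefault(entry.subject_id, []).append(entry)
    opts = FitOptions()
    records, controls = [], []
    for sid, entries in sorted(by_subject.items()):
        neutral = next(e for e in entries if e.label == "neutral")
        s_n, _, res = au.fit_identity(slc_model, neutral.raw, opts)
        s_hat = au.resample_neutral(res.deformed_target_frame, neutral.raw)
        controls.append(
            au.extract_au_coefficients(slc_model, s_hat, neutral.raw, opts,
                                       au_label="neutral", subject_id=sid)
        )
        for entry in entries:
            if entry.label == "neutral":
                continue
            records.append(
                au.extract_au_coefficients(slc_model, s_hat, entry.raw, opts,
                                           subject_id=sid, au_label=entry.label)
            )
    return {"records": records, "controls": controls}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
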