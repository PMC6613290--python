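"""Shared desk-scale study conditions and session-scoped pipeline fixtures."""

import numpy as np
import pytest
from hypothesis import settings

from vrisk import (
    ClassifierConfig,
    EmbeddingConfig,
    ViolenceRiskModel,
    generate_site,
)
from vrisk.synthetic import DEFAULT_SIGNAL_TERMS, desk_profile_1

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# Strongly planted signal: positive terms at log-odds +2.5, protective at -2.0.
STRONG_TERMS = [(t, 2.5) if d > 0 else (t, -2.0) for t, d in DEFAULT_SIGNAL_TERMS]
# Moderately planted signal for the cross-site transfer experiment.
TRANSFER_TERMS = [(t, 2.0) if d > 0 else (t, -1.5) for t, d in DEFAULT_SIGNAL_TERMS]


def desk_embedding(seed: int = 0) -> EmbeddingConfig:
    """Compact embedding for desk-scale corpora (48-d, 12 epochs)."""
    return EmbeddingConfig(dimension=48, epochs=12, min_term_count=3, seed=seed)


def desk_grid() -> list[ClassifierConfig]:
    """Reduced cost x kernel-width grid for desk-scale nested CV."""
    return [
        ClassifierConfig(cost=c, kernel_width=g)
        for c in (1.0, 10.0)
        for g in ("scale", 0.01)
    ]


@pytest.fixture(scope="session")
def strong_corpus():
    """One desk-scale site (~700 admissions) with strongly planted signal."""
    return generate_site(desk_profile_1(signal_terms=STRONG_TERMS), seed=11)


@pytest.fixture(scope="session")
def strong_fit(strong_corpus):
    """Fitted model + nested-CV results on the strong-signal corpus."""
    model = ViolenceRiskModel.from_corpus(
        strong_corpus, embedding_config=desk_embedding(), grid=desk_grid()
    )
    return model, model.fit(seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
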