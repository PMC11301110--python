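import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")

import groupcohesion as gc  # noqa: E402
from groupcohesion.preprocess import tokenize  # noqa: E402


@pytest.fixture(scope="session")
def small_corpus():
    """600 messages, planted cohesion rate 0.3, trap rate 0.1."""
    cfg = gc.GenConfig(
        n_sessions=3,
        messages_per_session=200,
        cohesion_rate=0.3,
        trap_rate=0.1,
        seed=7,
    )
    return gc.generate_corpus(cfg)


@pytest.fixture(scope="session")
def embedding_model(small_corpus):
    toks = [tokenize(lm.message.text) for lm in small_corpus]
    return gc.train_embeddings(toks, gc.EmbeddingConfig(seed=0))


@pytest.fixture(scope="session")
def cohesion_lexicon(embedding_model):
    return gc.expand_seeds(embedding_model, gc.default_seeds())


@pytest.fixture(scope="session")
def fitted_model(small_corpus, cohesion_lexicon):
    return gc.fit(small_corpus, seed=7, lexicon=cohesion_lexicon)
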