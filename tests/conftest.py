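import numpy as np
import pytest

import topicrsa as tr


@pytest.fixture(scope="session")
def small_corpus():
    """4 topics in 2 supra-categories, 40 sentences per topic."""
    cfg = tr.CorpusConfig(
        n_topics=4, n_supra=2, vocab_size=200, sentences_per_topic=40,
        length_range=(6, 12), stopword_fraction=0.3, seed=11,
    )
    return tr.make_topic_corpus(cfg)


@pytest.fixture(scope="session")
def small_embeddings(small_corpus):
    return tr.make_embedding_table(small_corpus, dim=16, cluster_strength=2.0, seed=12)


@pytest.fixture(scope="session")
def separable_corpus():
    """High concentration, no supra sharing, no stopwords: topics have
    disjoint content vocabularies and are separable by construction."""
    cfg = tr.CorpusConfig(
        n_topics=4, n_supra=4, vocab_size=300, sentences_per_topic=250,
        length_range=(6, 12), stopword_fraction=0.0, supra_mixture=0.0,
        topic_concentration=1.0, seed=21,
    )
    return tr.make_topic_corpus(cfg)


@pytest.fixture(scope="session")
def small_geometry():
    return tr.make_ball_geometry(
        (14, 14, 14), 2.0,
        {"roi_a": ((4.5, 6.5, 6.5), 2.5), "roi_b": ((9.5, 6.5, 6.5), 2.5)},
    )


def split_indices(n, train_frac, seed):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    k = int(train_frac * n)
    return np.sort(idx[:k]), np.sort(idx[k:])
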