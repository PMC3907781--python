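import pytest
from hypothesis import HealthCheck, settings

import apclust as ap

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def text_alphabet():
    return ap.Alphabet.text()


@pytest.fixture(scope="session")
def protein_alphabet():
    return ap.Alphabet.protein()


@pytest.fixture(scope="session")
def worked_sequences(text_alphabet):
    return ap.ten_sequence_example()


@pytest.fixture(scope="session")
def worked_patterns(worked_sequences, text_alphabet):
    cfg = ap.DiscoveryConfig(min_order=5, min_occurrence=5, delta=0.9)
    return ap.discover(worked_sequences, cfg, text_alphabet)


@pytest.fixture()
def permissive_cluster_config():
    """The relaxed thresholds used for the small worked examples."""
    return ap.ClusterConfig(termination_score=0.3, column_distribution_min=0.3)


@pytest.fixture(scope="session")
def six_word_apc():
    """The canonical six-word 6x6 cluster, built by the clustering step."""
    patterns = [ap.Pattern(string=w) for w in ap.six_example_words()]
    config = ap.ClusterConfig(termination_score=0.3, column_distribution_min=0.3)
    apcs = ap.cluster(patterns, config)
    assert len(apcs) == 1
    return apcs[0]
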