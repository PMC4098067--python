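import pytest

from histevo.classify import ClassifierConfig
from histevo.domains import partition_domains
from histevo.sequence_io import load_reference_set


@pytest.fixture(scope="session")
def reference_set():
    return load_reference_set()


@pytest.fixture(scope="session")
def h2a_ref(reference_set):
    return reference_set["H2A"]


@pytest.fixture(scope="session")
def human_partition(h2a_ref):
    return partition_domains(h2a_ref.human, h2a_ref.human_fold_span,
                             seq_id="human_H2A", species_id="hsapiens")


@pytest.fixture(scope="session")
def yeast_partition(h2a_ref):
    return partition_domains(h2a_ref.yeast, h2a_ref.yeast_fold_span,
                             seq_id="yeast_H2A", species_id="scerevisiae")


@pytest.fixture(scope="session")
def classifier_config():
    return ClassifierConfig()
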