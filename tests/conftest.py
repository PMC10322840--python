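import pytest

from ksrscan.motifs import annotate, load_exemplars
from ksrscan.synthetic_data import (reference_msa_rows, reference_records,
                                    reference_truths)


@pytest.fixture(scope="session")
def references():
    return reference_records()


@pytest.fixture(scope="session")
def truths():
    return reference_truths()


@pytest.fixture(scope="session")
def msa_rows():
    return reference_msa_rows()


@pytest.fixture(scope="session")
def exemplars():
    return load_exemplars()


@pytest.fixture(scope="session")
def annotations(references):
    """Annotations of the five zero-noise reference templates."""
    return {base: annotate(rec) for base, rec in references.items()}
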