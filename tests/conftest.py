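import pytest

from mitochar import refdata, synth
from mitochar.codons import GeneticCode


@pytest.fixture(scope="session")
def ref_annotation():
    """The 38-feature reference annotation on a 15,955 bp circle."""
    return refdata.reference_annotation()


@pytest.fixture(scope="session")
def ref_codon_counts():
    """Published pooled codon counts (RNA alphabet) over the 13 PCGs."""
    return refdata.reference_codon_counts()


@pytest.fixture(scope="session")
def composition_df():
    """Published per-region composition rows for 12 mitogenome records."""
    return refdata.composition_table()


@pytest.fixture(scope="session")
def code5():
    return GeneticCode.from_table_id(5)


@pytest.fixture(scope="session")
def default_synthesis():
    """One synthesized genome under the study-condition defaults."""
    cfg = synth.default_config(seed=20190828)
    return synth.synthesize(cfg)
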