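import pytest

from talocus.synthetic_data import LocusConfig, make_ta_locus


@pytest.fixture(scope="session")
def default_locus():
    """The default planted locus (seed 1) with its ground truth."""
    return make_ta_locus(LocusConfig(seed=1))
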