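import pytest

from carrierfreq import load_dhcr7_annotations, load_dhcr7_variants


@pytest.fixture(scope="session")
def dhcr7_records():
    return load_dhcr7_variants()


@pytest.fixture(scope="session")
def dhcr7_annotations():
    return load_dhcr7_annotations()
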