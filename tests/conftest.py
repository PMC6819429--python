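import pytest

from mrkit import datasets


@pytest.fixture(scope="session")
def calcium():
    """7-SNP serum-calcium instrument set (SD 0.5 mg/dl)."""
    return datasets.calcium_instruments()


@pytest.fixture(scope="session")
def magnesium():
    """6-SNP serum-magnesium instrument set (SD 0.1)."""
    return datasets.magnesium_instruments()


@pytest.fixture(scope="session")
def exclusions():
    return {e.name: e for e in datasets.pleiotropy_exclusions()}
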