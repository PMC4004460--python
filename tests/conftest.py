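import pytest

from reminder_agreement import cloud_profile, local_profile


@pytest.fixture(scope="session")
def cloud():
    return cloud_profile()


@pytest.fixture(scope="session")
def local():
    return local_profile()
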