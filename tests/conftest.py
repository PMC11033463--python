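import pytest

from acukg.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 12-document synthetic corpus with gold ledger."""
    return generate_fixture(FixtureSpec(n_documents=12, seed=0))


@pytest.fixture(scope="session")
def noisy_fixture():
    """Same conditions with distractor noise enabled."""
    return generate_fixture(FixtureSpec(n_documents=12, noise_rate=0.5, seed=0))
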