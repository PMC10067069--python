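import pytest

from omrs.experiments import train_default_classifier


@pytest.fixture(scope="session")
def trained():
    """Default classifier trained once on the standard synthetic textures,
    with its held-out test report."""
    model, report = train_default_classifier(seed=11)
    return model, report
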