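import pytest

import breadrisk as br


@pytest.fixture(scope="session")
def study():
    """The default synthetic survey (5 regions x 18 bakeries x 3 stages x 12)."""
    return br.generate_study(br.default_config(seed=0))


@pytest.fixture(scope="session")
def defaults():
    return br.builtin_defaults()


@pytest.fixture(scope="session")
def fitted(study):
    return br.BreadRiskModel(study).fit()
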