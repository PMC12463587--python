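import numpy as np
import pytest

from psmcea.config import default_config


@pytest.fixture
def china_overall():
    return default_config("china", "overall")


@pytest.fixture
def us_overall():
    return default_config("us", "overall")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
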