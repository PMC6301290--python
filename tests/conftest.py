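import logging

import numpy as np
import pytest

from capturestress.synthetic import (BoutModelConfig, nurse_config,
                                     simulate_study)


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # package warnings are tested explicitly via caplog where relevant
    logging.getLogger("capturestress").setLevel(logging.INFO)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small on-disk synthetic study: 8 sharks with short capture events."""
    out = tmp_path_factory.mktemp("study")
    bout_cfg = BoutModelConfig(duration_min_range=(3.0, 12.0))
    paths, truths = simulate_study(8, bout_cfg, nurse_config(), seed=77,
                                   out_dir=out)
    return out, paths, truths
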