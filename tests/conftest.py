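import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvcforest.synth import FeatureTableConfig, SynthConfig, generate_feature_table, generate_record

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CLEAN = dict(white_sd=0.0, baseline_amp=0.0, powerline_amp=0.0)


@pytest.fixture(scope="session")
def clean_record():
    """300-beat noise-free synthetic record with 10% PVC beats."""
    cfg = SynthConfig(n_beats=300, pvc_fraction=0.1, seed=11, **CLEAN)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def imbalanced_table():
    """13:1 labeled 4-feature table, 7000 beats."""
    return generate_feature_table(FeatureTableConfig(n=7000, ratio=13.0, seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
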