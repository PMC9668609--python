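import numpy as np
import pytest

from tractanomaly.registry import load_tract_registry
from tractanomaly.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_tract_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for pipeline-level tests: 10 tracts, strong effects."""
    cfg = SynthConfig(
        n_hc=20,
        n_ltle=6,
        n_rtle=4,
        n_tracts=10,
        n_affected_tracts=6,
        voxels_per_tract=(80, 120),
        effect_size_d=3.0,
        lesion_depth=8.0,
        n_patterns=2,
        master_seed=314,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def reference_cohort():
    """Full-size cohort mirroring the study conditions (37 HC vs 18 TLE)."""
    return generate_cohort(SynthConfig(master_seed=2022))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
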