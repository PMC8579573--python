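import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amyloscan import (FeatureSpec, SyntheticConfig, TrainingConfig,
                       confidence_levels, count_tripeptides,
                       generate_annotated_proteins, generate_hexapeptides,
                       rank_and_select, train)
from amyloscan.scales import standardize_scale

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_scales():
    """Two simple property scales for hand-checkable PseAAC values."""
    rng = np.random.default_rng(42)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    s1 = standardize_scale({aa: float(i) for i, aa in enumerate(aas)}, "ramp")
    s2 = standardize_scale(
        {aa: float(v) for aa, v in zip(aas, rng.normal(size=20))}, "noise")
    return [s1, s2]


@pytest.fixture(scope="session")
def planted_config():
    """The default planted-signal study conditions (n=200/200)."""
    return SyntheticConfig(n_pos=200, n_neg=200, seed=7)


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate_hexapeptides(planted_config)


@pytest.fixture(scope="session")
def planted_stats(planted_dataset):
    return confidence_levels(count_tripeptides(planted_dataset))


@pytest.fixture(scope="session")
def planted_spec(planted_stats) -> FeatureSpec:
    return rank_and_select(planted_stats, "threshold", 0.85)


@pytest.fixture(scope="session")
def planted_model(planted_dataset, planted_spec):
    return train(planted_dataset, planted_spec, TrainingConfig(seed=11))


@pytest.fixture(scope="session")
def planted_proteins(planted_config):
    return generate_annotated_proteins(
        20, hotspots_per_protein=2, length_range=(40, 80), config=planted_config)
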