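import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import silscreen as ss

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cos12():
    return ss.LOCUS_PRESETS["COS12"]


@pytest.fixture(scope="session")
def yfr057w():
    return ss.LOCUS_PRESETS["YFR057W"]


@pytest.fixture(scope="session")
def default_well(cos12):
    """One null co-culture well at full acquisition scale, with truth labels."""
    cfg = ss.GeneratorConfig(n_events_per_population=10000, seed=7)
    strain = ss.StrainSpec("YKU70", 0.0, "RFP", "COS12")
    table, truth = ss.simulate_well(cos12, strain, cfg, return_truth=True)
    return table, truth


@pytest.fixture(scope="session")
def small_null_screen(cos12):
    """60-strain all-null screen, small wells — enough for hit calling."""
    cfg = ss.GeneratorConfig(n_events_per_population=800, seed=42)
    tables, strains, truth = ss.simulate_screen(60, ss.EffectModel(0.0), cos12, cfg)
    screen = ss.score_screen(tables, strains, min_per_population=200)
    return screen, truth


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
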