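import numpy as np
import pytest

from oddlearn import (
    DesignSpec,
    GroundTruth,
    simulate_experiment,
    exclude_at_chance,
    apply_screening,
    truncate_trials,
)
from oddlearn.model import LearningModel, ModelSpec


@pytest.fixture(scope="session")
def tiny_experiment():
    """2 participants per cell, 2 x 30 trials; all learners (no at-chance responders)."""
    design = DesignSpec(n_per_cell=2, n_blocks=2, trials_per_block=30, seed=42)
    records, participants = simulate_experiment(design, GroundTruth(fraction_at_chance=0.0))
    return records, participants


#: fast-learning ground truth for small fixtures: thresholds identifiable
#: within ~60 trials so screening keeps every design cell populated
FAST_LEARNERS = GroundTruth(
    start_intercept=-1.2, start_age=0.0, rate_intercept=1.2, rate_age=0.0,
    asym_intercept=-2.6, asym_age=-0.3, sd_start=0.3, sd_rate=0.3,
    fraction_at_chance=0.0,
)


@pytest.fixture(scope="session")
def small_modelled_records():
    """Pipeline-shaped data: simulated, screened, truncated to 60 trials."""
    design = DesignSpec(n_per_cell=3, n_blocks=2, trials_per_block=40, seed=7)
    records, _ = simulate_experiment(design, FAST_LEARNERS)
    screened = apply_screening(records, exclude_at_chance(records))
    return truncate_trials(screened, 60)


@pytest.fixture(scope="session")
def small_full_fit(small_modelled_records):
    """A fitted full model at a small draw budget, reused by read-only tests."""
    model = LearningModel(small_modelled_records, ModelSpec.full())
    return model.fit(draws=120, warmup=100, chains=2, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
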