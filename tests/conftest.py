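import logging

import pytest
from hypothesis import HealthCheck, settings

from snapscreen import (
    normalize_design,
    paper_scale_config,
    score_screen,
    simulate_screen,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# Validation notices (cross-plate layout, control presence) are expected on
# every simulated screen; keep them out of the test log.
logging.getLogger("snapscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_sim():
    """One library-scale simulated screen (520 factors, duplicates, 384-well)."""
    return simulate_screen(paper_scale_config(seed=101))


@pytest.fixture(scope="session")
def paper_scored(paper_sim):
    """Normalized table, background models and scored result for paper_sim."""
    normalized, backgrounds = normalize_design(paper_sim.design())
    result = score_screen(
        normalized,
        paper_sim.library,
        paper_sim.config.condition_a,
        paper_sim.config.condition_b,
    )
    return normalized, backgrounds, result
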