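import numpy as np
import pytest

from polefocus import SimulationConfig, simulate_population
from polefocus.pipeline import AnalysisParams, match_cells_to_truth, run_analysis


@pytest.fixture(scope="session")
def small_population():
    """A 60-cell default-mixture movie plus its full analysis, shared across
    tests that only read from it."""
    cfg = SimulationConfig(n_cells=60, seed=11, nucleation_rate=0.0)
    stack, truth = simulate_population(cfg)
    result = run_analysis(stack, AnalysisParams())
    mapping = match_cells_to_truth(result.tracks, truth)
    return dict(config=cfg, stack=stack, truth=truth, result=result,
                mapping=mapping)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
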