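import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mrlink as M

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_proportional_set():
    """Four instruments whose outcome effects are exactly 0.2 x exposure
    effects: every ratio-based estimator must return 0.2."""
    return M.HarmonizedInstrumentSet.from_arrays(
        bx=[0.30, 0.25, 0.20, 0.15],
        sx=[0.01] * 4,
        by=[0.060, 0.050, 0.040, 0.030],
        sy=[0.01] * 4,
    )


@pytest.fixture
def random_set():
    """A benign 10-instrument set with a true effect of 0.25."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.2, 10)
    sx = np.full(10, 0.005)
    sy = np.full(10, 0.01)
    by = rng.normal(0.25 * bx, sy)
    return M.HarmonizedInstrumentSet.from_arrays(bx, sx, by, sy)


def make_summary_table(rows, trait_name="trait", trait_type="continuous",
                       case_fraction=None):
    """Build a GwasSummaryTable from a list of dicts with canonical keys."""
    df = pd.DataFrame(rows)
    return M.table_from_frame(df, trait_name, trait_type,
                              case_fraction=case_fraction)


@pytest.fixture
def estimator_config():
    return M.EstimatorConfig(rng_seed=7, bootstrap_reps=200)
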