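import numpy as np
import pandas as pd
import pytest

from refluxpred import cohort_sim, responder


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged calibrated cohort (n=1888, seed 0)."""
    cfg = cohort_sim.default_config(seed=0)
    patients, daily = cohort_sim.generate_cohort(cfg)
    return cfg, patients, daily


@pytest.fixture(scope="session")
def default_statuses(default_cohort):
    _, _, daily = default_cohort
    rule = responder.ResponderRule()
    return {
        28: responder.classify_cohort(daily, rule.at_horizon(28)),
        56: responder.classify_cohort(daily, rule.at_horizon(56)),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural tests."""
    cfg = cohort_sim.default_config(n_patients=150, seed=11)
    patients, daily = cohort_sim.generate_cohort(cfg)
    return cfg, patients, daily


def make_series(days, scores, patient_id="P0001"):
    """Long-format daily-score frame for one patient (gi only)."""
    gi = np.asarray(scores, dtype=float)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "day": np.asarray(days, dtype=int),
            "gi": gi,
            "wso": gi * 0.3,
            "total": gi * 1.3,
        }
    )


@pytest.fixture
def series_factory():
    return make_series
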