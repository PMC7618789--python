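import numpy as np
import pandas as pd
import pytest

from posbias.design import build_fert_design
from posbias.synthetic import CohortSpec, ResponseModel, simulate_cohort, simulate_fert_session


@pytest.fixture(scope="session")
def base_model() -> ResponseModel:
    return ResponseModel.default()


@pytest.fixture(scope="session")
def fert_design() -> pd.DataFrame:
    return build_fert_design(1)


@pytest.fixture(scope="session")
def fert_session(fert_design, base_model) -> pd.DataFrame:
    return simulate_fert_session(fert_design, base_model, 42)


@pytest.fixture(scope="session")
def small_cohort():
    """Behaviour-only cohort, small enough for fast group statistics."""
    return simulate_cohort(CohortSpec(n=20, responder_fraction=0.6, master_seed=7))


def random_trial_table(rng: np.random.Generator, n_trials: int = 250) -> pd.DataFrame:
    """A fully random trial table (uniform responses), for oracle checks."""
    from posbias.design import EMOTIONS

    design = build_fert_design(int(rng.integers(2**31)))
    resp = rng.integers(0, 7, size=n_trials)
    out = design.copy()
    out["response_emotion"] = [EMOTIONS[i] for i in resp]
    out["rt_ms"] = rng.uniform(300, 2000, n_trials)
    out["correct"] = out.response_emotion == out.true_emotion
    return out
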