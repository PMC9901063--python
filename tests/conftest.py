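import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import regimen_rl as rr

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest synthetic cohort shared by the slower integration tests."""
    return rr.generate_cohort(rr.GeneratorConfig(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def filtered_cohort(small_cohort) -> pd.DataFrame:
    return rr.filter_patients(small_cohort)


@pytest.fixture(scope="session")
def toy_deterministic_mdp() -> rr.GroundTruthMDP:
    """5-state, 3-action MDP with deterministic transitions s' = (s+a+1) mod 5."""
    S, A = 5, 3
    P = np.zeros((S, A, S))
    R = np.zeros((S, A))
    rng = np.random.default_rng(1)
    for s in range(S):
        for a in range(A):
            P[s, a, (s + a + 1) % S] = 1.0
            R[s, a] = rng.uniform(-1, 1)
    return rr.GroundTruthMDP(
        n_states=S, n_actions=A, transitions=P, rewards=R,
        behavior_policy=np.full((S, A), 1.0 / A),
    )


def tiny_visit_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal visit table, filling unspecified columns with defaults."""
    defaults = {
        "age": 75.0, "mmse": 25.0, "adas13": 20.0, "ravlt_immediate": 30.0,
        "ravlt_learning": 4.0, "cdrsb": 2.0, "moca": 22.0, "fdg": 1.2,
        "medication": "", "hypertension": False, "depression": False,
    }
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full)[list(rr.REQUIRED_COLUMNS)]
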