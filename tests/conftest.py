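import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from opponent_ema import CohortConfig
from opponent_ema.synthetic_data import TrueDynamics, default_group_effects

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def scenario_config(post_amplitude: float, noise_sd: float, seed: int,
                    post_rate: float = 0.3,
                    baseline: float = 5.0) -> CohortConfig:
    """Study-scale cohort whose only dynamic is a known mood decay.

    Both moral-incongruence groups share the same ground truth so the
    whole cohort identifies one (a, b, c) triple.
    """
    effects = default_group_effects()
    for group in effects:
        for var in effects[group]:
            effects[group][var] = TrueDynamics(baseline)
        effects[group]["mood"] = TrueDynamics(
            baseline, post_amplitude=post_amplitude, post_rate=post_rate)
    return CohortConfig(seed=seed, noise_sd=noise_sd, group_effects=effects)


@pytest.fixture
def hand_alignment_tables():
    """Two in-group episodes, one intercourse episode, 12 mood ratings.

    All expected full/truncated pre/post row sets for this fixture are
    enumerable by hand; see tests that consume it.
    """
    obs_hours = [90, 95, 99, 100, 101, 104, 105, 107, 109, 112, 115, 130]
    observations = pd.DataFrame(
        {
            "participant_id": "P1",
            "time_min": [h * 60.0 for h in obs_hours],
            "variable": "mood",
            "value": np.linspace(3, 7, len(obs_hours)),
            "origin": "scheduled",
        }
    )
    episodes = pd.DataFrame(
        {
            "episode_id": [0, 1, 2],
            "participant_id": "P1",
            "time_min": [100 * 60.0, 110 * 60.0, 105 * 60.0],
            "episode_type": ["porn_masturbation", "porn_masturbation_orgasm",
                             "intercourse"],
            "duration_min": [20.0, 25.0, 30.0],
            "peak_mood": [8.0, 7.5, 9.0],
        }
    )
    return observations, episodes
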