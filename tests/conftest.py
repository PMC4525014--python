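import dataclasses

import numpy as np
import pandas as pd
import pytest

from skerp.synth_cohort import CohortConfig, ParticipantSpec
from skerp.task_model import default_geometry


@pytest.fixture(scope="session")
def geometry():
    """Calibrated default work-space geometry (shared; computed once)."""
    return default_geometry()


@pytest.fixture(scope="session")
def base_spec():
    """A mid-skill performer with round amplitudes for analytic readouts."""
    return ParticipantSpec(
        id="T01", skill=0.5, theta_mean=272.0, theta_sd=5.0,
        theta_dot_mean=224.0, theta_dot_sd=60.0, a1=12.0, a2=6.0,
        a1_hit=3.6, kr_latency_center=0.860, noise_sd=10.0, blink_rate=15.0,
        seed=12345, omega=2.83, expected_hit_rate=0.7)


@pytest.fixture()
def quiet_spec(base_spec):
    """Noise-free, blink-free variant of the base performer."""
    return dataclasses.replace(base_spec, noise_sd=0.0, blink_rate=0.0)


def make_trials(labels, t_krs, spacing=2.2, participant="T01",
                thetas=None, theta_dots=None, distances=None):
    """Hand-built trial table with the schema the generator produces."""
    n = len(labels)
    if distances is None:
        distances = [0.02 if lb == "hit" else 0.30 for lb in labels]
    return pd.DataFrame({
        "participant": participant,
        "trial": np.arange(1, n + 1),
        "theta": thetas if thetas is not None else np.full(n, 272.0),
        "theta_dot": theta_dots if theta_dots is not None else np.full(n, 224.0),
        "min_distance": distances,
        "label": labels,
        "t_kr": t_krs,
        "release_time": 5.0 + spacing * np.arange(n),
    })


@pytest.fixture(scope="session")
def tiny_cohort_config():
    return CohortConfig(n_participants=2, min_trials=60, max_trials=90,
                        master_seed=9)
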