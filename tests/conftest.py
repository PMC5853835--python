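import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    from nirserp.montage import build_probe_layout
    return build_probe_layout()


@pytest.fixture(scope="session")
def small_design():
    """Short run: 6 sentences per condition, 10 nulls, 1 tone (29 events)."""
    from nirserp.design import build_design
    return build_design(n_per_sentence_condition=6, n_null=10, n_tone=1,
                        seed=123)


@pytest.fixture(scope="session")
def full_design():
    from nirserp.design import build_design
    return build_design(seed=0)


def sparse_design(n_trials: int = 8, spacing_s: float = 80.0,
                  condition: str = "correct") -> "pd.DataFrame":
    """Widely spaced single-condition design for convolution-shape tests."""
    from nirserp.design import EventDesign
    onsets = np.arange(n_trials) * spacing_s
    df = pd.DataFrame({"onset": onsets, "duration": 4.0,
                       "trial_type": condition})
    return EventDesign(df)
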