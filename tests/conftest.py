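import numpy as np
import pandas as pd
import pytest

from metaroc import observer_sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12 simulated participants under the default population."""
    return observer_sim.simulate_cohort(12, seed=7)


def make_trials(
    responses,
    corrects,
    confidences,
    rts=None,
    blocks=None,
    participant_id="P001",
):
    """Hand-built trial table; stimulus is derived from response and correct."""
    n = len(responses)
    rts = rts if rts is not None else [800.0] * n
    blocks = blocks if blocks is not None else [2] * n
    stimuli = [
        r if c else (observer_sim.S2 if r == observer_sim.S1 else observer_sim.S1)
        for r, c in zip(responses, corrects)
    ]
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": blocks,
            "trial": range(1, n + 1),
            "stimulus": stimuli,
            "response": list(responses),
            "correct": list(corrects),
            "confidence": list(confidences),
            "rt_ms": rts,
            "soa_ms": 25.0,
        }
    )
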