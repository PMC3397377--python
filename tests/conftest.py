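import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seqddm
from seqddm import analysis, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_params():
    return seqddm.EXPERIMENT1_FIT


@pytest.fixture(scope="session")
def exp2_params():
    return seqddm.EXPERIMENT2_FIT


@pytest.fixture(scope="session")
def exp1_session(exp1_params):
    """Model-simulated unbiased session (13 x 120 trials, 10 passes)."""
    sched = generate.generate_experiment_schedule("exp1", seed=42)
    stimuli = generate.generate_schedule_stimuli(sched)
    df = seqddm.simulate_session(stimuli, exp1_params, n_passes=10, seed=42,
                                 p_alt=sched.p_alts, subject="exp1-sim")
    return analysis.flag_outliers(analysis.label_transitions_and_sequences(df))


@pytest.fixture(scope="session")
def exp2_session(exp2_params):
    """Model-simulated transition-biased session (9 x 200 trials, 10 passes)."""
    sched = generate.generate_experiment_schedule("exp2", seed=42)
    stimuli = generate.generate_schedule_stimuli(sched)
    df = seqddm.simulate_session(stimuli, exp2_params, n_passes=10, seed=42,
                                 p_alt=sched.p_alts, subject="exp2-sim")
    return analysis.flag_outliers(analysis.label_transitions_and_sequences(df))


def toy_table(stimuli, responses, rts, block=1, subject="s1", p_alt=0.5,
              trial_start=1):
    """Small hand-built trial table for exact-arithmetic tests."""
    n = len(stimuli)
    return pd.DataFrame({
        "subject": subject,
        "block": block,
        "trial": np.arange(trial_start, trial_start + n),
        "p_alt": p_alt,
        "stimulus": list(stimuli),
        "response": list(responses),
        "correct": [s == r for s, r in zip(stimuli, responses)],
        "rt": list(rts),
    })
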