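import numpy as np
import pytest

from canegait.io import default_config
from canegait.pipeline import build_feature_table
from canegait.simulate import GaitSimParams, load_profile, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def default_trial():
    """One frail-preset trial at default noise with ground truth."""
    params = load_profile("default").presets["frail"]
    return simulate_trial(params, seed=42, trial_id="T1", subject_id="S1")


@pytest.fixture(scope="session")
def clean_single_harmonic_trial():
    """Noiseless, impact-free, single-harmonic, constant-stride trial.

    Every feature has a closed form: RMS = a/sqrt(2), MPF = stride
    frequency, peak angular velocity = g, stride time = the constant
    stride period.
    """
    params = GaitSimParams(
        stride_time_sd_s=0.0,
        weights_vt=(1.0, 0.0, 0.0, 0.0),
        weights_ap=(1.0, 0.0, 0.0, 0.0),
        weights_ml=(1.0, 0.0, 0.0, 0.0),
        impact_amp=0.0,
        noise_acc=0.0,
        noise_gyro=0.0,
        n_strides=10,
    )
    return simulate_trial(params, seed=7)


@pytest.fixture(scope="session")
def cohort(config):
    """Default-composition cohort (14/31 subjects, 37/94 trials) + features."""
    manifest, trials, kcl = simulate_cohort(load_profile("default"), seed=123)
    table, exclusions = build_feature_table((t.recording for t in trials), manifest, config)
    return {"manifest": manifest, "trials": trials, "kcl": kcl,
            "table": table, "exclusions": exclusions}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
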