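import numpy as np
import pytest

from mvnradar import RadarConfig, SceneSpec, VitalSignProfile
from mvnradar.radar_sim import synthesize_recording


@pytest.fixture(scope="session")
def short_config() -> RadarConfig:
    return RadarConfig(duration=10.0)


@pytest.fixture(scope="session")
def clean_scene() -> SceneSpec:
    """Subject only: no clutter, no DC, no noise."""
    return SceneSpec(subject_distance=0.75, static_clutter=(), dc_offset=0j,
                     snr_db=float("inf"))


@pytest.fixture(scope="session")
def steady_profile() -> VitalSignProfile:
    """Default kinematics without heart-rate drift."""
    return VitalSignProfile(heart_drift_std=0.0)


@pytest.fixture(scope="session")
def clean_recording(short_config, clean_scene, steady_profile):
    return synthesize_recording(short_config, clean_scene, steady_profile, seed=7)


@pytest.fixture(scope="session")
def toy_sinusoid_windows():
    """Noise-free sinusoid windows (n, 5, 128), z-scored, with BPM labels."""
    rng = np.random.default_rng(11)
    t = np.arange(128) / 50.0
    X, y = [], []
    for _ in range(120):
        f = rng.uniform(1.0, 1.7)
        s = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        X.append(np.tile(s, (5, 1)))
        y.append(60.0 * f)
    X = np.array(X)
    X = (X - X.mean(axis=(1, 2), keepdims=True)) / X.std(axis=(1, 2), keepdims=True)
    return X, np.array(y)
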