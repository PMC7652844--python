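import numpy as np
import pandas as pd
import pytest

from eegbeta.montage import standard_montage_1020
from eegbeta.recording import Recording
from eegbeta.simulate import (
    SimulationConfig,
    analytic_relative_beta,
    factor_table,
    simulate_profiles,
    simulate_recording,
    _component_shapes,
    _spatial_mixing,
)


@pytest.fixture(scope="session")
def montage():
    return standard_montage_1020()


@pytest.fixture(scope="session")
def sim_cfg():
    """Short-duration config for signal-level tests."""
    return SimulationConfig(n_subjects=8, n_female=4, duration=64.0, seed=11)


@pytest.fixture(scope="session")
def mixing(montage):
    return _spatial_mixing(montage)


@pytest.fixture(scope="session")
def shapes_64s(sim_cfg):
    n = int(sim_cfg.duration * sim_cfg.fs)
    return _component_shapes(n, sim_cfg.fs, sim_cfg.band_amplitudes.gamma)


def make_recording(seed: int, cfg=None, beta_factor: float = 1.0,
                   montage=None, mixing=None, shapes=None) -> Recording:
    cfg = cfg or SimulationConfig(n_subjects=8, n_female=4, duration=64.0, seed=11)
    rng = np.random.default_rng(seed)
    return simulate_recording(beta_factor, cfg, rng, montage, mixing, shapes)


@pytest.fixture()
def clean_recording(sim_cfg, montage, mixing, shapes_64s):
    return make_recording(3, sim_cfg, 1.0, montage, mixing, shapes_64s)


def sine_recording(freq: float, fs: float = 250.0, duration: float = 10.0,
                   n_channels: int = 2, amplitude: float = 1.0) -> Recording:
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording(data=data, fs=fs, labels=[f"ch{i}" for i in range(n_channels)])


def analytic_feature_table(
    config: SimulationConfig,
    channel_noise: float = 0.02,
    noise_seed: int = 1234,
    n_channels: int = 19,
) -> pd.DataFrame:
    """Feature table built from the noiseless analytic feature, no signals.

    Per-channel features are the analytic relative beta of each subject's
    beta factor plus small multiplicative channel noise, so channels are
    strongly correlated through the shared subject factor -- the same
    dependence structure the full pipeline produces, at zero signal cost.
    """
    meta = factor_table(simulate_profiles(config), config)
    rng = np.random.default_rng(noise_seed)
    labels = standard_montage_1020().labels[:n_channels]
    base = meta["analytic_rel_beta"].to_numpy()
    feats = base[:, None] * (1.0 + channel_noise * rng.standard_normal((len(meta), n_channels)))
    feats = np.clip(feats, 1e-6, 1 - 1e-6)
    for j, lab in enumerate(labels):
        meta[f"rb_{lab}"] = feats[:, j]
    meta["mean_rel_beta"] = feats.mean(axis=1)
    return meta
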