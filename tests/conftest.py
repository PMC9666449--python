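import numpy as np
import pandas as pd
import pytest

from tusvep.preprocess import EpochedEEG
from tusvep.synth import Channel, SimConfig, default_channels


def make_epochs(data: np.ndarray, fs: float = 1000.0,
                block: str = "LGN1", condition: str = "light",
                channels=None, pre_ms: float = 200.0) -> EpochedEEG:
    """Wrap a (trials, channels, time) array in an EpochedEEG with uniform
    labels, for tests that construct trials directly."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # single channel
        data = data[:, None, :]
    n_trials, n_ch, n_time = data.shape
    if channels is None:
        channels = tuple(
            Channel(f"O{i+1}", "occipital", "left" if i % 2 == 0 else "right")
            for i in range(n_ch)
        )
    time_ms = (np.arange(n_time) - pre_ms * fs / 1e3) / fs * 1e3
    labels = pd.DataFrame({
        "onset_s": np.arange(n_trials, dtype=float),
        "block": block, "condition": condition,
        "light_on": "light" in condition, "tus_on": "tus" in condition,
    })
    return EpochedEEG(data=data, fs=fs, time_ms=time_ms, labels=labels,
                      channels=channels)


@pytest.fixture
def quiet_config() -> SimConfig:
    """Noiseless, artifact-free configuration: evoked template only."""
    from tusvep.synth import BlinkParams, GammaParams, TusArtifactParams

    return SimConfig(
        seed=0,
        noise_scale_uv=0.0,
        gamma_burst=GammaParams(amplitude_uv=0.0),
        tus_artifact=TusArtifactParams(amplitude_uv=0.0),
        blink=BlinkParams(rate_per_trial=0.0),
    )


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture
def occipital_channels():
    return tuple(c for c in default_channels() if c.region == "occipital")
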