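import numpy as np
import pytest

from mubci import DecoderConfig, SimulationParams, TaskConfig, TrialTiming


@pytest.fixture
def fast_params() -> SimulationParams:
    """Reduced sampling rate keeps generator loops cheap in tests."""
    return SimulationParams(sampling_rate=250.0, seed=0)


@pytest.fixture
def fast_decoder_config() -> DecoderConfig:
    """Decoder config valid at 250 Hz (default bandpass needs >400 Hz)."""
    return DecoderConfig(bandpass=(0.5, 100.0))


@pytest.fixture
def short_timing() -> TrialTiming:
    return TrialTiming(iti=2.0, prefeedback=3.0, feedback=4.0, postfeedback=0.5)


@pytest.fixture
def task_config() -> TaskConfig:
    return TaskConfig()


def welch_band_power(x: np.ndarray, fs: float, band: tuple[float, float],
                     nperseg: int = 256) -> float:
    """Independent band-power oracle (Welch integral over the band)."""
    from scipy.signal import welch
    f, P = welch(x, fs=fs, nperseg=min(nperseg, len(x)))
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(P[sel], f[sel]))
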