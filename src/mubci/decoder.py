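"""Online mu-rhythm control pipeline.

Chain per update: bandpass + notch conditioning, small-Laplacian spatial
filtering at C3 and C4, sliding-window least-squares autoregressive spectral
estimation, upper-mu band amplitude extraction, adaptive z-normalization and
a linear map to a 2-axis velocity command.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .synthetic import EEGRecording, C3_NEIGHBORS, C4_NEIGHBORS


class ChannelNotFoundError(KeyError):
    """A required electrode label is missing from the recording."""


@dataclass(frozen=True)
class DecoderConfig:
    band_low: float = 10.0
    band_high: float = 14.0
    ar_order: int = 16
    window_length: float = 0.400
    update_interval: float = 0.040
    laplacian_map: dict = field(default_factory=lambda: {
        "C3": list(C3_NEIGHBORS), "C4": list(C4_NEIGHBORS)})
    gain_x: float = 3.0
    gain_y: float = 3.0
    normalizer_halflife: float = 20.0
    notch_freq: float = 60.0
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (0.5, 200.0)
    spectrum_bin_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.band_low >= self.band_high:
            raise ValueError("band_low must be < band_high")
        if self.update_interval > self.window_length:
            raise ValueError("update_interval must not exceed window_length")

    def validate_rate(self, sampling_rate: float) -> None:
        if sampling_rate <= 2.0 * self.bandpass[1]:
            raise ValueError(
                f"sampling rate {sampling_rate} Hz too low for bandpass "
                f"upper edge {self.bandpass[1]} Hz")
        if self.ar_order >= self.window_length * sampling_rate:
            raise ValueError("ar_order must be smaller than the window in samples")


@dataclass
class ARModel:
    """y_t = sum_i w_i y_{t-i} + e_t, fit by least squares on one window."""

    coefficients: np.ndarray
    order: int
    residual_variance: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.order:
            raise ValueError("coefficient count must equal order")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")


@dataclass
class ControlState:
    vx: float
    vy: float
    left_feature: float
    right_feature: float
    left_z: float
    right_z: float
    timestamp: float
    warmup: bool = False


def condition(recording: EEGRecording, config: DecoderConfig) -> EEGRecording:
    """Zero-phase bandpass plus 60 Hz notch, per channel, length-preserving."""
    fs = recording.sampling_rate
    config.validate_rate(fs)
    lo, hi = config.bandpass
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    b, a = _sig.iirnotch(config.notch_freq, config.notch_q, fs=fs)
    # the narrow notch and the 0.5 Hz high-pass corner both have impulse
    # responses far longer than scipy's default padding
    pad = min(recording.n_samples - 1, int(2.0 * fs))
    out = _sig.sosfiltfilt(sos, recording.data, axis=1, padlen=pad)
    out = _sig.filtfilt(b, a, out, axis=1, padlen=pad)
    return EEGRecording(out, fs, recording.channel_labels, recording.start_time)


def small_laplacian(recording: EEGRecording, center: str,
                    config: DecoderConfig | None = None) -> np.ndarray:
    """Center channel minus the mean of its four mapped neighbours."""
    config = config or DecoderConfig()
    if center not in config.laplacian_map:
        raise ChannelNotFoundError(f"no Laplacian neighbour map for {center!r}")
    labels = recording.channel_labels
    missing = [c for c in [center] + list(config.laplacian_map[center])
               if c not in labels]
    if missing:
        raise ChannelNotFoundError(f"channels missing from recording: {missing}")
    neigh = np.stack([recording.channel(c) for c in config.laplacian_map[center]])
    return recording.channel(center) - neigh.mean(axis=0)


def fit_ar(window: np.ndarray, order: int, ridge: float = 1e-8) -> ARModel:
    """Least-squares (covariance-method) AR fit on one window.

    Minimizes the squared one-step prediction error over the window; this is
    the direct least-squares criterion on the data, not Yule-Walker.  A tiny
    ridge keeps the normal equations well conditioned.
    """
    y = np.asarray(window, dtype=float)
    if y.ndim != 1:
        raise ValueError("window must be 1-D")
    n = len(y)
    if n <= order:
        raise ValueError(f"window of {n} samples too short for order {order}")
    y = y - y.mean()
    var = float(np.mean(y * y))
    if var < 1e-30:
        return ARModel(np.zeros(order), order, var, degenerate=True)
    # design matrix of lagged samples: X[t, i] = y[t - 1 - i]
    X = np.column_stack([y[order - 1 - i:n - 1 - i] for i in range(order)])
    target = y[order:]
    A = X.T @ X + ridge * np.eye(order)
    w = np.linalg.solve(A, X.T @ target)
    resid = target - X @ w
    return ARModel(w, order, float(np.mean(resid * resid)))


def ar_spectrum(model: ARModel, freqs: np.ndarray,
                sampling_rate: float) -> np.ndarray:
    """Amplitude spectrum sqrt(sigma^2)/|1 - sum w_k e^{-i 2 pi f k / fs}|."""
    k = np.arange(1, model.order + 1)
    z = np.exp(-2j * math.pi * np.asarray(freqs)[:, None] * k[None, :] / sampling_rate)
    denom = np.abs(1.0 - z @ model.coefficients)
    denom = np.maximum(denom, 1e-12)
    return math.sqrt(max(model.residual_variance, 0.0)) / denom


def ar_band_amplitude(model: ARModel, band: tuple[float, float],
                      sampling_rate: float, bin_spacing: float = 1.0) -> float:
    """Mean amplitude of the AR spectrum over a fixed in-band frequency grid."""
    lo, hi = band
    if not (0.0 < lo < hi < sampling_rate / 2.0):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    freqs = np.arange(lo, hi + 1e-9, bin_spacing)
    return float(np.mean(ar_spectrum(model, freqs, sampling_rate)))


class RunningNorm:
    """Exponentially-weighted z-scoring with a configurable half-life.

    Mean and variance decay with factor ``lambda = 2**(-dt/halflife)`` per
    update; stats advance only when ``update=True`` (feedback periods).
    """

    def __init__(self, halflife: float, update_interval: float):
        if halflife <= 0 or update_interval <= 0:
            raise ValueError("halflife and update_interval must be positive")
        self.lam = 2.0 ** (-update_interval / halflife)
        self.mean = 0.0
        self.var = 0.0
        self.weight = 0.0  # total accumulated weight, for unbiased warm-up
        self.degenerate = False

    def __call__(self, x: float, update: bool = True) -> float:
        if update:
            lam = self.lam
            self.weight = lam * self.weight + 1.0
            # EW mean/var with bias-corrected effective weight
            alpha = 1.0 / self.weight
            delta = x - self.mean
            self.mean += alpha * delta
            self.var = (1.0 - alpha) * (self.var + alpha * delta * delta)
        sd = math.sqrt(self.var)
        if sd <= 0.0 or self.weight < 2.0:
            self.degenerate = True
            return 0.0
        self.degenerate = False
        return (x - self.mean) / sd


def control_signal(left_z: float, right_z: float,
                   gain_x: float = 1.0, gain_y: float = 1.0) -> tuple[float, float]:
    """Map hemispheric z-features to a velocity command.

    Right-hand imagery (left-hemisphere ERD, left_z < 0) drives vx > 0;
    both-hands (both z < 0) drives vy > 0 (up); relaxation (both z > 0,
    ERS) drives vy < 0 (down).
    """
    if not (math.isfinite(left_z) and math.isfinite(right_z)):
        raise ValueError("z-features must be finite")
    vx = gain_x * (right_z - left_z)
    vy = gain_y * (-(left_z + right_z) / 2.0)
    return vx, vy


class OnlineDecoder:
    """Streaming decoder emitting one :class:`ControlState` per update interval.

    Feed raw multichannel blocks with :meth:`process`; states are produced
    whenever another ``update_interval`` of samples has accumulated and at
    least one full analysis window is buffered.
    """

    def __init__(self, config: DecoderConfig, sampling_rate: float,
                 channel_labels: tuple[str, ...]):
        config.validate_rate(sampling_rate)
        self.config = config
        self.fs = sampling_rate
        self.labels = tuple(channel_labels)
        for center, neigh in config.laplacian_map.items():
            missing = [c for c in [center] + list(neigh) if c not in self.labels]
            if missing:
                raise ChannelNotFoundError(
                    f"channels missing for Laplacian at {center}: {missing}")
        self.win = int(round(config.window_length * sampling_rate))
        self.hop = int(round(config.update_interval * sampling_rate))
        # keep some context beyond the window so zero-phase filtering of the
        # analysis window is not dominated by edge transients
        self.buf_len = self.win + 4 * self.hop + 200
        self._buf = np.zeros((len(self.labels), 0))
        self._since_update = 0
        self._samples_seen = 0
        self.norm_left = RunningNorm(config.normalizer_halflife, config.update_interval)
        self.norm_right = RunningNorm(config.normalizer_halflife, config.update_interval)
        self._last_state = ControlState(0, 0, 0, 0, 0, 0, 0.0, warmup=True)
        lo, hi = config.bandpass
        self._sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate,
                                output="sos")
        self._notch = _sig.iirnotch(config.notch_freq, config.notch_q,
                                    fs=sampling_rate)

    def _features(self) -> tuple[float, float]:
        cfg = self.config
        seg = self._buf
        # Laplacian first (linear, commutes with temporal filtering) so only
        # two signals need conditioning
        rec = EEGRecording(seg, self.fs, self.labels)
        feats = []
        pad = min(seg.shape[1] - 1, 2 * self.win)
        for center in ("C3", "C4"):
            lap = small_laplacian(rec, center, cfg)
            x = _sig.sosfiltfilt(self._sos, lap, padlen=pad)
            x = _sig.filtfilt(*self._notch, x, padlen=pad)
            model = fit_ar(x[-self.win:], cfg.ar_order)
            feats.append(ar_band_amplitude(
                model, (cfg.band_low, cfg.band_high), self.fs,
                cfg.spectrum_bin_spacing))
        return feats[0], feats[1]

    def process(self, block: np.ndarray, feedback: bool = True) -> list[ControlState]:
        """Append a channels x samples block; return newly emitted states."""
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != len(self.labels):
            raise ValueError("block channel count mismatch")
        self._buf = np.concatenate([self._buf, block], axis=1)[:, -self.buf_len:]
        self._since_update += block.shape[1]
        self._samples_seen += block.shape[1]
        out: list[ControlState] = []
        while self._since_update >= self.hop:
            self._since_update -= self.hop
            emitted_at = (self._samples_seen - self._since_update) / self.fs
            if self._buf.shape[1] < self.win:
                st = ControlState(self._last_state.vx, self._last_state.vy,
                                  self._last_state.left_feature,
                                  self._last_state.right_feature,
                                  self._last_state.left_z, self._last_state.right_z,
                                  emitted_at, warmup=True)
                out.append(st)
                continue
            lf, rf = self._features()
            lz = self.norm_left(lf, update=feedback)
            rz = self.norm_right(rf, update=feedback)
            warm = self.norm_left.degenerate or self.norm_right.degenerate
            vx, vy = control_signal(lz, rz, self.config.gain_x, self.config.gain_y)
            st = ControlState(vx, vy, lf, rf, lz, rz, emitted_at, warmup=warm)
            self._last_state = st
            out.append(st)
        return out
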