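"""Offline ERD/ERS time-frequency quantification with bootstrap masking.

Per frequency bin: zero-phase bandpass, per-trial segmentation around the
movement-onset cue, linear detrending, sample-wise squaring, short temporal
smoothing and trial averaging yield a band power course; percent change
against a pre-cue baseline gives ERD (negative) / ERS (positive).  Trial
resampling provides a percentile confidence interval per time-frequency
cell; cells whose interval covers zero are masked out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .synthetic import EEGRecording, TrialEvents, ImageryClass


def _default_bins() -> tuple[tuple[float, float], ...]:
    # 1 Hz-spaced, 3 Hz-wide overlapping bins tiling 8-26 Hz
    return tuple((float(lo), float(lo) + 3.0) for lo in range(8, 24))


@dataclass(frozen=True)
class ERDParams:
    freq_bins: tuple[tuple[float, float], ...] = field(default_factory=_default_bins)
    baseline_window: tuple[float, float] = (-4.5, -3.0)  # s, relative to cue
    analysis_window: tuple[float, float] = (-4.5, 4.0)
    n_boot: int = 1000
    alpha: float = 0.05
    detrend: str = "linear"          # none | constant | linear
    smooth: float = 0.100            # s, moving-average width over squared samples
    time_step: float = 0.050         # s, resolution of the output time axis
    cue: str = "feedback_onset"      # event field defining t = 0

    def __post_init__(self) -> None:
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede the cue")
        if self.detrend not in ("none", "constant", "linear"):
            raise ValueError("detrend must be none, constant or linear")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def for_cursor(cls, **kw) -> "ERDParams":
        """Cursor paradigm: target at -3 s, baseline -4.5 to -3 s."""
        return cls(baseline_window=(-4.5, -3.0), **kw)

    @classmethod
    def for_robot(cls, **kw) -> "ERDParams":
        """Robot paradigm: target at -2.5 s, baseline -4 to -2.5 s."""
        return cls(baseline_window=(-4.0, -2.5), analysis_window=(-4.0, 4.0), **kw)


@dataclass
class ERDMap:
    """Percent power change, time x frequency, with a significance mask."""

    values: np.ndarray           # (n_times, n_bins), % change
    mask: np.ndarray             # bool, True = CI excludes 0
    time_axis: np.ndarray        # s relative to cue
    freq_bins: tuple[tuple[float, float], ...]
    condition: ImageryClass | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if (self.values < -100.0 - 1e-9).any():
            raise ValueError("percent power change cannot fall below -100")

    def masked_values(self) -> np.ndarray:
        """Map with non-significant cells zeroed (export convention)."""
        return np.where(self.mask, self.values, 0.0)

    def cell_mean(self, tmin: float, tmax: float,
                  fmin: float, fmax: float) -> float:
        """Mean value over cells whose bin center lies in [fmin, fmax] and
        time in [tmin, tmax]."""
        centers = np.array([(lo + hi) / 2.0 for lo, hi in self.freq_bins])
        fsel = (centers >= fmin) & (centers <= fmax)
        tsel = (self.time_axis >= tmin) & (self.time_axis <= tmax)
        return float(self.values[np.ix_(tsel, fsel)].mean())


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average normalized by the actual window overlap, so
    edge samples are unbiased rather than dragged toward zero."""
    if width <= 1:
        return x
    kern = np.ones(width)
    norm = np.convolve(np.ones(x.shape[-1]), kern, mode="same")
    return np.apply_along_axis(
        lambda r: np.convolve(r, kern, mode="same") / norm, -1, x)


def trial_power_courses(recording: EEGRecording, events: TrialEvents,
                        band: tuple[float, float], params: ERDParams,
                        channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial smoothed band power, (n_trials, n_times), plus time axis.

    Trials whose analysis window extends beyond the recording are dropped;
    an error is raised if none survive.
    """
    fs = recording.sampling_rate
    filtered = _bandpass(recording.channel(channel), band, fs)
    t0, t1 = params.analysis_window
    n_seg = int(round((t1 - t0) * fs))
    step = max(int(round(params.time_step * fs)), 1)
    width = max(int(round(params.smooth * fs)), 1)
    segs = []
    for ev in events:
        cue = getattr(ev, params.cue)
        i0 = int(round((cue - recording.start_time + t0) * fs))
        if i0 < 0 or i0 + n_seg > recording.n_samples:
            continue
        segs.append(filtered[i0:i0 + n_seg])
    if len(segs) < 2:
        raise ValueError("fewer than 2 trials fit inside the recording")
    x = np.stack(segs)
    if params.detrend == "linear":
        x = _sig.detrend(x, axis=1, type="linear")
    elif params.detrend == "constant":
        x = _sig.detrend(x, axis=1, type="constant")
    power = _smooth(x * x, width)
    power = power[:, ::step]
    times = t0 + np.arange(power.shape[1]) * step / fs
    return power, times


def compute_power_course(recording: EEGRecording, events: TrialEvents,
                         band: tuple[float, float], params: ERDParams,
                         channel: str = "C3") -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged band power versus time for one frequency bin."""
    courses, times = trial_power_courses(recording, events, band, params, channel)
    return courses.mean(axis=0), times


def erd_percent(power_course: np.ndarray, time_axis: np.ndarray,
                baseline_window: tuple[float, float]) -> np.ndarray:
    """100 * (A_j - R) / R with R the mean power over the baseline window."""
    sel = (time_axis >= baseline_window[0]) & (time_axis <= baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window is empty on this time axis")
    R = float(np.asarray(power_course)[..., sel].mean())
    if R <= 0.0:
        raise ValueError("degenerate baseline: zero reference power")
    return 100.0 * (np.asarray(power_course) - R) / R


def _boot_erd(courses: np.ndarray, time_axis: np.ndarray,
              params: ERDParams, rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n_times[, n_bins]) bootstrap replicates of the ERD course."""
    n = courses.shape[0]
    flat = courses.reshape(n, -1)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=params.n_boot)
    means = (counts @ flat) / n
    means = means.reshape((params.n_boot,) + courses.shape[1:])
    sel = (time_axis >= params.baseline_window[0]) & \
          (time_axis <= params.baseline_window[1])
    # per-replicate (and, for 3-D input, per-bin) baseline reference
    R = means[:, sel].mean(axis=1)
    R = np.where(R <= 0, np.nan, R)
    return 100.0 * (means - R[:, None]) / R[:, None]


def bootstrap_mask(courses: np.ndarray, time_axis: np.ndarray,
                   params: ERDParams,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Boolean mask where the (1 - alpha) percentile CI of ERD excludes 0.

    ``courses`` is per-trial power, (n_trials, n_times) or
    (n_trials, n_times, n_bins); resampling is over trials.
    """
    if params.n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    courses = np.asarray(courses)
    if courses.shape[0] < 2:
        raise ValueError("bootstrap requires at least 2 trials")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reps = _boot_erd(courses, time_axis, params, rng)
    lo = np.nanpercentile(reps, 100.0 * params.alpha / 2.0, axis=0)
    hi = np.nanpercentile(reps, 100.0 * (1.0 - params.alpha / 2.0), axis=0)
    return (lo > 0.0) | (hi < 0.0)


def erd_map(recording: EEGRecording, events: TrialEvents, params: ERDParams,
            channel: str, condition: ImageryClass | None = None,
            rng: np.random.Generator | int | None = None) -> ERDMap:
    """Full time-frequency ERD/ERS map with bootstrap mask for one channel."""
    per_bin = []
    times = None
    for band in params.freq_bins:
        courses, times = trial_power_courses(recording, events, band, params,
                                             channel)
        per_bin.append(courses)
    cube = np.stack(per_bin, axis=-1)        # (n_trials, n_times, n_bins)
    mean_power = cube.mean(axis=0)
    sel = (times >= params.baseline_window[0]) & (times <= params.baseline_window[1])
    R = mean_power[sel].mean(axis=0)         # per-bin reference
    if (R <= 0).any():
        raise ValueError("degenerate baseline: zero reference power")
    values = 100.0 * (mean_power - R[None, :]) / R[None, :]
    mask = bootstrap_mask(cube, times, params, rng)
    return ERDMap(values, mask, times, tuple(params.freq_bins),
                  condition=condition, channel=channel)


def condition_maps(recording: EEGRecording, events: TrialEvents,
                   params: ERDParams, channels: tuple[str, ...] = ("C3", "C4"),
                   rng: np.random.Generator | int | None = None
                   ) -> dict[tuple[ImageryClass, str], ERDMap]:
    """One map per (condition x channel) over the conditions present."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    present = []
    for ev in events:
        if ev.target_class not in present:
            present.append(ev.target_class)
    out: dict[tuple[ImageryClass, str], ERDMap] = {}
    for cond in present:
        sub = TrialEvents([ev for ev in events if ev.target_class is cond])
        for ch in channels:
            out[(cond, ch)] = erd_map(recording, sub, params, ch,
                                      condition=cond, rng=rng)
    return out


def recover_erd_depth(erd_value_percent: float) -> float:
    """Invert ERD% -> amplitude attenuation d via d = 1 - sqrt(1 + ERD/100)."""
    return 1.0 - math.sqrt(max(1.0 + erd_value_percent / 100.0, 0.0))
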