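"""Seeded synthetic EEG with task-locked mu-rhythm modulation.

The simulated subject produces a narrowband mu oscillation (~10-14 Hz) over
each sensorimotor cortex whose amplitude is attenuated (ERD) or boosted (ERS)
according to the imagined movement class, on top of 1/f background noise and
common-mode 60 Hz line contamination.  Output is available both as offline
trial/session recordings and as a phase-continuous block stream for
closed-loop use.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.random import Generator, PCG64, SeedSequence
from scipy import signal as _sig


class ImageryClass(enum.Enum):
    """The five mental states driving control (REST = no task)."""

    LEFT_HAND = "LEFT_HAND"
    RIGHT_HAND = "RIGHT_HAND"
    BOTH_HANDS = "BOTH_HANDS"
    RELAX = "RELAX"
    REST = "REST"


#: minimal montage: the two control electrodes plus the four small-Laplacian
#: neighbours of each.
C3_NEIGHBORS = ("FC3", "CP3", "C1", "C5")
C4_NEIGHBORS = ("FC4", "CP4", "C2", "C6")
DEFAULT_MONTAGE = ("C3",) + C3_NEIGHBORS + ("C4",) + C4_NEIGHBORS


@dataclass(frozen=True)
class SimulationParams:
    """Free parameters of the simulated subject.

    ``erd_depth`` is the fractional mu-amplitude attenuation during
    event-related desynchronization; ``ers_gain`` the fractional increase
    during synchronization.  ``leakage`` scales the copy of each hemispheric
    mu source seen by its neighbour electrodes, which is what the small
    Laplacian exists to reject.
    """

    sampling_rate: float = 1000.0
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    mu_center_freq: float = 12.0
    mu_baseline_amp: float = 10.0
    erd_depth: float = 0.5
    ers_gain: float = 0.2
    background_exponent: float = 1.0
    background_amp: float = 1.0
    line_noise_amp: float = 5.0
    line_freq: float = 60.0
    modulation_latency: float = 0.5
    leakage: float = 0.5
    mu_freq_jitter: float = 0.3
    jitter_timescale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.ers_gain < 0.0:
            raise ValueError("ers_gain must be non-negative")
        if self.sampling_rate <= 2.0 * max(self.line_freq, self.mu_center_freq):
            raise ValueError("sampling_rate must exceed twice the highest generated frequency")
        for ch in ("C3",) + C3_NEIGHBORS + ("C4",) + C4_NEIGHBORS:
            if ch not in self.channel_labels:
                raise ValueError(f"channel_labels must include {ch}")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class EEGRecording:
    """Multichannel signal matrix, channels x samples, in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("row count must equal number of channel labels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class TrialTiming:
    """Durations (s) of the four phases of one trial."""

    iti: float = 2.0
    prefeedback: float = 3.0
    feedback: float = 4.0
    postfeedback: float = 1.0

    def __post_init__(self) -> None:
        for name in ("iti", "prefeedback", "feedback", "postfeedback"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} duration must be >= 0")

    @property
    def total(self) -> float:
        return self.iti + self.prefeedback + self.feedback + self.postfeedback

    def scaled(self, factor: float) -> "TrialTiming":
        return TrialTiming(self.iti * factor, self.prefeedback * factor,
                           self.feedback * factor, self.postfeedback * factor)


class Outcome(enum.Enum):
    HIT = "HIT"
    MISS = "MISS"
    ABORT = "ABORT"
    NA = "NA"


@dataclass
class TrialEvent:
    """Phase timestamps (absolute seconds) and labels for one trial."""

    trial_index: int
    target_class: ImageryClass
    iti_onset: float
    prefeedback_onset: float
    feedback_onset: float
    feedback_end: float
    trial_end: float
    outcome: Outcome = Outcome.NA

    def __post_init__(self) -> None:
        ts = (self.iti_onset, self.prefeedback_onset, self.feedback_onset,
              self.feedback_end, self.trial_end)
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("trial phase timestamps must be non-decreasing")


class TrialEvents:
    """Ordered, non-overlapping collection of :class:`TrialEvent` rows."""

    def __init__(self, trials: list[TrialEvent]):
        trials = sorted(trials, key=lambda t: t.iti_onset)
        for a, b in zip(trials, trials[1:]):
            if b.iti_onset < a.trial_end - 1e-9:
                raise ValueError("trials overlap")
        self.trials = trials

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> TrialEvent:
        return self.trials[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialEvents) and self.trials == other.trials


def class_modulation(imagery: ImageryClass,
                     params: SimulationParams) -> tuple[float, float]:
    """Multiplicative mu-amplitude factors (left hemisphere/C3, right/C4).

    Unilateral hand imagery attenuates the contralateral source; both hands
    attenuates both; relaxation boosts both; REST leaves both unchanged.
    """
    d, g = params.erd_depth, params.ers_gain
    table = {
        ImageryClass.RIGHT_HAND: (1.0 - d, 1.0),
        ImageryClass.LEFT_HAND: (1.0, 1.0 - d),
        ImageryClass.BOTH_HANDS: (1.0 - d, 1.0 - d),
        ImageryClass.RELAX: (1.0 + g, 1.0 + g),
        ImageryClass.REST: (1.0, 1.0),
    }
    return table[imagery]


def _fractional_diff_coeffs(beta: float, n_taps: int = 64) -> np.ndarray:
    # AR coefficients of the fractional integrator whose output spectrum
    # falls as 1/f^beta when driven with white noise (Kasdin recursion).
    a = np.empty(n_taps)
    a[0] = 1.0
    for k in range(1, n_taps):
        a[k] = (k - 1 - beta / 2.0) * a[k - 1] / k
    return a


class MuStreamGenerator:
    """Stateful phase-continuous generator.

    All random components are drawn from independent per-component RNG
    streams spawned from the root seed, so output is invariant to how the
    request is chunked into blocks: two consecutive ``next_block`` calls
    concatenate to exactly the single larger call.
    """

    def __init__(self, params: SimulationParams, seed_key: tuple[int, ...] = ()):
        self.params = params
        ss = SeedSequence((params.seed,) + tuple(seed_key))
        kids = ss.spawn(4)
        self._bg_rng: Generator = Generator(PCG64(kids[0]))
        self._jit_rng_l: Generator = Generator(PCG64(kids[1]))
        self._jit_rng_r: Generator = Generator(PCG64(kids[2]))
        init_rng = Generator(PCG64(kids[3]))
        n_ch = len(params.channel_labels)
        self._fd = _fractional_diff_coeffs(params.background_exponent)
        self._bg_zi = np.zeros((n_ch, len(self._fd) - 1))
        # random initial phase and stationary jitter state: oscillations must
        # not be phase-locked across trials or ERD trial-averaging breaks
        self._phase = init_rng.uniform(0.0, 2.0 * math.pi, size=2)
        self._jitter = init_rng.normal(0.0, params.mu_freq_jitter, size=2)
        self._counter = 0  # samples generated so far
        # modulation ramp state: linear from _ramp_from to _target over
        # _ramp_total samples, _ramp_done of which have been emitted
        self._factors = np.array([1.0, 1.0])
        self._target = np.array([1.0, 1.0])
        self._ramp_from = np.array([1.0, 1.0])
        self._ramp_total = 0
        self._ramp_done = 0
        self._chan_idx = {c: i for i, c in enumerate(params.channel_labels)}

    # -- imagery control -------------------------------------------------
    def set_imagery(self, imagery: ImageryClass,
                    latency: float | None = None) -> None:
        """Begin ramping the modulation toward ``imagery`` over the latency."""
        p = self.params
        lat = p.modulation_latency if latency is None else latency
        self._target = np.array(class_modulation(imagery, p))
        self._ramp_from = self._factors.copy()
        self._ramp_total = max(int(round(lat * p.sampling_rate)), 0)
        self._ramp_done = 0
        if self._ramp_total == 0:
            self._factors = self._target.copy()

    def _envelope(self, n: int) -> np.ndarray:
        """(n, 2) modulation factors for the next n samples, advancing state."""
        env = np.empty((n, 2))
        i = 0
        remaining = self._ramp_total - self._ramp_done
        if remaining > 0:
            k = min(remaining, n)
            # interpolate against the fixed ramp origin so values do not
            # depend on where block boundaries fall
            steps = (np.arange(self._ramp_done + 1, self._ramp_done + k + 1)
                     / self._ramp_total)
            env[:k] = (self._ramp_from[None, :]
                       + steps[:, None] * (self._target - self._ramp_from)[None, :])
            self._ramp_done += k
            self._factors = (self._target.copy() if self._ramp_done == self._ramp_total
                             else env[k - 1].copy())
            i = k
        if i < n:
            env[i:] = self._factors[None, :]
        return env

    def burn_in(self, duration: float = 1.0) -> None:
        """Generate and discard ``duration`` seconds so the background
        filter state is stationary before the first emitted sample."""
        n = int(round(duration * self.params.sampling_rate))
        if n > 0:
            self.next_block(n)
            self._counter -= n

    # -- block generation ------------------------------------------------
    def next_block(self, n_samples: int) -> EEGRecording:
        if n_samples <= 0:
            raise ValueError("n_samples must be positive")
        env = self._envelope(n_samples)
        return self._render(env)

    def _render(self, env: np.ndarray) -> EEGRecording:
        p = self.params
        n = env.shape[0]
        fs = p.sampling_rate
        n_ch = len(p.channel_labels)
        start = self._counter / fs

        # background: per-channel 1/f-filtered white noise (streaming state)
        white = self._bg_rng.standard_normal((n, n_ch)).T * p.background_amp
        bg, self._bg_zi = _sig.lfilter([1.0], self._fd, white, axis=1, zi=self._bg_zi)

        # mu oscillators with slowly wandering instantaneous frequency
        rho = math.exp(-1.0 / (p.jitter_timescale * fs))
        innov_sd = p.mu_freq_jitter * math.sqrt(1.0 - rho * rho)
        mu = np.empty((2, n))
        for s, rng in ((0, self._jit_rng_l), (1, self._jit_rng_r)):
            eps = rng.standard_normal(n) * innov_sd
            phase = np.empty(n)
            prev = self._jitter[s]
            ph = self._phase[s]
            step = 2.0 * math.pi / fs
            # strictly sequential recursions (cumsum would accumulate in a
            # different order and break bitwise chunk-invariance)
            for k in range(n):
                prev = rho * prev + eps[k]
                ph = ph + step * (p.mu_center_freq + prev)
                phase[k] = ph
            self._jitter[s] = prev
            self._phase[s] = ph
            mu[s] = p.mu_baseline_amp * env[:, s] * np.sin(phase)

        # common-mode line noise (same phase on every channel)
        t = (self._counter + np.arange(n)) / fs
        line = p.line_noise_amp * np.sin(2.0 * math.pi * p.line_freq * t)

        data = bg + line[None, :]
        ci = self._chan_idx
        data[ci["C3"]] += mu[0]
        data[ci["C4"]] += mu[1]
        for nb in C3_NEIGHBORS:
            data[ci[nb]] += p.leakage * mu[0]
        for nb in C4_NEIGHBORS:
            data[ci[nb]] += p.leakage * mu[1]

        self._counter += n
        return EEGRecording(data, fs, p.channel_labels, start_time=start)


def generate_background(duration: float, params: SimulationParams) -> EEGRecording:
    """1/f Gaussian background plus 60 Hz line noise; no mu sources."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    quiet = replace(params, mu_baseline_amp=0.0)
    gen = MuStreamGenerator(quiet)
    n = int(round(duration * params.sampling_rate))
    return gen.next_block(n)


def _n_samples(duration: float, fs: float) -> int:
    return int(round(duration * fs))


def generate_trial(imagery: ImageryClass, timing: TrialTiming,
                   params: SimulationParams, trial_index: int = 0,
                   start_time: float = 0.0) -> tuple[EEGRecording, TrialEvent]:
    """One trial: ITI, prefeedback (cue), feedback, postfeedback.

    Modulation ramps up over ``modulation_latency`` starting at the cue
    (prefeedback onset) and ramps back down after feedback ends.  A per-trial
    RNG substream keyed on ``trial_index`` makes trials reproducible
    independently of generation order.
    """
    fs = params.sampling_rate
    gen = MuStreamGenerator(params, seed_key=(1, trial_index))
    gen.burn_in()
    n_iti = _n_samples(timing.iti, fs)
    n_pre = _n_samples(timing.prefeedback, fs)
    n_fb = _n_samples(timing.feedback, fs)
    n_post = _n_samples(timing.postfeedback, fs)

    blocks = []
    if n_iti:
        blocks.append(gen.next_block(n_iti).data)
    gen.set_imagery(imagery)
    if n_pre + n_fb:
        blocks.append(gen.next_block(n_pre + n_fb).data)
    gen.set_imagery(ImageryClass.REST)
    if n_post:
        blocks.append(gen.next_block(n_post).data)

    data = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(params.channel_labels), 0))
    rec = EEGRecording(data, fs, params.channel_labels, start_time=start_time)
    ev = TrialEvent(
        trial_index=trial_index,
        target_class=imagery,
        iti_onset=start_time,
        prefeedback_onset=start_time + n_iti / fs,
        feedback_onset=start_time + (n_iti + n_pre) / fs,
        feedback_end=start_time + (n_iti + n_pre + n_fb) / fs,
        trial_end=start_time + (n_iti + n_pre + n_fb + n_post) / fs,
    )
    return rec, ev


def generate_session(trial_plan: list[tuple[ImageryClass, TrialTiming]],
                     params: SimulationParams) -> tuple[EEGRecording, TrialEvents]:
    """Continuous multi-trial recording with an aligned event table.

    One phase-continuous generator spans the whole session (modulation ramps
    at the cue and back after feedback); stitching independently generated
    trials would put discontinuities at every trial seam, which bandpass
    filtering downstream turns into spurious broadband power.
    """
    if not trial_plan:
        raise ValueError("trial plan must be non-empty")
    fs = params.sampling_rate
    gen = MuStreamGenerator(params)
    gen.burn_in()
    datas, events = [], []
    counter = 0
    for idx, (imagery, timing) in enumerate(trial_plan):
        n_iti = _n_samples(timing.iti, fs)
        n_pre = _n_samples(timing.prefeedback, fs)
        n_fb = _n_samples(timing.feedback, fs)
        n_post = _n_samples(timing.postfeedback, fs)
        if n_iti:
            datas.append(gen.next_block(n_iti).data)
        gen.set_imagery(imagery)
        if n_pre + n_fb:
            datas.append(gen.next_block(n_pre + n_fb).data)
        gen.set_imagery(ImageryClass.REST)
        if n_post:
            datas.append(gen.next_block(n_post).data)
        events.append(TrialEvent(
            trial_index=idx,
            target_class=imagery,
            iti_onset=counter / fs,
            prefeedback_onset=(counter + n_iti) / fs,
            feedback_onset=(counter + n_iti + n_pre) / fs,
            feedback_end=(counter + n_iti + n_pre + n_fb) / fs,
            trial_end=(counter + n_iti + n_pre + n_fb + n_post) / fs,
        ))
        counter += n_iti + n_pre + n_fb + n_post
    data = np.concatenate(datas, axis=1)
    return (EEGRecording(data, fs, params.channel_labels),
            TrialEvents(events))
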