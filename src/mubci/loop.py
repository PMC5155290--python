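"""Closed-loop glue: a simulated subject driving the task engine.

The subject holds an intention policy (imagine toward the cued target,
rest inside the hover area), emits synthetic EEG accordingly, and the
online decoder turns that EEG into the velocity command the engine
integrates — the full loop the study's participants closed.
"""

from __future__ import annotations

import numpy as np

from .decoder import DecoderConfig, OnlineDecoder
from .synthetic import ImageryClass, MuStreamGenerator, SimulationParams, Outcome
from .task import TaskConfig, TargetSpec, TrialResult, run_trial, lr_layout


class SimulatedSubjectPolicy:
    """Task-engine control source backed by synthetic EEG plus the decoder.

    ``intent="cued"`` imagines the class matching the direction of the cued
    target and rests once inside the hover area; ``intent="rest"`` never
    engages (the resting protocol used for empirical chance levels).
    """

    def __init__(self, sim_params: SimulationParams, decoder_config: DecoderConfig,
                 intent: str = "cued", calibration: float = 15.0):
        if intent not in ("cued", "rest"):
            raise ValueError("intent must be 'cued' or 'rest'")
        self.params = sim_params
        self.intent = intent
        self.gen = MuStreamGenerator(sim_params)
        self.decoder = OnlineDecoder(decoder_config, sim_params.sampling_rate,
                                     sim_params.channel_labels)
        self.block = int(round(decoder_config.update_interval
                               * sim_params.sampling_rate))
        self._imagery = ImageryClass.REST
        self._target = np.zeros(2)
        self._kind = "planar"
        self._config: TaskConfig | None = None
        if calibration > 0:
            self._stream(calibration, feedback=True)

    def _stream(self, duration: float, feedback: bool) -> None:
        n_blocks = int(round(duration * self.params.sampling_rate)) // self.block
        for _ in range(max(n_blocks, 1)):
            self.decoder.process(self.gen.next_block(self.block).data,
                                 feedback=feedback)

    def _set_imagery(self, imagery: ImageryClass) -> None:
        if imagery is not self._imagery:
            self.gen.set_imagery(imagery)
            self._imagery = imagery

    def begin_step(self, kind: str, target: np.ndarray, config: TaskConfig) -> None:
        self._kind = kind
        self._target = np.asarray(target, dtype=float)
        self._config = config
        # prefeedback: the cue is visible, imagery starts, cursor is frozen
        self._set_imagery(self._choose(np.zeros(2) if kind == "planar"
                                       else np.array([0.0, config.approach_height])))
        if config.prefeedback > 0:
            self._stream(config.prefeedback, feedback=False)

    def _choose(self, pos: np.ndarray) -> ImageryClass:
        if self.intent == "rest":
            return ImageryClass.REST
        cfg = self._config
        if self._kind == "vertical":
            z = pos[1]
            if z <= cfg.grasp_tolerance * 0.8:
                return ImageryClass.REST
            return ImageryClass.RELAX          # relax -> downward drive
        err = self._target - pos
        if float(np.linalg.norm(err)) <= cfg.hover_radius * 0.8:
            return ImageryClass.REST
        if abs(err[0]) >= abs(err[1]):
            return ImageryClass.RIGHT_HAND if err[0] > 0 else ImageryClass.LEFT_HAND
        return ImageryClass.BOTH_HANDS if err[1] > 0 else ImageryClass.RELAX

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        self._set_imagery(self._choose(np.asarray(pos, dtype=float)))
        states = self.decoder.process(self.gen.next_block(self.block).data,
                                      feedback=True)
        st = states[-1] if states else self.decoder._last_state
        return np.array([st.vx, st.vy])


def run_lr_session(n_trials: int, sim_params: SimulationParams,
                   decoder_config: DecoderConfig, task_config: TaskConfig,
                   seed: int, intent: str = "cued",
                   layout: list[TargetSpec] | None = None) -> list[TrialResult]:
    """Closed-loop 1-D left/right session with uniformly cued targets."""
    rng = np.random.default_rng(seed)
    subject = SimulatedSubjectPolicy(sim_params.with_seed(int(rng.integers(2**31))),
                                     decoder_config, intent=intent)
    layout = layout if layout is not None else lr_layout()
    results = []
    for _ in range(n_trials):
        cued = int(rng.integers(len(layout)))
        results.append(run_trial(subject, layout, cued, task_config, dims=1,
                                 record_trajectory=False))
    return results
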