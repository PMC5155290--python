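"""Performance accounting: PVC, chance levels, run summaries.

PVC (percent valid correct) is hits over hits-plus-misses; aborted trials
(neither the correct nor a wrong target acquired before the feedback
timeout) are excluded.  Chance level is estimated by Monte-Carlo with an
unbiased control policy over the same task engine the subject uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import Outcome
from .task import (TaskConfig, TargetSpec, TrialResult, SequenceResult,
                   RandomWalkPolicy, run_trial, lr_layout, fixed4_layout,
                   fixed5_layout)


@dataclass
class RunSummary:
    n_hit: int
    n_miss: int
    n_abort: int
    pvc: float | None            # None = undefined (no valid trials)
    mean_time_to_hit: float | None
    blocks_completed: int
    run_duration: float


def pvc(results: list[TrialResult]) -> float | None:
    """Percent valid correct; ``None`` when every trial aborted."""
    n_hit = sum(r.outcome is Outcome.HIT for r in results)
    n_miss = sum(r.outcome is Outcome.MISS for r in results)
    if n_hit + n_miss == 0:
        return None
    return 100.0 * n_hit / (n_hit + n_miss)


@dataclass
class ChanceResult:
    pvc: float | None
    n_trials: int
    n_valid: int
    outcomes: list[TrialResult]
    run_hit_counts: list[int]     # hits per consecutive block of `run_length`
    ci_low: float | None = None
    ci_high: float | None = None


STAGE_LAYOUTS = {
    "cursor1d": (lr_layout, 1),
    "cursor2d": (fixed4_layout, 2),
    "cursor5": (fixed5_layout, 2),
}


def no_hover(config: TaskConfig) -> TaskConfig:
    """Variant selecting a target on first disc entry (no dwell)."""
    return replace(config, hover_duration=0.0)


def chance_level(layout: list[TargetSpec], config: TaskConfig, n_trials: int,
                 seed: int, policy=None, dims: int = 2,
                 run_length: int = 25, n_boot_ci: int = 500) -> ChanceResult:
    """Monte-Carlo chance PVC under an unbiased control policy.

    The cued target is drawn uniformly per trial, so for any selection
    dynamics independent of the cue the expected PVC is 100/n_targets.
    """
    if n_trials < 100:
        import warnings
        warnings.warn("fewer than 100 trials gives a noisy chance estimate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    if policy is None:
        policy = RandomWalkPolicy(rng=np.random.default_rng(rng.integers(2**63)))
    results = []
    for _ in range(n_trials):
        cued = int(rng.integers(len(layout)))
        results.append(run_trial(policy, layout, cued, config, dims=dims,
                                 record_trajectory=False))
    valid = [r for r in results if r.outcome is not Outcome.ABORT]
    hits = np.array([r.outcome is Outcome.HIT for r in results])
    run_hits = [int(hits[i:i + run_length].sum())
                for i in range(0, n_trials, run_length)]
    p = pvc(results)
    lo = hi = None
    if valid and p is not None:
        vh = np.array([r.outcome is Outcome.HIT for r in valid], dtype=float)
        boots = rng.multinomial(len(vh), np.full(len(vh), 1 / len(vh)),
                                size=n_boot_ci) @ vh / len(vh)
        lo, hi = (100.0 * float(np.percentile(boots, q)) for q in (2.5, 97.5))
    return ChanceResult(p, n_trials, len(valid), results, run_hits, lo, hi)


def summarize_run(results: list[TrialResult],
                  sequences: list[SequenceResult] | None = None,
                  block_cap: int | None = None) -> RunSummary:
    """Aggregate counts, PVC, mean time-to-hit and blocks completed."""
    n_hit = sum(r.outcome is Outcome.HIT for r in results)
    n_miss = sum(r.outcome is Outcome.MISS for r in results)
    n_abort = sum(r.outcome is Outcome.ABORT for r in results)
    hit_times = [r.time_to_hit for r in results if r.outcome is Outcome.HIT]
    blocks = sum(s.completed for s in sequences) if sequences else 0
    if block_cap is not None:
        blocks = min(blocks, block_cap)
    duration = sum(r.time_to_hit for r in results)
    if sequences:
        duration = sum(s.total_time for s in sequences)
    return RunSummary(
        n_hit=n_hit, n_miss=n_miss, n_abort=n_abort, pvc=pvc(results),
        mean_time_to_hit=float(np.mean(hit_times)) if hit_times else None,
        blocks_completed=blocks, run_duration=duration)
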