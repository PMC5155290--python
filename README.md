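# mubci

A desk-testable, fully simulated closed-loop motor-imagery brain-computer
interface. The package contains everything needed to exercise a
sensorimotor-rhythm BCI without a subject or hardware:

- **`mubci.synthetic`** — a seeded "simulated subject": multichannel EEG with
  a narrowband mu rhythm (~10–14 Hz) over each sensorimotor cortex, 1/f
  background noise and common-mode 60 Hz line contamination. Unilateral hand
  imagery attenuates the contralateral source (ERD), both-hands imagery
  attenuates both, relaxation boosts both (ERS). Available as offline trial /
  session recordings and as a phase-continuous block stream whose output is
  bitwise independent of block chunking.
- **`mubci.decoder`** — the online control pipeline: zero-phase bandpass +
  60 Hz notch conditioning, small-Laplacian spatial filtering at C3/C4,
  sliding-window (400 ms) order-16 least-squares autoregressive spectral
  estimation, upper-mu band amplitude extraction, adaptive EWMA
  z-normalization, and a linear map to a 2-axis velocity command
  (left/right from the interhemispheric difference, up/down from the
  bilateral mean).
- **`mubci.task`** — discrete-time simulation of the cursor / robotic-arm
  tasks: square 32 × 32 cm workspace, hover-dwell target selection (3 cm
  disc, 2 s dwell, 12 s feedback timeout), reach-and-grasp and shelf
  reach-and-release sequences, a fast variant, quadrant-balanced random
  target placement with exclusion zones, and a speed-limited effector
  tracker.
- **`mubci.erd`** — offline ERD/ERS time–frequency quantification: per-bin
  bandpass → trial segmentation → detrending → squaring → smoothing → trial
  averaging, percent change against a pre-cue baseline, and a seeded
  trial-resampling bootstrap significance mask.
- **`mubci.metrics`** — PVC (percent valid correct, aborts excluded),
  run summaries, and Monte-Carlo chance-level estimation under unbiased
  control policies.
- **`mubci.loop`** — glue that closes the loop: an intention policy
  (imagine toward the cued target, rest inside the hover area, or rest
  always) drives the synthetic EEG, the decoder turns it into velocity, the
  task engine integrates it.

## CLI

All subcommands are seeded and reproducible from the logged config.

```bash
# write a synthetic 25-trial session (TSV or EDF) with its event table
mubci simulate --seed 7 --out-dir out/

# run a task stage under a policy: decoder (simulated subject), ideal, random
mubci run-loop --stage grasp4 --policy ideal --seed 1 --out-dir out/

# offline ERD/ERS maps with bootstrap masks
mubci erd-map --recording out/recording.tsv --events out/events.tsv \
    --paradigm cursor --n-boot 1000 --seed 1 --out-dir out/maps

# Monte-Carlo chance level with a bootstrap CI
mubci chance --stage cursor2d --no-hover --n 2000 --seed 1

# summarize a trial log
mubci report --trials out/trials.tsv
```

Exit codes: 0 ok, 2 bad arguments, 3 validation failure, 4 I/O failure.

## File formats

- Recordings: tab-separated text (channel-label header plus a metadata
  comment line; `.gz` supported) for lossless debugging, or 16-bit EDF.
- Events: TSV with columns `onset  duration  trial_index  label`, one row
  per trial phase, labels drawn from the imagery-class vocabulary.
- Configs: YAML mirroring the parameter dataclasses section by section;
  unknown keys are rejected.
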