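"""Format readers and writers: delimited recordings, EDF, event tables.

Delimited text is the lossless debug format (one header of channel labels,
one metadata comment line, one row per sample; ``.gz`` suffix compresses).
EDF is the interchange format: 16-bit integers against per-channel physical
ranges, so a round trip is exact only to one quantization step.
"""

from __future__ import annotations

import gzip
import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (EEGRecording, ImageryClass, Outcome, TrialEvent,
                        TrialEvents)

_META_PREFIX = "# mubci-recording"


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# delimited recordings

def write_recording(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".edf":
        write_edf(recording, path)
        return
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"{_META_PREFIX} sampling_rate={recording.sampling_rate!r} "
                 f"start_time={recording.start_time!r}\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.17g", delimiter="\t")


def read_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    if path.suffix == ".edf":
        return read_edf(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        meta = fh.readline().strip()
        if not meta.startswith(_META_PREFIX):
            raise ParseError(f"{path}: missing recording metadata header")
        kv = dict(tok.split("=", 1) for tok in meta[len(_META_PREFIX):].split())
        header = fh.readline().strip().split("\t")
        n_cols = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno} has {len(parts)} columns, "
                    f"header has {n_cols}")
            rows.append([float(p) for p in parts])
    data = np.asarray(rows, dtype=float).T if rows else np.zeros((n_cols, 0))
    return EEGRecording(data, float(kv["sampling_rate"]), tuple(header),
                        start_time=float(kv["start_time"]))


# ---------------------------------------------------------------------------
# minimal EDF (16-bit, continuous, 1 s data records)

def write_edf(recording: EEGRecording, path: str | Path) -> None:
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = math.ceil(recording.n_samples / fs) if recording.n_samples else 0
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :recording.n_samples] = recording.data

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None]
                       + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = _io.BytesIO()
    hdr.write(pad("0", 8))
    hdr.write(pad("mubci synthetic subject", 80))
    hdr.write(pad("mubci recording", 80))
    hdr.write(pad("01.01.00", 8))
    hdr.write(pad("00.00.00", 8))
    hdr.write(pad(str(256 * (1 + n_ch)), 8))
    hdr.write(pad("", 44))
    hdr.write(pad(str(n_rec), 8))
    hdr.write(pad("1", 8))
    hdr.write(pad(str(n_ch), 4))
    for lab in recording.channel_labels:
        hdr.write(pad(lab, 16))
    for _ in range(n_ch):
        hdr.write(pad("AgAgCl electrode", 80))
    for _ in range(n_ch):
        hdr.write(pad("uV", 8))
    for v in phys_min:
        hdr.write(pad(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        hdr.write(pad(f"{v:.8g}"[:8], 8))
    hdr.write(pad(str(dig_min), 8) * n_ch)
    hdr.write(pad(str(dig_max), 8) * n_ch)
    for _ in range(n_ch):
        hdr.write(pad("", 80))
    hdr.write(pad(str(fs), 8) * n_ch)
    hdr.write(pad("", 32) * n_ch)

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        n_rec = int(raw[236:244])
        dur = float(raw[244:252])
        n_ch = int(raw[252:256])
        off = 256
        labels = tuple(raw[off + 16 * i:off + 16 * (i + 1)].decode().strip()
                       for i in range(n_ch))
        off += n_ch * (16 + 80 + 8)
        phys_min = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                             for i in range(n_ch)])
        off += 8 * n_ch
        phys_max = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                             for i in range(n_ch)])
        off += 8 * n_ch
        dig_min = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                            for i in range(n_ch)])
        off += 8 * n_ch
        dig_max = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                            for i in range(n_ch)])
        off += 8 * n_ch + 80 * n_ch
        n_samp = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                           for i in range(n_ch)])
        header_len = int(raw[184:192])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: not a parseable EDF header") from exc
    if len(set(n_samp)) != 1:
        raise ParseError(f"{path}: per-channel rates differ; unsupported")
    ns = int(n_samp[0])
    fs = ns / dur
    body = np.frombuffer(raw[header_len:], dtype="<i2")
    body = body[:n_rec * n_ch * ns].reshape(n_rec, n_ch, ns)
    digital = np.concatenate([body[r] for r in range(n_rec)], axis=1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    return EEGRecording(data, fs, labels)


# ---------------------------------------------------------------------------
# event tables

_PHASES = ("iti", "prefeedback", "feedback", "postfeedback")
EVENT_COLUMNS = ("onset", "duration", "trial_index", "label")


def write_events(events: TrialEvents, path: str | Path) -> None:
    """One row per phase transition: onset, duration, trial_index, label."""
    rows = []
    for ev in events:
        bounds = (ev.iti_onset, ev.prefeedback_onset, ev.feedback_onset,
                  ev.feedback_end, ev.trial_end)
        for (a, b) in zip(bounds, bounds[1:]):
            rows.append((repr(a), repr(b - a), ev.trial_index,
                         ev.target_class.value))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> TrialEvents:
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != EVENT_COLUMNS:
        raise ParseError(f"{path}: expected columns {EVENT_COLUMNS}, "
                         f"got {tuple(df.columns)}")
    allowed = {c.value for c in ImageryClass}
    bad = set(df["label"]) - allowed
    if bad:
        raise ParseError(f"{path}: unknown labels {sorted(bad)}; "
                         f"allowed: {sorted(allowed)}")
    trials = []
    for idx, grp in df.groupby("trial_index"):
        grp = grp.sort_values("onset", kind="stable")
        if len(grp) != len(_PHASES):
            raise ParseError(f"{path}: trial {idx} has {len(grp)} phase rows, "
                             f"expected {len(_PHASES)}")
        labels = set(grp["label"])
        if len(labels) != 1:
            raise ParseError(f"{path}: trial {idx} has inconsistent labels")
        onsets = grp["onset"].to_numpy(dtype=float)
        durs = grp["duration"].to_numpy(dtype=float)
        trials.append(TrialEvent(
            trial_index=int(idx),
            target_class=ImageryClass(grp["label"].iloc[0]),
            iti_onset=onsets[0],
            prefeedback_onset=onsets[1],
            feedback_onset=onsets[2],
            feedback_end=onsets[3],
            trial_end=onsets[3] + durs[3],
        ))
    return TrialEvents(trials)


# ---------------------------------------------------------------------------
# control-state and trial logs

def write_control_log(states, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.timestamp, s.left_feature, s.right_feature, s.left_z, s.right_z,
          s.vx, s.vy) for s in states],
        columns=("timestamp", "left_feature", "right_feature", "left_z",
                 "right_z", "vx", "vy"))
    df.to_csv(path, sep="\t", index=False)


def write_trial_log(results, path: str | Path) -> None:
    df = pd.DataFrame(
        [(i, r.selected_target if r.selected_target is not None else -1,
          r.outcome.value, r.time_to_hit) for i, r in enumerate(results)],
        columns=("trial_index", "target", "outcome", "time_to_hit"))
    df.to_csv(path, sep="\t", index=False)


def read_trial_log(path: str | Path):
    from .task import TrialResult
    df = pd.read_csv(path, sep="\t")
    expected = ("trial_index", "target", "outcome", "time_to_hit")
    if tuple(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, "
                         f"got {tuple(df.columns)}")
    out = []
    for _, row in df.iterrows():
        sel = None if row["target"] < 0 else int(row["target"])
        out.append(TrialResult(Outcome(row["outcome"]),
                               float(row["time_to_hit"]),
                               trajectory=[], selected_target=sel))
    return out


def write_trajectory(trajectory, path: str | Path) -> None:
    df = pd.DataFrame(trajectory, columns=("t", "x", "y"))
    df.to_csv(path, sep="\t", index=False)
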