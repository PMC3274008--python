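"""Delimited-text trial I/O.

A trial is a CSV (``time_s, emg_ch1..emg_chN, angle_deg``) plus a JSON
sidecar (``<stem>.meta.json``) carrying the stage timeline, subject id,
trial role and a config echo when the trial came from the generator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import AngleSignal, MultiChannelSignal
from .synthetic import StageTimeline, TrialBundle

__all__ = ["sidecar_path", "write_trial", "read_trial"]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".meta.json")


def write_trial(bundle: TrialBundle, csv_path, config=None) -> None:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    data = {"time_s": bundle.emg.times}
    for i, label in enumerate(bundle.emg.channel_labels):
        data[label] = bundle.emg.samples[:, i]
    data["angle_deg"] = bundle.angle.angle
    pd.DataFrame(data).to_csv(csv_path, index=False)

    meta = {
        "subject_id": bundle.subject_id,
        "trial_role": bundle.trial_role,
        "sampling_rate": bundle.emg.sampling_rate,
        "channel_labels": list(bundle.emg.channel_labels),
        "timeline": dataclasses.asdict(bundle.timeline) if bundle.timeline else None,
        "config": _config_echo(config),
    }
    with open(sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_echo(config):
    if config is None:
        return None
    echo = dataclasses.asdict(config)
    echo["angle_drift_rate"] = config.angle_drift_rate
    return echo


def read_trial(csv_path) -> TrialBundle:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    if "time_s" not in frame or "angle_deg" not in frame:
        raise ValueError("trial CSV must contain time_s and angle_deg columns")
    emg_cols = [c for c in frame.columns if c not in ("time_s", "angle_deg")]
    if not emg_cols:
        raise ValueError("trial CSV contains no sEMG channels")

    meta_path = sidecar_path(csv_path)
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)

    t = frame["time_s"].to_numpy()
    fs = meta.get("sampling_rate") or 1.0 / float(np.median(np.diff(t)))
    t0 = float(t[0])
    emg = MultiChannelSignal(fs, frame[emg_cols].to_numpy(), tuple(emg_cols), t0)
    angle = AngleSignal(fs, frame["angle_deg"].to_numpy(), t0)
    timeline = None
    if meta.get("timeline"):
        timeline = StageTimeline(**meta["timeline"])
    return TrialBundle(
        emg=emg,
        angle=angle,
        timeline=timeline,
        subject_id=meta.get("subject_id", csv_path.stem),
        trial_role=meta.get("trial_role", "testing"),
    )
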