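"""Simple on-disk session container: numeric matrix + JSON sidecar.

A session is stored as ``<stem>.npy`` (channels x samples, microvolts)
next to ``<stem>.json`` carrying the sampling rate, channel labels, cue
events and, for synthetic sessions, the generator's ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import SessionRecording
from .synthetic import GroundTruth


def save_session(
    stem: str | Path,
    recording: SessionRecording,
    truth: GroundTruth | None = None,
) -> tuple[Path, Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, recording.samples)
    sidecar = {
        "fs": recording.fs,
        "channel_labels": list(recording.channel_labels),
        "events": [[int(i), str(lab)] for i, lab in recording.events],
        "ids": list(recording.ids),
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "alpha_amp": truth.alpha_amp.tolist(),
            "erd_depth": truth.erd_depth.tolist(),
            "labels": truth.labels.tolist(),
            "artifact": truth.artifact.tolist(),
        }
    meta.write_text(json.dumps(sidecar, indent=1))
    return npy, meta


def load_session(stem: str | Path) -> tuple[SessionRecording, GroundTruth | None]:
    stem = Path(stem)
    samples = np.load(stem.with_suffix(".npy"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    recording = SessionRecording(
        samples=samples,
        fs=float(sidecar["fs"]),
        channel_labels=list(sidecar["channel_labels"]),
        events=[(int(i), str(lab)) for i, lab in sidecar["events"]],
        ids=tuple(sidecar.get("ids", (0, 0))),
    )
    truth = None
    if "ground_truth" in sidecar:
        gt = sidecar["ground_truth"]
        truth = GroundTruth(
            alpha_amp=np.asarray(gt["alpha_amp"], dtype=float),
            erd_depth=np.asarray(gt["erd_depth"], dtype=float),
            labels=np.asarray(gt["labels"]),
            artifact=np.asarray(gt["artifact"], dtype=bool),
        )
    return recording, truth
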