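"""End-to-end glue: recording -> streams -> events -> labeled feature matrix.

These helpers wire the stage modules together for the common case of running
the whole pipeline over one or many sessions.  Labels are attached by greedy
time-matching of detected events to ground-truth throw times (0.1 s
tolerance), so a spurious or missed detection simply yields an unlabeled or
absent row rather than corrupting its neighbours.
"""

from __future__ import annotations

import logging

import pandas as pd

from .feature_extraction import FeatureCatalogue, featurize_windows
from .imu_io import RawRecording, SensorStream, to_streams
from .throw_detection import DetectionConfig, detect_throws, extract_window

logger = logging.getLogger(__name__)


def featurize_recording(
    raw: RawRecording,
    detection: DetectionConfig | None = None,
    window_sizes_s: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0),
    truth: pd.DataFrame | None = None,
    match_tol_s: float = 0.1,
    catalogue: FeatureCatalogue | None = None,
) -> tuple[pd.DataFrame, list]:
    """Detect, window and featurize every throw of one recording.

    Returns ``(feature_matrix, events)``.  When ``truth`` is given (columns
    ``t_event_s, approach, windup, velocity_mps``), matched labels are merged
    into the matrix and unmatched detections are dropped with a log entry.
    """
    detection = detection or DetectionConfig()
    streams = to_streams(raw)
    events = detect_throws(streams["gyro"], detection)

    labels_by_event: dict[int, dict] = {}
    if truth is not None:
        from .throw_detection import match_events_to_truth

        _, _, pairs = match_events_to_truth(
            events, truth["t_event_s"].tolist(), tol_s=match_tol_s
        )
        for ei, ti in pairs:
            row = truth.iloc[ti]
            labels_by_event[ei] = {
                "approach": row["approach"],
                "windup": row["windup"],
                "velocity_mps": float(row["velocity_mps"]),
            }
        unmatched = len(events) - len(pairs)
        if unmatched:
            logger.info("%d detection(s) had no ground-truth match and carry no labels", unmatched)

    frames = []
    for w in window_sizes_s:
        windows, labels = [], []
        for ei, ev in enumerate(events):
            if truth is not None and ei not in labels_by_event:
                continue
            win = extract_window(streams, ev, w)
            if win is None:
                continue
            windows.append(win)
            lab = {"subject_id": raw.subject_id, "t_peak_s": ev.t_peak}
            lab.update(labels_by_event.get(ei, {}))
            labels.append(lab)
        if windows:
            frames.append(featurize_windows(windows, catalogue, labels))
    fm = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return fm, events


def featurize_study(
    sessions,
    detection: DetectionConfig | None = None,
    window_sizes_s: tuple[float, ...] = (2.0, 3.0),
    match_tol_s: float = 0.1,
    catalogue: FeatureCatalogue | None = None,
) -> pd.DataFrame:
    """Pooled labeled feature matrix across simulated sessions."""
    frames = []
    for sess in sessions:
        fm, _ = featurize_recording(
            sess.recording,
            detection=detection,
            window_sizes_s=window_sizes_s,
            truth=sess.truth,
            match_tol_s=match_tol_s,
            catalogue=catalogue,
        )
        frames.append(fm)
    return pd.concat(frames, ignore_index=True)
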