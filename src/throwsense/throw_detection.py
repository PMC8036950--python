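"""Throw-event detection on the gyroscope y-axis and window cutting.

A handball throw produces a violent forearm rotation whose angular velocity
on the gyroscope y-axis far exceeds anything seen in running, jumping or
ball handling.  Events are therefore recognised as supra-threshold excursions
of gyro-y (default threshold 1500 deg/s): each contiguous run of samples at
or above the threshold contributes one candidate at the run's maximum, and
candidates closer together than a refractory separation (default 1 s) are
merged keeping the larger peak.  Feature windows of 2, 3, 4 and 6 s are then
cut from every sensor stream, temporally centered on the peak-rotation
instant; windows that would extend past the recording bounds are discarded
rather than padded, because padding corrupts spectral and moment statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .imu_io import FEATURE_SENSORS, SensorStream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    threshold_dps: float = 1500.0
    min_separation_s: float = 1.0
    window_sizes_s: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0)
    #: threshold the absolute value instead of the signed signal
    use_abs: bool = False

    def __post_init__(self):
        if self.threshold_dps <= 0 or self.min_separation_s <= 0:
            raise ContractError("threshold and separation must be positive")
        if any(w <= 0 for w in self.window_sizes_s):
            raise ContractError("window sizes must be positive")


@dataclass(frozen=True)
class ThrowEvent:
    """A detected peak-rotation instant on the gyro stream."""

    t_peak: float
    peak_value_dps: float
    index_gyro: int


@dataclass
class ThrowWindow:
    """Multi-channel excerpt centered on one throw event.

    ``excerpts`` maps sensor name -> dict of axis name -> array; each sensor
    keeps its own rate, so excerpt lengths differ across sensors.
    """

    event: ThrowEvent
    window_s: float
    excerpts: dict[str, dict[str, np.ndarray]]
    rates: dict[str, float] = field(default_factory=dict)


def detect_throws(gyro: SensorStream, cfg: DetectionConfig | None = None) -> list[ThrowEvent]:
    """Locate peak-rotation events on the gyro y-axis.

    Returns events sorted by time; each peak is >= the threshold and no two
    events are closer than ``cfg.min_separation_s``.
    """
    cfg = cfg or DetectionConfig()
    v = np.abs(gyro.y) if cfg.use_abs else gyro.y
    if v.size == 0:
        return []

    above = v >= cfg.threshold_dps
    if not above.any():
        return []
    # contiguous supra-threshold runs
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, v.size]

    candidates: list[ThrowEvent] = []
    for s, e in zip(starts, ends):
        i = s + int(np.argmax(v[s:e]))
        candidates.append(
            ThrowEvent(
                t_peak=gyro.t0 + i / gyro.rate_hz,
                peak_value_dps=float(v[i]),
                index_gyro=int(i),
            )
        )

    # merge close candidates, keeping the larger peak
    merged: list[ThrowEvent] = []
    for ev in candidates:  # already time-ordered
        if merged and ev.t_peak - merged[-1].t_peak < cfg.min_separation_s:
            if ev.peak_value_dps > merged[-1].peak_value_dps:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def extract_window(
    streams: dict[str, SensorStream], event: ThrowEvent, window_s: float
) -> ThrowWindow | None:
    """Cut one multi-sensor excerpt centered on ``event.t_peak``.

    High-g excerpts are located by *time*, not by shared sample index, since
    sensors run at different rates.  Returns ``None`` (with a log entry) when
    the window would extend beyond any stream's bounds.
    """
    if window_s <= 0:
        raise ContractError("window_s must be positive")
    excerpts: dict[str, dict[str, np.ndarray]] = {}
    rates: dict[str, float] = {}
    for name in FEATURE_SENSORS:
        s = streams[name]
        n = int(round(window_s * s.rate_hz))
        center = int(round((event.t_peak - s.t0) * s.rate_hz))
        lo = center - n // 2
        hi = lo + n
        if lo < 0 or hi > len(s):
            logger.info(
                "event at t=%.3fs: %g s window exceeds %s bounds, discarded",
                event.t_peak,
                window_s,
                name,
            )
            return None
        excerpts[name] = {ax: s.axis(ax)[lo:hi] for ax in ("x", "y", "z")}
        rates[name] = s.rate_hz
    return ThrowWindow(event=event, window_s=window_s, excerpts=excerpts, rates=rates)


def extract_windows(
    streams: dict[str, SensorStream],
    events: list[ThrowEvent],
    window_sizes_s: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0),
) -> dict[float, list[ThrowWindow]]:
    """Cut every requested window size around every event, skipping out-of-bounds ones."""
    out: dict[float, list[ThrowWindow]] = {w: [] for w in window_sizes_s}
    for w in window_sizes_s:
        for ev in events:
            win = extract_window(streams, ev, w)
            if win is not None:
                out[w].append(win)
    return out


def match_events_to_truth(
    events: list[ThrowEvent] | list[float],
    truth_times: list[float],
    tol_s: float = 0.1,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to ground-truth times.

    Pairs are matched in order of increasing time distance, each detection and
    each truth time used at most once, only within ``tol_s``.  Returns
    ``(precision, recall, pairs)`` where pairs are (event index, truth index).
    With no detections, precision is reported as 0.0.
    """
    if tol_s <= 0:
        raise ContractError("tol_s must be positive")
    det = np.array(
        [ev.t_peak if isinstance(ev, ThrowEvent) else float(ev) for ev in events], dtype=float
    )
    tru = np.asarray(truth_times, dtype=float)
    if det.size == 0:
        return 0.0, 0.0 if tru.size else 1.0, []
    if tru.size == 0:
        return 0.0, 1.0, []

    dist = np.abs(det[:, None] - tru[None, :])
    order = np.argsort(dist, axis=None, kind="stable")
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), tru.size)
        if dist[i, j] > tol_s:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    precision = len(pairs) / det.size
    recall = len(pairs) / tru.size
    return precision, recall, pairs
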