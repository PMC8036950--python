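"""Reading, validation, and uniform resampling of raw multi-rate IMU recordings.

A 9-DoF wrist unit ships three feature-bearing sensors at different nominal
rates: a low-g accelerometer (+-16 g, 1125 Hz), a high-g accelerometer
(+-200 g, 1600 Hz) and a gyroscope (+-2000 deg/s, 1125 Hz); the magnetometer
(+-4900 uT, 100 Hz) is carried through untouched and never used by features.
Because the true per-sample rates fluctuate around nominal, every
feature-bearing channel is linearly interpolated onto an exactly uniform grid
(1150 Hz for the low-g accelerometer and gyroscope, 1600 Hz for the high-g
accelerometer) before any event detection or feature computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, InsufficientDataError, SchemaError

logger = logging.getLogger(__name__)

#: Sensors whose channels feed the feature inventory.
FEATURE_SENSORS = ("acc_low", "acc_high", "gyro")

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class SensorSpec:
    """Physical range and rate bookkeeping for one sensor.

    ``target_rate_hz`` is the uniform post-resampling rate; ``None`` means the
    sensor is passed through without resampling (magnetometer).
    """

    name: str
    range: float
    nominal_rate_hz: float
    target_rate_hz: float | None
    units: str

    def __post_init__(self):
        if self.range <= 0:
            raise ConfigurationError(f"{self.name}: range must be positive")
        if self.name in FEATURE_SENSORS and (
            self.target_rate_hz is None or self.target_rate_hz <= 0
        ):
            raise ConfigurationError(f"{self.name}: feature-bearing sensor needs a target rate")


DEFAULT_SPECS: dict[str, SensorSpec] = {
    "acc_low": SensorSpec("acc_low", 16.0, 1125.0, 1150.0, "g"),
    "acc_high": SensorSpec("acc_high", 200.0, 1600.0, 1600.0, "g"),
    "gyro": SensorSpec("gyro", 2000.0, 1125.0, 1150.0, "dps"),
    "mag": SensorSpec("mag", 4900.0, 100.0, None, "uT"),
}

#: Default CSV column mapping: one shared time column, per-sensor axis columns.
DEFAULT_SCHEMA: dict = {
    "time": "time_s",
    "sensors": {
        "acc_low": {"x": "alx", "y": "aly", "z": "alz"},
        "acc_high": {"x": "ahx", "y": "ahy", "z": "ahz"},
        "gyro": {"x": "gx", "y": "gy", "z": "gz"},
        "mag": {"x": "mx", "y": "my", "z": "mz"},
    },
}


@dataclass
class RawRecording:
    """Per-sensor irregular time series as read from disk or a simulator.

    ``sensors`` maps sensor name -> dict with keys ``t, x, y, z`` (1-D float
    arrays of equal length, timestamps strictly increasing, seconds).
    """

    subject_id: str
    sensors: dict[str, dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, ch in self.sensors.items():
            n = len(ch["t"])
            for ax in AXES:
                if len(ch[ax]) != n:
                    raise DataError(f"{name}: axis {ax} length {len(ch[ax])} != {n}")
            dt = np.diff(ch["t"])
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise DataError(
                    f"{name}: timestamps not strictly increasing at index {bad[0] + 1}"
                )


@dataclass
class SensorStream:
    """One uniformly sampled triaxial channel group."""

    sensor: str
    rate_hz: float
    t0: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    units: str

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return (len(self.x) - 1) / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.x)) / self.rate_hz

    def axis(self, name: str) -> np.ndarray:
        return getattr(self, name)


def load_schema(path) -> dict:
    """Load a YAML column-mapping schema (see ``DEFAULT_SCHEMA`` for shape)."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if "time" not in schema or "sensors" not in schema:
        raise SchemaError("schema must define 'time' and 'sensors'")
    return schema


def read_recording(path, schema: dict | None = None, subject_id: str = "") -> RawRecording:
    """Read one session CSV into a :class:`RawRecording`.

    The dialect is fixed: comma-separated, header row, UTF-8, '.' decimal.
    Rows whose time or axis values are non-finite are dropped per sensor (and
    counted in the log), which lets a single file carry sensors sampled at
    different rates: a row simply leaves the columns of absent sensors empty.
    """
    schema = schema or DEFAULT_SCHEMA
    df = pd.read_csv(path)
    tcol = schema["time"]
    if tcol not in df.columns:
        raise SchemaError(f"missing time column {tcol!r}")

    sensors: dict[str, dict[str, np.ndarray]] = {}
    for sensor, axes in schema["sensors"].items():
        cols = [axes.get(ax) for ax in AXES]
        present = [c for c in cols if c is not None and c in df.columns]
        if not present:
            continue  # sensor absent from this file altogether
        missing = [c for c in cols if c is not None and c not in df.columns]
        if missing:
            raise SchemaError(f"{sensor}: mapped column(s) missing from file: {missing}")
        block = df[[tcol, *cols]].to_numpy(dtype=float)
        keep = np.isfinite(block).all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s: dropped %d non-finite row(s) for sensor %s", path, dropped, sensor)
        block = block[keep]
        t = block[:, 0]
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise DataError(
                f"{sensor}: timestamps not strictly increasing at index {bad[0] + 1}"
            )
        sensors[sensor] = {
            "t": t,
            "x": block[:, 1],
            "y": block[:, 2],
            "z": block[:, 3],
        }

    rec = RawRecording(subject_id=subject_id, sensors=sensors)
    rec.validate()
    return rec


def resample_linear(
    timestamps: np.ndarray, values: np.ndarray, target_rate_hz: float
) -> tuple[np.ndarray, float]:
    """Linearly interpolate one channel onto a uniform grid.

    The grid is anchored at the first input timestamp and spans the input
    range only (no extrapolation): it has ``floor((t_last - t0) * rate) + 1``
    points at exact spacing ``1 / target_rate_hz``.

    Returns ``(values_on_grid, t0)``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    if np.any(np.diff(timestamps) <= 0):
        raise DataError("timestamps must be strictly increasing")
    t0 = timestamps[0]
    span = timestamps[-1] - t0
    # tiny epsilon so an input already on the target grid keeps its last point
    n = int(np.floor(span * target_rate_hz + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate_hz
    return np.interp(grid, timestamps, values), t0


def to_streams(
    raw: RawRecording, specs: dict[str, SensorSpec] | None = None
) -> dict[str, SensorStream]:
    """Resample every feature-bearing sensor of ``raw`` to its target rate.

    The magnetometer, when present, is ignored: no feature uses it.
    """
    specs = specs or DEFAULT_SPECS
    missing = [s for s in FEATURE_SENSORS if s not in raw.sensors]
    if missing:
        raise ConfigurationError(f"recording lacks feature-bearing sensor(s): {missing}")

    streams: dict[str, SensorStream] = {}
    for name in FEATURE_SENSORS:
        spec = specs[name]
        ch = raw.sensors[name]
        xr, t0 = resample_linear(ch["t"], ch["x"], spec.target_rate_hz)
        yr, _ = resample_linear(ch["t"], ch["y"], spec.target_rate_hz)
        zr, _ = resample_linear(ch["t"], ch["z"], spec.target_rate_hz)
        streams[name] = SensorStream(
            sensor=name,
            rate_hz=spec.target_rate_hz,
            t0=t0,
            x=xr,
            y=yr,
            z=zr,
            units=spec.units,
        )
    return streams


def write_streams(streams: dict[str, SensorStream], out_dir) -> list[str]:
    """Dump each resampled stream to ``<out_dir>/<sensor>.csv`` for inspection."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, s in streams.items():
        df = pd.DataFrame({"time_s": s.times(), "x": s.x, "y": s.y, "z": s.z})
        p = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
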