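"""The 201-feature signal inventory computed on each throw window.

For each of the three feature-bearing sensors (low-g accelerometer, high-g
accelerometer, gyroscope) the x, y, z axes and the vector magnitude
sqrt(x^2 + y^2 + z^2) each yield 16 per-channel statistics, and each sensor
additionally yields the 3 between-axis Pearson correlations:

    3 sensors x 4 channels x 16 statistics + 3 sensors x 3 correlations = 201

The per-channel statistics are: mean, sum, standard deviation, variance,
coefficient of variation, min, max, peak-to-peak amplitude, interquartile
range, skewness, excess kurtosis, power (mean of squares), RMS, lag-1
autocorrelation, dominant frequency, and normalised spectral entropy.

Names follow the convention ``<acc|gyr>_<x|y|z|vm>_<stat>`` with the suffix
``h`` marking features obtained from the high-g accelerometer (e.g.
``acc_y_iqrh``); between-axis correlations are ``<acc|gyr>_<ab>_cor[h]``.

Degenerate-window policies keep every value finite: on a constant channel the
coefficient of variation, skewness, kurtosis, lag-1 autocorrelation,
dominant frequency and spectral entropy are all defined as 0, and a
zero-variance axis contributes 0 to its between-axis correlations.  The
coefficient of variation is additionally capped at 100: gyroscope axes have
near-zero means, making the raw sd/|mean| ratio heavy-tailed in a way that
destabilises downstream kernels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError
from .throw_detection import ThrowWindow

logger = logging.getLogger(__name__)

CATALOGUE_VERSION = "1.0"

CHANNEL_STATS = (
    "mean",
    "sum",
    "sd",
    "variance",
    "cv",
    "min",
    "max",
    "amp",
    "iqr",
    "skewness",
    "kurtosis",
    "power",
    "rms",
    "autocorr_lag1",
    "dominant_frequency",
    "spectral_entropy",
)

CHANNELS = ("x", "y", "z", "vm")
AXIS_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))

#: sensor -> (name prefix, high-g suffix)
_SENSOR_TAG = {"acc_low": ("acc", ""), "acc_high": ("acc", "h"), "gyro": ("gyr", "")}

_EPS = 1e-12

#: Label columns carried alongside features in a feature matrix.
LABEL_COLUMNS = (
    "subject_id",
    "throw_id",
    "t_peak_s",
    "window_s",
    "approach",
    "windup",
    "velocity_mps",
)

APPROACHES = ("standing", "running", "jumping")
WINDUPS = ("circle", "whip")


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered, versioned enumeration of the 201 feature names."""

    names: tuple[str, ...]
    version: str = CATALOGUE_VERSION

    def __len__(self) -> int:
        return len(self.names)

    def sensor_of(self, name: str) -> str:
        """Invert the naming convention: which sensor produced this feature."""
        if name.startswith("gyr"):
            return "gyro"
        stem = name.split("_", 2)[-1]
        return "acc_high" if stem.endswith("h") else "acc_low"

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "names": list(self.names)}, indent=1)


def build_catalogue() -> FeatureCatalogue:
    names: list[str] = []
    for sensor in ("acc_low", "acc_high", "gyro"):
        prefix, suffix = _SENSOR_TAG[sensor]
        for ch in CHANNELS:
            for stat in CHANNEL_STATS:
                names.append(f"{prefix}_{ch}_{stat}{suffix}")
    for sensor in ("acc_low", "acc_high", "gyro"):
        prefix, suffix = _SENSOR_TAG[sensor]
        for a, b in AXIS_PAIRS:
            names.append(f"{prefix}_{a}{b}_cor{suffix}")
    assert len(names) == 201 and len(set(names)) == 201
    return FeatureCatalogue(names=tuple(names))


DEFAULT_CATALOGUE = build_catalogue()


def vector_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a triaxial signal."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ContractError("axes must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with the degenerate-variance policy value 0."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < _EPS:
        return 0.0
    return float((a * b).sum() / denom)


def channel_features(v: np.ndarray, rate_hz: float) -> dict[str, float]:
    """The 16 per-channel statistics of one windowed signal."""
    v = np.asarray(v, dtype=float)
    if v.size < 8:
        raise ContractError("channel_features needs at least 8 samples")
    if rate_hz <= 0:
        raise ContractError("rate_hz must be positive")

    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    variance = sd * sd
    vmin, vmax = float(v.min()), float(v.max())
    degenerate = variance < _EPS * max(1.0, mean * mean)

    out: dict[str, float] = {
        "mean": mean,
        "sum": float(v.sum()),
        "sd": sd,
        "variance": variance,
        # bounded: sd/|mean| is heavy-tailed on near-zero-mean channels
        # (e.g. gyro axes), so the ratio is capped at 100
        "cv": 0.0 if abs(mean) < _EPS else min(sd / abs(mean), 100.0),
        "min": vmin,
        "max": vmax,
        "amp": vmax - vmin,
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "skewness": 0.0 if degenerate else float(sps.skew(v, bias=True)),
        "kurtosis": 0.0 if degenerate else float(sps.kurtosis(v, fisher=True, bias=True)),
        "power": float(np.mean(v * v)),
        "rms": float(np.sqrt(np.mean(v * v))),
        "autocorr_lag1": 0.0 if degenerate else _pearson(v[:-1], v[1:]),
    }

    # Spectral statistics on the mean-removed signal, zero-frequency bin excluded.
    spec = np.abs(np.fft.rfft(v - mean)) ** 2
    spec = spec[1:]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)[1:]
    total = spec.sum()
    if degenerate or total < _EPS:
        out["dominant_frequency"] = 0.0
        out["spectral_entropy"] = 0.0
    else:
        out["dominant_frequency"] = float(freqs[int(np.argmax(spec))])
        p = spec / total
        nz = p[p > 0]
        out["spectral_entropy"] = float(-(nz * np.log(nz)).sum() / np.log(spec.size))
    return out


def cross_axis_correlations(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> dict[str, float]:
    """Pearson correlation of each axis pair; zero-variance axes contribute 0."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ContractError("axes must have equal length")
    if len(x) < 3:
        raise ContractError("correlations need at least 3 samples")
    axes = {"x": x, "y": y, "z": z}
    return {f"{a}{b}": _pearson(axes[a], axes[b]) for a, b in AXIS_PAIRS}


def featurize_throw(
    w: ThrowWindow, cat: FeatureCatalogue | None = None
) -> dict[str, float]:
    """All 201 features of one throw window, in catalogue order."""
    cat = cat or DEFAULT_CATALOGUE
    values: dict[str, float] = {}
    for sensor in ("acc_low", "acc_high", "gyro"):
        prefix, suffix = _SENSOR_TAG[sensor]
        ex = w.excerpts[sensor]
        rate = w.rates[sensor]
        chans = dict(ex)
        chans["vm"] = vector_magnitude(ex["x"], ex["y"], ex["z"])
        for ch in CHANNELS:
            stats = channel_features(chans[ch], rate)
            for stat in CHANNEL_STATS:
                values[f"{prefix}_{ch}_{stat}{suffix}"] = stats[stat]
        cors = cross_axis_correlations(ex["x"], ex["y"], ex["z"])
        for a, b in AXIS_PAIRS:
            values[f"{prefix}_{a}{b}_cor{suffix}"] = cors[f"{a}{b}"]

    vec = {name: values[name] for name in cat.names}
    assert all(np.isfinite(v) for v in vec.values())
    return vec


def feature_columns(fm: pd.DataFrame) -> list[str]:
    """The feature columns of a feature matrix (everything but the labels)."""
    return [c for c in fm.columns if c not in LABEL_COLUMNS]


def split_range_sets(fm: pd.DataFrame, cat: FeatureCatalogue | None = None):
    """Split the full matrix into the high-g and low-g feature sets.

    Both sets keep every gyroscope feature (67 columns); the high-g set adds
    the high-g accelerometer's 67, the low-g set the low-g accelerometer's 67,
    giving 134 feature columns each.  Label columns are carried through.
    """
    cat = cat or DEFAULT_CATALOGUE
    feats = feature_columns(fm)
    labels = [c for c in fm.columns if c in LABEL_COLUMNS]
    high = [c for c in feats if cat.sensor_of(c) in ("gyro", "acc_high")]
    low = [c for c in feats if cat.sensor_of(c) in ("gyro", "acc_low")]
    return fm[labels + high].copy(), fm[labels + low].copy()


def featurize_windows(
    windows: list[ThrowWindow],
    cat: FeatureCatalogue | None = None,
    labels: list[dict] | None = None,
) -> pd.DataFrame:
    """Stack one feature row per window into a DataFrame.

    ``labels``, when given, is a parallel list of dicts merged into each row
    (subject_id, approach, windup, velocity_mps, ...).
    """
    cat = cat or DEFAULT_CATALOGUE
    rows = []
    for i, w in enumerate(windows):
        try:
            vec = featurize_throw(w, cat)
        except ContractError as err:
            logger.info("throw at t=%.3fs skipped: %s", w.event.t_peak, err)
            continue
        row: dict = {"throw_id": i, "window_s": w.window_s}
        if labels is not None:
            row.update(labels[i])
        row.update(vec)
        rows.append(row)
    return pd.DataFrame(rows)
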