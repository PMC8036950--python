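"""The 201-feature catalogue and its statistic definitions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_channel_features, oracle_pearson
from throwsense.errors import ContractError
from throwsense.feature_extraction import (
    CHANNEL_STATS,
    DEFAULT_CATALOGUE,
    build_catalogue,
    channel_features,
    cross_axis_correlations,
    feature_columns,
    featurize_throw,
    split_range_sets,
    vector_magnitude,
)
from throwsense.throw_detection import ThrowEvent, ThrowWindow


def _window(n_lg=64, n_hg=96, rng=None, duplicate_acc=False):
    rng = rng or np.random.default_rng(0)
    ex = {}
    lg = {ax: rng.normal(size=n_lg) for ax in ("x", "y", "z")}
    hg = (
        {ax: lg[ax].copy() for ax in ("x", "y", "z")}
        if duplicate_acc
        else {ax: rng.normal(size=n_hg) for ax in ("x", "y", "z")}
    )
    gy = {ax: rng.normal(size=n_lg) for ax in ("x", "y", "z")}
    ex["acc_low"], ex["acc_high"], ex["gyro"] = lg, hg, gy
    rates = {"acc_low": 1150.0, "acc_high": 1150.0 if duplicate_acc else 1600.0, "gyro": 1150.0}
    return ThrowWindow(event=ThrowEvent(1.0, 1800.0, 1150), window_s=0.05,
                       excerpts=ex, rates=rates)


def test_catalogue_arithmetic():
    cat = build_catalogue()
    assert len(cat) == 201
    assert len(set(cat.names)) == 201
    per_channel = [n for n in cat.names if "_cor" not in n]
    cors = [n for n in cat.names if "_cor" in n]
    assert len(per_channel) == 12 * 16
    assert len(cors) == 9
    for stat in CHANNEL_STATS:  # every named statistic family is present
        assert any(n.endswith(stat) or n.endswith(stat + "h") for n in cat.names)


def test_catalogue_sensor_partition():
    cat = DEFAULT_CATALOGUE
    counts = {"acc_low": 0, "acc_high": 0, "gyro": 0}
    for n in cat.names:
        counts[cat.sensor_of(n)] += 1
    assert counts == {"acc_low": 67, "acc_high": 67, "gyro": 67}


def test_vector_magnitude_345():
    vm = vector_magnitude([3.0, 0.0], [4.0, 0.0], [0.0, 0.0])
    assert np.allclose(vm, [5.0, 0.0])


def test_vector_magnitude_brute_force():
    rng = np.random.default_rng(1)
    x, y, z = rng.normal(size=(3, 50))
    vm = vector_magnitude(x, y, z)
    expect = [np.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
    assert np.allclose(vm, expect, rtol=1e-12)


def test_vector_magnitude_length_mismatch():
    with pytest.raises(ContractError):
        vector_magnitude([1.0], [1.0, 2.0], [1.0])


def test_channel_features_constant_signal_policies():
    f = channel_features(np.full(32, 2.0), 100.0)
    assert f["variance"] == 0.0
    assert f["amp"] == 0.0
    assert f["skewness"] == 0.0
    assert f["kurtosis"] == 0.0
    assert f["cv"] == 0.0
    assert f["autocorr_lag1"] == 0.0
    assert f["power"] == pytest.approx(4.0)
    assert f["dominant_frequency"] == 0.0
    assert f["spectral_entropy"] == 0.0


def test_channel_features_ramp_order_statistics():
    v = np.arange(1.0, 9.0)  # 1..8
    f = channel_features(v, 10.0)
    assert f["mean"] == pytest.approx(4.5)
    assert f["sum"] == pytest.approx(36.0)
    assert f["min"] == 1.0 and f["max"] == 8.0 and f["amp"] == 7.0
    assert f["iqr"] == pytest.approx(np.percentile(v, 75) - np.percentile(v, 25))


def test_pure_tone_closed_forms():
    rate, dur, f0 = 100.0, 2.0, 5.0
    t = np.arange(int(rate * dur)) / rate
    v = np.sin(2 * np.pi * f0 * t)
    f = channel_features(v, rate)
    assert f["dominant_frequency"] == pytest.approx(f0, abs=1e-12)
    assert f["power"] == pytest.approx(0.5, abs=1e-12)
    assert f["spectral_entropy"] < 0.05


def test_channel_features_too_short():
    with pytest.raises(ContractError):
        channel_features(np.ones(7), 100.0)


def test_channel_statistics_match_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(10):
        v = rng.normal(scale=rng.uniform(0.1, 50), size=int(rng.integers(16, 80)))
        got = channel_features(v, 100.0)
        want = oracle_channel_features(v, 100.0)
        for k in CHANNEL_STATS:
            assert got[k] == pytest.approx(want[k], rel=1e-9, abs=1e-9), k


@given(st.floats(0.01, 1000.0))
def test_scale_equivariance(a):
    rng = np.random.default_rng(9)
    v = rng.normal(size=64) + 0.7
    base = channel_features(v, 200.0)
    scaled = channel_features(a * v, 200.0)
    for k in ("mean", "sum", "sd", "amp", "iqr", "rms", "min", "max"):
        assert scaled[k] == pytest.approx(a * base[k], rel=1e-9)
    for k in ("variance", "power"):
        assert scaled[k] == pytest.approx(a * a * base[k], rel=1e-9)
    for k in ("cv", "skewness", "kurtosis", "autocorr_lag1",
              "dominant_frequency", "spectral_entropy"):
        assert scaled[k] == pytest.approx(base[k], rel=1e-9, abs=1e-12)


def test_cross_axis_correlations_signs_and_policy():
    x = np.arange(10.0)
    assert cross_axis_correlations(x, x, x)["xy"] == pytest.approx(1.0)
    assert cross_axis_correlations(x, -x, x)["xy"] == pytest.approx(-1.0)
    flat = np.ones(10)
    assert cross_axis_correlations(x, flat, x)["xy"] == 0.0


def test_cross_axis_correlations_independent_noise_small():
    rng = np.random.default_rng(12)
    x, y, z = rng.normal(size=(3, 2300))
    cors = cross_axis_correlations(x, y, z)
    assert all(abs(r) < 0.1 for r in cors.values())
    for pair, r in cors.items():
        a, b = {"x": x, "y": y, "z": z}[pair[0]], {"x": x, "y": y, "z": z}[pair[1]]
        assert r == pytest.approx(oracle_pearson(list(a), list(b)), rel=1e-9)


def test_featurize_throw_full_vector():
    w = _window()
    vec = featurize_throw(w)
    assert len(vec) == 201
    assert list(vec) == list(DEFAULT_CATALOGUE.names)
    assert all(np.isfinite(v) for v in vec.values())
    assert featurize_throw(w) == vec  # deterministic


def test_featurize_duplicated_high_low_symmetry():
    w = _window(duplicate_acc=True)
    vec = featurize_throw(w)
    for name, val in vec.items():
        if DEFAULT_CATALOGUE.sensor_of(name) == "acc_low":
            assert vec[name + "h"] == pytest.approx(val, rel=1e-12)


def test_split_range_sets_bookkeeping(small_feature_matrix):
    fm = small_feature_matrix
    assert len(feature_columns(fm)) == 201
    high, low = split_range_sets(fm)
    hf, lf = feature_columns(high), feature_columns(low)
    assert len(hf) == 134 and len(lf) == 134
    shared = set(hf) & set(lf)
    assert len(shared) == 67  # the gyro block appears in both
    assert all(n.startswith("gyr") for n in shared)
    assert len(set(hf) | set(lf)) == 201
    gyr = sorted(shared)
    assert high[gyr].equals(low[gyr])
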