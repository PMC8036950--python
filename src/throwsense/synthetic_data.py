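"""Synthetic multi-rate IMU study generator with ground-truth throws.

The simulator emulates the structure of a standardised handball throwing
study: 17 players, 6 conditions (standing / running / jumping approach
crossed with circular / whip-like wind-up), 7-10 throws per condition per
player, radar-measured peak ball velocities drawn per condition from Normal
distributions (standing 20.7+-2.6 and 20.1+-2.5 m/s, running 22.0+-2.4 and
21.2+-2.4, jumping 21.4+-2.5 and 21.0+-2.4 for circle/whip respectively,
truncated at 2 sigma), and a wrist 9-DoF unit sampling a low-g accelerometer
(+-16 g, ~1125 Hz), a high-g accelerometer (+-200 g, ~1600 Hz) and a
gyroscope (+-2000 deg/s, ~1125 Hz) with per-sample timestamp jitter so that
resampling is actually exercised.

Signal mechanism per throw (raised-cosine pulses, all amplitudes scaled by a
per-subject random gain):

* gyro-y: a 0.3 s pulse whose peak is ``peak_gain_dps`` (default 90 deg/s per
  m/s) times a noisy copy of the ball velocity, floored at 1650 deg/s so that
  every true throw exceeds the 1500 deg/s detection threshold;
* gyro-x: the wind-up signature - one broad 0.6 s lobe (circle) vs a sharp
  0.15 s biphasic pulse (whip);
* accelerometer: an impact-like flat-top spike on x/y - a fixed, limb-speed-
  limited rise envelope capped at an apex proportional to ball velocity -
  plus the approach signature on z (standing quiet; running a 2.5 Hz step
  oscillation for the 2 s before the throw; jumping a near-weightless flight
  phase then a landing spike).

The low-g channel clips at +-16 g, well below the burst apex, so its view of
the spike is the same for every throw and carries essentially no velocity
information; the high-g channel keeps the apex.  Because the gyro-y peak
carries extra encoding noise relative to the accelerometer apex, the low-g
feature set is measurably worse for velocity regression - the synthetic
analogue of the measurement-range contrast the pipeline is meant to probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .imu_io import RawRecording

#: (approach, windup) -> (mean m/s, sd m/s) of radar peak ball velocity
DEFAULT_VELOCITY_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("standing", "circle"): (20.7, 2.6),
    ("standing", "whip"): (20.1, 2.5),
    ("running", "circle"): (22.0, 2.4),
    ("running", "whip"): (21.2, 2.4),
    ("jumping", "circle"): (21.4, 2.5),
    ("jumping", "whip"): (21.0, 2.4),
}

CONDITIONS = tuple(DEFAULT_VELOCITY_PARAMS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings; defaults are the emulated study design."""

    n_subjects: int = 17
    throws_per_condition: tuple[int, int] = (7, 10)
    velocity_params: dict = field(default_factory=lambda: dict(DEFAULT_VELOCITY_PARAMS))
    velocity_trunc_sigma: float = 2.0
    #: optional per-subject total throw-count window (None disables the cap)
    total_throws_range: tuple[int, int] | None = None

    # velocity -> signal encoding
    peak_gain_dps: float = 90.0          # gyro-y peak per m/s
    gyro_peak_floor_dps: float = 1650.0  # keeps every throw above the 1500 threshold
    velocity_noise_sd: float = 0.9       # shared measurement noise, m/s
    gyro_encoding_noise_sd: float = 0.8  # extra gyro-only noise, m/s
    acc_encoding_noise_sd: float = 0.2   # extra accelerometer-only noise, m/s
    acc_burst_gain_g: float = 1.1        # accelerometer burst apex per m/s
    acc_burst_y_frac: float = 0.8        # y-axis burst apex as a fraction of the x apex
    acc_burst_env_g: float = 60.0        # fixed rise-envelope amplitude of the impact spike
    subject_gain_sd: float = 0.02        # per-subject multiplicative gain spread

    # sensor imperfections
    low_g_clip_g: float = 16.0
    acc_noise_low_sd_g: float = 0.02
    acc_noise_high_sd_g: float = 0.08
    gyro_noise_sd_dps: float = 8.0
    timestamp_jitter_frac: float = 0.02

    # timing
    inter_throw_gap_s: float = 8.0
    lead_in_s: float = 3.5

    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.throws_per_condition
        if not (1 <= lo <= hi):
            raise ConfigurationError("throws_per_condition must satisfy 1 <= lo <= hi")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if self.inter_throw_gap_s <= 6.0:
            raise ConfigurationError("inter-throw gap must exceed the largest window (6 s)")
        if self.gyro_peak_floor_dps <= 1500.0:
            raise ConfigurationError("gyro peak floor must exceed the 1500 dps threshold")
        for cond, (m, sd) in self.velocity_params.items():
            if m <= 0 or sd <= 0:
                raise ConfigurationError(f"bad velocity params for {cond}")
            if m - self.velocity_trunc_sigma * sd <= 0:
                raise ConfigurationError(f"{cond}: truncated velocities must stay positive")


@dataclass
class SimulatedSession:
    """One subject's synthetic recording plus its ground truth."""

    subject_id: str
    recording: RawRecording
    truth: pd.DataFrame  # columns: subject_id, t_event_s, approach, windup, velocity_mps
    config: SimulationConfig


def _raised_cosine(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """Smooth unimodal pulse supported on [center - width/2, center + width/2]."""
    out = np.zeros_like(t)
    m = np.abs(t - center) <= width / 2
    out[m] = amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t[m] - center) / width))
    return out


def _flat_top_spike(
    t: np.ndarray, center: float, width: float, amp: float, env_amp: float
) -> np.ndarray:
    """Impact-like spike: a fixed rise envelope capped at ``amp``.

    The rise profile (``env_amp`` raised cosine) is the same for every throw -
    only the flat apex height varies - so a sensor that saturates below the
    apex records a waveform carrying no apex information at all.
    """
    return np.minimum(_raised_cosine(t, center, width, env_amp), amp)


def _biphasic(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """One full sine cycle: sharp positive then negative lobe."""
    out = np.zeros_like(t)
    m = np.abs(t - center) <= width / 2
    out[m] = amp * np.sin(2.0 * np.pi * (t[m] - center) / width)
    return out


def _jittered_times(duration: float, nominal_rate: float, frac: float, rng) -> np.ndarray:
    """Strictly increasing timestamps with uniform per-interval jitter."""
    n = int(np.ceil(duration * nominal_rate)) + 1
    dt = (1.0 / nominal_rate) * (1.0 + frac * rng.uniform(-0.5, 0.5, size=n))
    t = np.concatenate(([0.0], np.cumsum(dt[:-1])))
    return t


def _truncnorm(rng, mean, sd, k, size=None):
    """Normal draw re-sampled (via clipping) to +-k sigma."""
    v = rng.normal(mean, sd, size=size)
    return np.clip(v, mean - k * sd, mean + k * sd)


def simulate_session(
    cfg: SimulationConfig,
    subject_id: str = "S01",
    rng: np.random.Generator | None = None,
    subject_gain: float | None = None,
) -> SimulatedSession:
    """Generate one subject's multi-rate recording with ground-truth throws."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if subject_gain is None:
        subject_gain = float(_truncnorm(rng, 1.0, cfg.subject_gain_sd, 2.0))

    # condition schedule: 7-10 throws per condition, order randomized
    lo, hi = cfg.throws_per_condition
    schedule: list[tuple[str, str]] = []
    for cond in CONDITIONS:
        schedule.extend([cond] * int(rng.integers(lo, hi + 1)))
    if cfg.total_throws_range is not None:
        tmin, tmax = cfg.total_throws_range
        while len(schedule) > tmax:
            schedule.pop(int(rng.integers(len(schedule))))
        if len(schedule) < tmin:
            raise ConfigurationError("total_throws_range incompatible with per-condition range")
    rng.shuffle(schedule)
    n_throws = len(schedule)

    # event times: fixed gap plus small jitter, margins for the largest window
    t_events = cfg.lead_in_s + cfg.inter_throw_gap_s * np.arange(n_throws)
    t_events = t_events + rng.uniform(-0.3, 0.3, size=n_throws)
    duration = t_events[-1] + cfg.lead_in_s

    rows = []
    for (approach, windup), tc in zip(schedule, t_events):
        m, sd = cfg.velocity_params[(approach, windup)]
        v = float(_truncnorm(rng, m, sd, cfg.velocity_trunc_sigma))
        rows.append(
            {
                "subject_id": subject_id,
                "t_event_s": float(tc),
                "approach": approach,
                "windup": windup,
                "velocity_mps": v,
            }
        )
    truth = pd.DataFrame(rows)

    # sensor time bases (jittered around nominal rates)
    t_lg = _jittered_times(duration, 1125.0, cfg.timestamp_jitter_frac, rng)
    t_hg = _jittered_times(duration, 1600.0, cfg.timestamp_jitter_frac, rng)
    t_gy = _jittered_times(duration, 1125.0, cfg.timestamp_jitter_frac, rng)

    gyro_x = np.zeros_like(t_gy)
    gyro_y = np.zeros_like(t_gy)
    gyro_z = np.zeros_like(t_gy)
    acc_x = np.zeros_like(t_lg)   # true (unclipped) acceleration, g
    acc_y = np.zeros_like(t_lg)
    acc_z = np.ones_like(t_lg)    # gravity baseline
    acch_x = np.zeros_like(t_hg)
    acch_y = np.zeros_like(t_hg)
    acch_z = np.ones_like(t_hg)

    for row in rows:
        tc = row["t_event_s"]
        v = row["velocity_mps"]
        eps_shared = float(rng.normal(0.0, cfg.velocity_noise_sd))
        eps_gyro = float(rng.normal(0.0, cfg.gyro_encoding_noise_sd))
        eps_acc = float(rng.normal(0.0, cfg.acc_encoding_noise_sd))

        peak = subject_gain * cfg.peak_gain_dps * (v + eps_shared + eps_gyro)
        peak = max(peak, cfg.gyro_peak_floor_dps)
        gyro_y += _raised_cosine(t_gy, tc, 0.30, peak)

        if row["windup"] == "circle":
            gyro_x += _raised_cosine(t_gy, tc - 0.50, 0.60, 400.0 * subject_gain)
        else:  # whip
            gyro_x += _biphasic(t_gy, tc - 0.15, 0.15, 600.0 * subject_gain)

        amp_g = subject_gain * cfg.acc_burst_gain_g * (v + eps_shared + eps_acc)
        env = cfg.acc_burst_env_g * subject_gain
        for tt, ax, ay in ((t_lg, acc_x, acc_y), (t_hg, acch_x, acch_y)):
            ax += _flat_top_spike(tt, tc, 0.12, amp_g, env)
            ay += _flat_top_spike(tt, tc + 0.02, 0.12, cfg.acc_burst_y_frac * amp_g, env)

        if row["approach"] == "running":
            for tt, az in ((t_lg, acc_z), (t_hg, acch_z)):
                m_run = (tt >= tc - 2.5) & (tt <= tc - 0.5)
                az[m_run] += 0.5 * subject_gain * np.sin(2.0 * np.pi * 2.5 * (tt[m_run] - tc))
        elif row["approach"] == "jumping":
            for tt, az in ((t_lg, acc_z), (t_hg, acch_z)):
                m_fly = (tt >= tc - 1.0) & (tt <= tc - 0.55)
                az[m_fly] -= 1.0  # free fall: proper acceleration ~ 0
                az += _raised_cosine(tt, tc - 0.5, 0.06, 8.0 * subject_gain)

    sensors = {
        "acc_low": {
            "t": t_lg,
            "x": np.clip(acc_x, -cfg.low_g_clip_g, cfg.low_g_clip_g)
            + rng.normal(0.0, cfg.acc_noise_low_sd_g, t_lg.size),
            "y": np.clip(acc_y, -cfg.low_g_clip_g, cfg.low_g_clip_g)
            + rng.normal(0.0, cfg.acc_noise_low_sd_g, t_lg.size),
            "z": np.clip(acc_z, -cfg.low_g_clip_g, cfg.low_g_clip_g)
            + rng.normal(0.0, cfg.acc_noise_low_sd_g, t_lg.size),
        },
        "acc_high": {
            "t": t_hg,
            "x": acch_x + rng.normal(0.0, cfg.acc_noise_high_sd_g, t_hg.size),
            "y": acch_y + rng.normal(0.0, cfg.acc_noise_high_sd_g, t_hg.size),
            "z": acch_z + rng.normal(0.0, cfg.acc_noise_high_sd_g, t_hg.size),
        },
        "gyro": {
            "t": t_gy,
            "x": gyro_x + rng.normal(0.0, cfg.gyro_noise_sd_dps, t_gy.size),
            "y": gyro_y + rng.normal(0.0, cfg.gyro_noise_sd_dps, t_gy.size),
            "z": gyro_z + rng.normal(0.0, cfg.gyro_noise_sd_dps, t_gy.size),
        },
    }
    recording = RawRecording(subject_id=subject_id, sensors=sensors)
    recording.validate()
    return SimulatedSession(subject_id=subject_id, recording=recording, truth=truth, config=cfg)


def simulate_study(cfg: SimulationConfig) -> tuple[list[SimulatedSession], pd.DataFrame]:
    """Independent per-subject sessions plus the pooled ground-truth table."""
    cfg.validate()
    if cfg.n_subjects < 2:
        raise ConfigurationError("a study needs at least 2 subjects")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    sessions = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sessions.append(simulate_session(cfg, subject_id=f"S{i + 1:02d}", rng=rng))
    truth = pd.concat([s.truth for s in sessions], ignore_index=True)
    return sessions, truth


def session_to_csv(session: SimulatedSession, path) -> None:
    """Write one session in the imu_io CSV dialect (union time grid, NaN gaps)."""
    frames = []
    colmap = {"acc_low": ("alx", "aly", "alz"), "acc_high": ("ahx", "ahy", "ahz"),
              "gyro": ("gx", "gy", "gz")}
    for sensor, cols in colmap.items():
        ch = session.recording.sensors[sensor]
        frames.append(
            pd.DataFrame({"time_s": ch["t"], cols[0]: ch["x"], cols[1]: ch["y"], cols[2]: ch["z"]})
        )
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on="time_s", how="outer")
    merged = merged.sort_values("time_s", kind="stable").reset_index(drop=True)
    merged.to_csv(path, index=False)


def easy_config(**overrides) -> SimulationConfig:
    """Smaller, faster configuration for demos and smoke tests (not the study design)."""
    base = SimulationConfig(n_subjects=3, throws_per_condition=(2, 2), seed=0)
    return replace(base, **overrides)
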