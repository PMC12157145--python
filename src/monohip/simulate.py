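"""Synthetic gait cohort generator.

Produces ground-truth sagittal hip/thigh kinematics per gait cycle and the
corresponding thigh-worn IMU signals (gyroscope + accelerometer), so the whole
measurement chain — functional calibration, strapdown/fusion ROM, feature
extraction, prediction and agreement analysis — can be exercised without any
recorded data.

Model in brief
--------------
* Each participant contributes two limb sides; each side is measured over one
  or more trials at different walking speeds.
* The hip flexion waveform of a cycle is a smooth periodic curve built from a
  small number of cosine harmonics, rescaled so its range equals the drawn
  hip ROM exactly.
* The thigh angle is the hip angle minus a sinusoidal pelvis-tilt
  contribution whose amplitude is solved per cycle so that, by construction,

      hip_rom = b0 + b1 * thigh_rom + b2 * leg_length + b3 * speed + eps

  with known coefficients. This gives the downstream multiple linear
  regression a recoverable target.
* The IMU model places a misaligned sensor on the thigh: the gyroscope sees
  the thigh angular velocity about the segment medio-lateral axis plus small
  out-of-plane components, soft-tissue ringing at heel strike and white
  noise; the accelerometer sees gravity in the rotating, misaligned sensor
  frame plus noise. Translational acceleration of the thigh is not modelled.

Units: degrees (angles), deg/s (angular velocity), m/s^2 (acceleration),
seconds (time), metres (lengths) throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .signals import TimeSeries

GRAVITY = 9.81  # m/s^2
N_POINTS = 100  # samples of a time-normalized gait cycle


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GaitSimConfig:
    """Parameters of the synthetic cohort.

    The defaults describe 25 virtual participants walking at slow,
    self-selected and fast speed, with hip ROM spanning the reduced / average
    / normal classes (boundaries 10-30 / 30-45 / >=45 degrees).
    """

    n_participants: int = 25
    sides: tuple[str, ...] = ("L", "R")
    visits: int = 1
    cycles_per_trial: int = 8
    trials_per_participant: int = 3

    # hip ROM distribution (between participant-visit) and per-cycle jitter
    hip_rom_mean: float = 38.0
    hip_rom_sd: float = 10.0
    hip_rom_cycle_sd: float = 1.5
    hip_rom_speed_slope: float = 7.0     # deg per m/s

    # pelvis-tilt contribution: hip-minus-thigh offset driver
    pelvis_tilt_amp_mean: float = 1.0    # deg
    pelvis_tilt_amp_sd: float = 0.2

    # affine relation hip = 2*amp_p + b1*thigh + b2*LL + b3*WS + eps
    coef_thigh: float = 1.0
    coef_leg_length: float = 7.0         # deg per m
    coef_speed: float = 2.0              # deg per m/s
    hip_noise_sd: float = 2.0            # eps, deg

    leg_length_mean: float = 0.90
    leg_length_sd: float = 0.11
    speed_levels: tuple[float, ...] = (0.8, 1.2, 1.6)
    # cycle duration (s) = cadence_intercept + cadence_slope * speed
    cadence_intercept: float = 1.5
    cadence_slope: float = -0.25
    duration_jitter_frac: float = 0.03   # stride-time CV within a trial

    misalignment_deg: float = 15.0
    gyro_noise_sd: float = 1.0           # deg/s
    accel_noise_sd: float = 0.05         # m/s^2
    sta_amp: float = 10.0                # deg/s, soft-tissue ringing
    sta_freq: float = 10.0               # Hz
    sta_decay: float = 20.0              # 1/s

    n_harmonics: int = 4
    phase_jitter_sd: float = 0.25        # rad, stride-to-stride shape change
    outofplane_frac: tuple[float, float] = (0.15, 0.20)
    fs: float = 128.0
    gyro_range: float = 2000.0           # deg/s
    accel_range: float = 16.0 * GRAVITY  # m/s^2
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("hip_rom_sd", "hip_rom_cycle_sd", "pelvis_tilt_amp_sd",
                     "hip_noise_sd", "leg_length_sd", "gyro_noise_sd",
                     "accel_noise_sd", "sta_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.speed_levels:
            raise ValueError("speed_levels must be nonempty")
        if not (10.0 <= self.hip_rom_mean <= 60.0):
            raise ValueError("hip_rom_mean must lie in [10, 60] degrees")
        top = max(self.n_harmonics + 2, 1) / self.min_cycle_duration
        top = max(top, self.sta_freq)
        if self.fs <= 2.0 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest simulated "
                f"frequency ({top:.2f} Hz)")
        if self.n_participants < 1 or self.cycles_per_trial < 1:
            raise ValueError("counts must be positive")

    @property
    def min_cycle_duration(self) -> float:
        return min(self.cycle_duration(s) for s in self.speed_levels)

    def cycle_duration(self, speed: float) -> float:
        """Cycle duration in seconds from the linear cadence model."""
        dur = self.cadence_intercept + self.cadence_slope * speed
        if dur <= 0:
            raise ValueError("cadence model gives non-positive duration")
        return dur

    def noise_free(self) -> "GaitSimConfig":
        """Copy with every stochastic disturbance switched off."""
        return dataclasses.replace(
            self, hip_rom_cycle_sd=0.0, hip_noise_sd=0.0,
            pelvis_tilt_amp_sd=0.0, gyro_noise_sd=0.0, accel_noise_sd=0.0,
            sta_amp=0.0)


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

class HarmonicWaveform:
    """Periodic angle curve  offset + sum_k a_k cos(2 pi k u + phi_k),
    u in [0, 1] the normalized cycle time."""

    def __init__(self, amps: np.ndarray, phases: np.ndarray,
                 offset: float = 0.0):
        self.amps = np.asarray(amps, dtype=float)
        self.phases = np.asarray(phases, dtype=float)
        self.offset = float(offset)
        self._k = np.arange(1, len(self.amps) + 1)

    def angle(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        arg = 2.0 * np.pi * np.outer(u, self._k) + self.phases
        return self.offset + np.cos(arg) @ self.amps

    def rate(self, u: np.ndarray, duration: float) -> np.ndarray:
        """Time derivative in deg/s for a cycle lasting `duration` seconds."""
        u = np.asarray(u, dtype=float)
        arg = 2.0 * np.pi * np.outer(u, self._k) + self.phases
        w = -2.0 * np.pi * self._k * self.amps
        return (np.sin(arg) @ w) / duration

    def sampled(self, n: int = N_POINTS) -> np.ndarray:
        return self.angle(np.linspace(0.0, 1.0, n))

    def scaled(self, factor: float) -> "HarmonicWaveform":
        return HarmonicWaveform(self.amps * factor, self.phases,
                                self.offset * factor)

    def rom(self, n: int = N_POINTS) -> float:
        return float(np.ptp(self.sampled(n)))


def _raw_harmonics(n_harmonics: int, rng: np.random.Generator
                   ) -> HarmonicWaveform:
    # steeply decaying spectrum: sagittal thigh motion during gait is
    # dominated by the stride-frequency fundamental
    amps = 1.0 / np.arange(1, n_harmonics + 1) ** 3
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    wave = HarmonicWaveform(amps, phases)
    # orient so the peak angular-velocity magnitude is positive (the
    # swing-phase flexion peak), matching physiological hip flexion and
    # making the PCA sign rule of the calibration deterministic
    u = np.linspace(0.0, 1.0, 400)
    r = wave.rate(u, 1.0)
    if r.max() < -r.min():
        wave = HarmonicWaveform(amps, phases + np.pi)
    return wave


def _hip_waveform(rom: float, n_harmonics: int, rng: np.random.Generator
                  ) -> HarmonicWaveform:
    if rom <= 0:
        raise ValueError("rom must be positive")
    wave = _raw_harmonics(n_harmonics, rng)
    wave = wave.scaled(rom / wave.rom())
    # anchor the cycle start at zero degrees so consecutive cycles join
    # continuously in angle
    wave.offset = -float(wave.angle(np.array([0.0]))[0])
    return wave


def hip_flexion_waveform(rom: float, n_harmonics: int = 4,
                         phase_seed: int = 0) -> np.ndarray:
    """A smooth periodic sagittal hip angle cycle with range exactly `rom`.

    Returns a 100-point series in degrees; the first and last points
    coincide (full-period harmonics).
    """
    if rom <= 0:
        raise ValueError("rom must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    rng = np.random.default_rng(phase_seed)
    return _hip_waveform(rom, n_harmonics, rng).sampled()


def thigh_from_hip(hip_waveform: np.ndarray, pelvis_tilt_amp: float,
                   phase: float = 0.0) -> np.ndarray:
    """Thigh angle = hip angle minus a sinusoidal pelvis-tilt contribution."""
    hip = np.asarray(hip_waveform, dtype=float)
    if hip.ndim != 1:
        raise ValueError("hip_waveform must be a 1-D angle series")
    if pelvis_tilt_amp < 0:
        raise ValueError("pelvis_tilt_amp must be >= 0")
    u = np.linspace(0.0, 1.0, len(hip))
    return hip - pelvis_tilt_amp * np.sin(2.0 * np.pi * u + phase)


def _thigh_waveform(hip: HarmonicWaveform, thigh_rom_target: float
                    ) -> HarmonicWaveform:
    """Thigh angle = hip angle minus a pelvis-tilt contribution.

    The pelvis tilt is modelled as a scaled copy of the hip waveform (pelvic
    tilt oscillates in phase with hip flexion during gait), so subtracting
    it scales the waveform: range(thigh) == thigh_rom_target exactly, with
    extremes coinciding with the hip extremes.
    """
    hip_rom = hip.rom()
    kappa = 1.0 - thigh_rom_target / hip_rom
    wave = hip.scaled(1.0 - kappa)
    wave.offset = -float(
        HarmonicWaveform(wave.amps, wave.phases).angle(np.array([0.0]))[0])
    return wave


# ---------------------------------------------------------------------------
# IMU sensor model
# ---------------------------------------------------------------------------

@dataclass
class IMURecording:
    """Synchronized tri-axial gyroscope / accelerometer streams."""

    t: np.ndarray                 # s
    gyro: np.ndarray              # (N, 3) deg/s, sensor frame
    accel: np.ndarray             # (N, 3) m/s^2, sensor frame
    fs: float
    gyro_range: float = 2000.0
    accel_range: float = 16.0 * GRAVITY

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if not (len(self.t) == len(self.gyro) == len(self.accel)):
            raise ValueError("t, gyro and accel must share a length")

    def gyro_series(self) -> TimeSeries:
        return TimeSeries(self.t, self.gyro, self.fs)

    def accel_series(self) -> TimeSeries:
        return TimeSeries(self.t, self.accel, self.fs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "gx": self.gyro[:, 0], "gy": self.gyro[:, 1],
            "gz": self.gyro[:, 2],
            "ax": self.accel[:, 0], "ay": self.accel[:, 1],
            "az": self.accel[:, 2]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float | None = None
                   ) -> "IMURecording":
        t = df["t"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df[["gx", "gy", "gz"]].to_numpy(float),
                   df[["ax", "ay", "az"]].to_numpy(float), fs)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("misalignment must be a proper rotation matrix")
    return R


def _sta_burst(t_rel: np.ndarray, cfg: GaitSimConfig) -> np.ndarray:
    """Exponentially damped oscillation triggered at a heel strike."""
    return (cfg.sta_amp * np.exp(-cfg.sta_decay * t_rel)
            * np.sin(2.0 * np.pi * cfg.sta_freq * t_rel))


def _synthesize_imu(thigh_rate: np.ndarray, thigh_angle_deg: np.ndarray,
                    u_in_cycle: np.ndarray, t: np.ndarray,
                    cfg: GaitSimConfig, misalignment: np.ndarray,
                    rng: np.random.Generator,
                    hs_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gyro/accel in the (misaligned) sensor frame for one trial."""
    R_m = misalignment  # segment -> sensor mapping is R_m.T (v_sens = R_m.T v_seg)
    n = len(t)
    peak = max(float(np.max(np.abs(thigh_rate))), 1e-9)
    fx, fz = cfg.outofplane_frac
    phx, phz = rng.uniform(0.0, 2.0 * np.pi, size=2)
    # out-of-plane components at cycle harmonics above the sagittal band,
    # hence orthogonal to the sagittal rate over a full cycle
    nh = cfg.n_harmonics
    omega_seg = np.column_stack([
        fx * peak * np.sin(2.0 * np.pi * (nh + 1) * u_in_cycle + phx),
        thigh_rate,
        fz * peak * np.sin(2.0 * np.pi * (nh + 2) * u_in_cycle + phz)])
    gyro = omega_seg @ R_m  # R_m.T applied to rows

    if cfg.sta_amp > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        burst = np.zeros(n)
        for hs in hs_times:
            mask = t >= hs
            burst[mask] += _sta_burst(t[mask] - hs, cfg)
        gyro = gyro + np.outer(burst, direction)
    if cfg.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, cfg.gyro_noise_sd, size=(n, 3))

    theta = np.deg2rad(thigh_angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # gravity in segment frame: Ry(theta)^T (0,0,g) = (-g sin, 0, g cos)
    g_seg = np.column_stack([-GRAVITY * s, np.zeros_like(s), GRAVITY * c])
    accel = g_seg @ R_m
    if cfg.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, cfg.accel_noise_sd, size=(n, 3))

    gyro = np.clip(gyro, -cfg.gyro_range, cfg.gyro_range)
    accel = np.clip(accel, -cfg.accel_range, cfg.accel_range)
    return gyro, accel


def imu_from_kinematics(thigh_waveform: np.ndarray, cycle_duration: float,
                        cfg: GaitSimConfig,
                        misalignment: np.ndarray | None = None,
                        seed: int | None = None) -> IMURecording:
    """Simulate one gait cycle of IMU data from a 100-point thigh angle.

    The waveform is interpolated with a periodic cubic spline; the gyroscope
    medio-lateral channel is its analytic time derivative (before
    misalignment, artifact and noise).
    """
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    wave = np.asarray(thigh_waveform, dtype=float)
    if misalignment is None:
        misalignment = np.eye(3)
    R_m = _check_rotation(misalignment)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    u_grid = np.linspace(0.0, 1.0, len(wave))
    w = wave.copy()
    if not np.isclose(w[0], w[-1], atol=1e-6 * max(1.0, np.ptp(w))):
        w[-1] = w[0]  # enforce periodicity for the spline
    else:
        w[-1] = w[0]
    spline = CubicSpline(u_grid, w, bc_type="periodic")

    n = int(round(cfg.fs * cycle_duration))
    t = np.arange(n) / cfg.fs
    u = (t / cycle_duration) % 1.0
    angle = spline(u)
    rate = spline(u, 1) / cycle_duration
    gyro, accel = _synthesize_imu(rate, angle, u, t, cfg, R_m, rng,
                                  hs_times=np.array([0.0]))
    return IMURecording(t, gyro, accel, cfg.fs,
                        cfg.gyro_range, cfg.accel_range)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class TrialData:
    """One walking trial of one participant-side at one speed."""

    trial_id: str
    group_id: str            # participant-side: the cross-validation group
    participant: str
    side: str
    visit: int
    walking_speed: float     # m/s
    leg_length: float        # m
    cycle_duration: float    # s
    imu: IMURecording
    events: np.ndarray       # heel-strike times, len = n_cycles + 1
    truth: pd.DataFrame      # cycle_index, hip_rom, thigh_rom
    hip_waveforms: np.ndarray    # (n_cycles, 100) deg
    thigh_waveforms: np.ndarray  # (n_cycles, 100) deg
    misalignment: np.ndarray     # segment->sensor rotation offset (3,3)

    @property
    def ml_axis_true(self) -> np.ndarray:
        """True medio-lateral (flexion) axis expressed in the sensor frame."""
        return self.misalignment.T @ np.array([0.0, 1.0, 0.0])


@dataclass
class Cohort:
    config: GaitSimConfig
    trials: list[TrialData] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            df = tr.truth.copy()
            df["trial_id"] = tr.trial_id
            df["group_id"] = tr.group_id
            df["leg_length"] = tr.leg_length
            df["walking_speed"] = tr.walking_speed
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write(self, out_dir: str | Path) -> None:
        """Write the CSV/JSON interchange files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta: dict[str, dict] = {}
        for tr in self.trials:
            tag = tr.trial_id
            tr.imu.to_frame().to_csv(out / f"imu_{tag}.csv", index=False)
            pd.DataFrame({
                "cycle_index": np.arange(len(tr.events) - 1),
                "heel_strike_t": tr.events[:-1],
            }).to_csv(out / f"events_{tag}.csv", index=False)
            tr.truth.to_csv(out / f"truth_{tag}.csv", index=False)
            meta[tag] = {
                "leg_length_m": tr.leg_length,
                "walking_speed_mps": tr.walking_speed,
                "participant": tr.participant,
                "side": tr.side,
                "visit": tr.visit,
                "group_id": tr.group_id,
            }
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def _random_misalignment(rng: np.random.Generator, max_deg: float
                         ) -> np.ndarray:
    if max_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def simulate_cohort(cfg: GaitSimConfig) -> Cohort:
    """Generate the full synthetic cohort. Deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    ws_mean = float(np.mean(cfg.speed_levels))
    cohort = Cohort(cfg)

    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        leg_length = rng.normal(cfg.leg_length_mean, cfg.leg_length_sd)
        leg_length = float(np.clip(leg_length, 0.6, 1.2))
        for side in cfg.sides:
            group = f"{pid}-{side}"
            amp_p = max(rng.normal(cfg.pelvis_tilt_amp_mean,
                                   cfg.pelvis_tilt_amp_sd), 0.0)
            misalignment = _random_misalignment(rng, cfg.misalignment_deg)
            for visit in range(1, cfg.visits + 1):
                hip_base = rng.normal(cfg.hip_rom_mean, cfg.hip_rom_sd)
                hip_base = float(np.clip(hip_base, 12.0, 70.0))
                shape = _raw_harmonics(cfg.n_harmonics, rng)
                for k in range(cfg.trials_per_participant):
                    speed = cfg.speed_levels[k % len(cfg.speed_levels)]
                    trial_id = f"{pid}-{side}-V{visit}-T{k + 1}"
                    trial = _simulate_trial(
                        cfg, rng, shape, trial_id, group, pid, side, visit,
                        speed, leg_length, hip_base, amp_p, misalignment,
                        ws_mean)
                    cohort.trials.append(trial)
    return cohort


def _simulate_trial(cfg: GaitSimConfig, rng: np.random.Generator,
                    shape: HarmonicWaveform, trial_id: str, group: str,
                    pid: str, side: str, visit: int, speed: float,
                    leg_length: float, hip_base: float, amp_p: float,
                    misalignment: np.ndarray, ws_mean: float) -> TrialData:
    duration = cfg.cycle_duration(speed)
    ncyc = cfg.cycles_per_trial
    if cfg.duration_jitter_frac > 0:
        durations = duration * (1.0 + np.clip(
            rng.normal(0.0, cfg.duration_jitter_frac, size=ncyc),
            -0.3, 0.3))
    else:
        durations = np.full(ncyc, duration)
    events = np.concatenate([[0.0], np.cumsum(durations)])

    # the thigh ROM is the exogenous driver; the hip ROM then follows the
    # affine relation with independent noise, so OLS on (thigh, leg
    # length, speed) is unbiased for the generating coefficients
    mean_offset = (2.0 * amp_p + cfg.coef_leg_length * leg_length
                   + cfg.coef_speed * ws_mean)
    thigh_base = (hip_base - mean_offset) / cfg.coef_thigh
    thigh_speed_slope = ((cfg.hip_rom_speed_slope - cfg.coef_speed)
                         / cfg.coef_thigh)

    hip_waves: list[HarmonicWaveform] = []
    thigh_waves: list[HarmonicWaveform] = []
    hip_roms = np.empty(ncyc)
    thigh_roms = np.empty(ncyc)
    for c in range(ncyc):
        thigh_rom = (thigh_base + thigh_speed_slope * (speed - ws_mean)
                     + rng.normal(0.0, cfg.hip_rom_cycle_sd))
        thigh_rom = float(np.clip(thigh_rom, 2.0, 70.0))
        eps = rng.normal(0.0, cfg.hip_noise_sd)
        hip_rom = (2.0 * amp_p + cfg.coef_thigh * thigh_rom
                   + cfg.coef_leg_length * leg_length
                   + cfg.coef_speed * speed + eps)
        # the pelvis contribution cannot be negative; essentially never
        # binds under the default offset of ~10 deg
        hip_rom = max(hip_rom, thigh_rom + 0.1)

        # stride-to-stride variability: jitter the harmonic phases a little
        if cfg.phase_jitter_sd > 0:
            cyc_shape = HarmonicWaveform(
                shape.amps,
                shape.phases + rng.normal(0.0, cfg.phase_jitter_sd,
                                          size=len(shape.phases)))
        else:
            cyc_shape = shape
        hip_wave = cyc_shape.scaled(hip_rom / cyc_shape.rom())
        hip_wave.offset = -float(hip_wave.angle(np.array([0.0]))[0])
        thigh_wave = _thigh_waveform(hip_wave, thigh_rom)

        hip_waves.append(hip_wave)
        thigh_waves.append(thigh_wave)
        hip_roms[c] = hip_wave.rom()
        thigh_roms[c] = thigh_wave.rom()

    # sample the trial on a single uniform grid; cycles join continuously
    # because every cycle's thigh angle is anchored at zero at heel strike
    n = int(round(cfg.fs * events[-1])) + 1
    t = np.arange(n) / cfg.fs
    cyc_idx = np.clip(np.searchsorted(events, t, side="right") - 1,
                      0, ncyc - 1)
    u = np.clip((t - events[cyc_idx]) / durations[cyc_idx], 0.0, 1.0)
    angle = np.empty(n)
    rate = np.empty(n)
    for c in range(ncyc):
        m = cyc_idx == c
        angle[m] = thigh_waves[c].angle(u[m])
        rate[m] = thigh_waves[c].rate(u[m], durations[c])

    gyro, accel = _synthesize_imu(rate, angle, u, t, cfg, misalignment, rng,
                                  hs_times=events[:-1])
    imu = IMURecording(t, gyro, accel, cfg.fs, cfg.gyro_range,
                       cfg.accel_range)
    truth = pd.DataFrame({
        "cycle_index": np.arange(ncyc),
        "hip_rom": hip_roms,
        "thigh_rom": thigh_roms})
    return TrialData(
        trial_id=trial_id, group_id=group, participant=pid, side=side,
        visit=visit, walking_speed=speed, leg_length=leg_length,
        cycle_duration=duration, imu=imu, events=events, truth=truth,
        hip_waveforms=np.vstack([w.sampled() for w in hip_waves]),
        thigh_waveforms=np.vstack([w.sampled() for w in thigh_waves]),
        misalignment=misalignment)
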