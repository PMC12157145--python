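"""Sensor-to-segment functional calibration and per-cycle thigh flexion ROM.

The thigh medio-lateral (flexion-extension) axis is estimated functionally:
during walking the dominant component of the thigh angular velocity lies
along that axis, so it is recovered as the first principal component of the
3-D gyroscope signal. The sagittal thigh angle then comes either from direct
trapezoidal integration of the medio-lateral angular velocity restarted at
every gait cycle (strapdown), or from quaternion sensor fusion of gyroscope
and accelerometer (complementary or error-state Kalman filter) followed by a
ZYX Euler decomposition in the calibrated segment frame. Per-cycle ROM is
the range of the sagittal angle within the cycle.

Quaternions are Hamilton convention, scalar-first, body-to-world.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .signals import TimeSeries

METHOD_ORDER = ("strapdown", "complementary", "kalman")
GRAVITY = 9.81


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SegmentCalibration:
    """Rotation from the sensor frame to the anatomical segment frame.

    Rows of `rotation` are the segment axes (anterior, medio-lateral,
    longitudinal) expressed in sensor coordinates: v_segment = R @ v_sensor.
    """

    rotation: np.ndarray
    ml_axis: np.ndarray
    pca_explained: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.ml_axis = np.asarray(self.ml_axis, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")
        if not np.isclose(np.linalg.norm(self.ml_axis), 1.0, atol=1e-6):
            raise ValueError("ml_axis must be a unit vector")
        if not 0.0 <= self.pca_explained <= 1.0:
            raise ValueError("pca_explained must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.ravel().tolist(),
                "ml_axis": self.ml_axis.tolist(),
                "pca_explained": self.pca_explained}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentCalibration":
        return cls(np.asarray(d["rotation"], dtype=float).reshape(3, 3),
                   np.asarray(d["ml_axis"], dtype=float),
                   float(d["pca_explained"]))


@dataclass
class OrientationSeries:
    """Unit quaternion per sample (scalar-first, Hamilton, body-to-world)."""

    quaternions: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must be an (N, 4) array")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit-norm within 1e-6")

    def __len__(self) -> int:
        return len(self.quaternions)

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternions, scalar_first=True)


@dataclass
class CycleROM:
    cycle_index: int
    thigh_rom: float
    method: str = "strapdown"
    gimbal_warning: bool = False

    def __post_init__(self) -> None:
        if self.thigh_rom < 0:
            raise ValueError("thigh_rom must be >= 0")


# ---------------------------------------------------------------------------
# functional calibration
# ---------------------------------------------------------------------------

def functional_calibration(gyro: TimeSeries,
                           long_axis_hint: np.ndarray = (0.0, 0.0, 1.0)
                           ) -> SegmentCalibration:
    """Estimate the thigh medio-lateral axis by PCA of walking gyro data.

    The first principal axis of the mean-removed 3-D angular velocity is
    taken as the medio-lateral axis. Its sign is fixed deterministically:
    first the largest-magnitude component is made positive, then the axis is
    flipped if the peak projected angular velocity (the swing-phase flexion
    burst) is negative, so that flexion is positive. The segment frame is
    completed by Gram-Schmidt orthogonalization of the longitudinal-axis
    hint against the medio-lateral axis.
    """
    X = gyro.values
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("gyro must be a tri-axial time series")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(len(Xc) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] < 1e-12 or evals[1] / evals[0] < 1e-10:
        raise ValueError("degenerate angular-velocity covariance (rank < 2)")

    ml = evecs[:, 0]
    if ml[np.argmax(np.abs(ml))] < 0:
        ml = -ml
    proj = X @ ml
    if proj.max() < -proj.min():  # flexion peak must be positive
        ml = -ml

    explained = float(evals[0] / evals.sum())
    if explained < 0.6:
        warnings.warn(
            f"dominant rotation explains only {explained:.2f} of the "
            "angular-velocity variance; calibration may be unreliable",
            stacklevel=2)

    hint = np.asarray(long_axis_hint, dtype=float)
    hint = hint / np.linalg.norm(hint)
    long_axis = hint - (hint @ ml) * ml
    nrm = np.linalg.norm(long_axis)
    if nrm < 1e-8:
        raise ValueError("long_axis_hint is parallel to the estimated "
                         "medio-lateral axis")
    long_axis /= nrm
    anterior = np.cross(ml, long_axis)
    R = np.vstack([anterior, ml, long_axis])
    return SegmentCalibration(rotation=R, ml_axis=ml,
                              pca_explained=explained)


# ---------------------------------------------------------------------------
# strapdown integration
# ---------------------------------------------------------------------------

def strapdown_cycle_angle(gyro_ml: np.ndarray, fs: float
                          ) -> tuple[np.ndarray, float]:
    """Trapezoidal integration of one cycle's medio-lateral angular velocity.

    The angle starts at zero at the cycle's heel strike (integration is
    restarted every cycle, so drift cannot accumulate across cycles);
    returns the angle series (deg) and its range (the thigh ROM).
    """
    w = np.asarray(gyro_ml, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("cycle must be a 1-D series of >= 2 samples")
    angle = np.concatenate([[0.0], cumulative_trapezoid(w, dx=1.0 / fs)])
    return angle, float(np.ptp(angle))


def rom_by_strapdown(gyro_ml_cycles: list[np.ndarray], fs: float
                     ) -> list[CycleROM]:
    out = []
    for i, cyc in enumerate(gyro_ml_cycles):
        _, rom = strapdown_cycle_angle(cyc, fs)
        out.append(CycleROM(i, rom, "strapdown"))
    return out


# ---------------------------------------------------------------------------
# quaternion helpers
# ---------------------------------------------------------------------------

def _quat_mul(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2])


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    return np.concatenate([[np.cos(0.5 * angle)],
                           np.sin(0.5 * angle) * axis])


def _rotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """R(q)^T v, i.e. a world vector expressed in the body frame."""
    w, x, y, z = q
    # conjugate rotation applied to v
    t = 2.0 * np.cross(np.array([-x, -y, -z]), v)
    return v + w * t + np.cross(np.array([-x, -y, -z]), t)


def _init_from_accel(accel0: np.ndarray) -> np.ndarray:
    """Zero-yaw initial orientation whose gravity prediction matches the
    first accelerometer sample; identity if the sample is degenerate."""
    nrm = np.linalg.norm(accel0)
    if nrm < 1e-8:
        return np.array([1.0, 0.0, 0.0, 0.0])
    a = accel0 / nrm
    ez = np.array([0.0, 0.0, 1.0])
    rot, _ = Rotation.align_vectors(ez[None, :], a[None, :])
    q = rot.inv().as_quat(scalar_first=True)
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# sensor fusion
# ---------------------------------------------------------------------------

def complementary_orientation(gyro: TimeSeries, accel: TimeSeries,
                              gain: float = 0.02) -> OrientationSeries:
    """Complementary filter: gyro quaternion propagation, tilt-corrected
    toward the accelerometer gravity direction with weight `gain` per sample.

    With gain 0 this is pure strapdown quaternion integration; gains of a
    few percent bound pitch/roll drift while barely touching the short-term
    gyro dynamics. Zero-norm accelerometer samples skip the correction.
    """
    if not 0.0 <= gain <= 1.0:
        raise ValueError("gain must lie in [0, 1]")
    if len(gyro) != len(accel) or not np.isclose(gyro.fs, accel.fs):
        raise ValueError("gyro and accel must be synchronized at one rate")
    omega = np.deg2rad(gyro.values)
    acc = accel.values
    dt = 1.0 / gyro.fs
    n = len(omega)
    ez = np.array([0.0, 0.0, 1.0])

    q = _init_from_accel(acc[0])
    quats = np.empty((n, 4))
    quats[0] = q
    for k in range(1, n):
        q = _quat_mul(q, _quat_from_rotvec(omega[k] * dt))
        if gain > 0.0:
            nrm = np.linalg.norm(acc[k])
            if nrm > 1e-8:
                a_hat = acc[k] / nrm
                v = _rotate_inv(q, ez)  # predicted gravity direction
                cross = np.cross(a_hat, v)
                s = np.linalg.norm(cross)
                if s > 1e-12:
                    angle = np.arctan2(s, float(np.clip(a_hat @ v, -1, 1)))
                    q = _quat_mul(q, _quat_from_rotvec(
                        gain * angle * cross / s))
        q = q / np.linalg.norm(q)
        quats[k] = q
    return OrientationSeries(quats, gyro.fs)


def kalman_orientation(gyro: TimeSeries, accel: TimeSeries,
                       gyro_noise_sd: float = 1.0,
                       accel_noise_sd: float = 0.05) -> OrientationSeries:
    """Error-state Kalman filter: predict with the gyroscope, correct tilt
    with the accelerometer gravity direction.

    `gyro_noise_sd` is in deg/s, `accel_noise_sd` in m/s^2; both must be
    positive (they define the process and measurement covariances). As the
    measurement noise grows the filter tends to pure gyro integration.
    """
    if gyro_noise_sd <= 0 or accel_noise_sd <= 0:
        raise ValueError("noise standard deviations must be positive")
    if len(gyro) != len(accel) or not np.isclose(gyro.fs, accel.fs):
        raise ValueError("gyro and accel must be synchronized at one rate")
    omega = np.deg2rad(gyro.values)
    acc = accel.values
    dt = 1.0 / gyro.fs
    n = len(omega)
    ez = np.array([0.0, 0.0, 1.0])

    q = _init_from_accel(acc[0])
    P = np.eye(3) * 1e-4
    Q = np.eye(3) * (np.deg2rad(gyro_noise_sd) * dt) ** 2
    Rm = np.eye(3) * (accel_noise_sd / GRAVITY) ** 2
    quats = np.empty((n, 4))
    quats[0] = q
    for k in range(1, n):
        q = _quat_mul(q, _quat_from_rotvec(omega[k] * dt))
        P = P + Q
        nrm = np.linalg.norm(acc[k])
        if nrm > 1e-8:
            a_hat = acc[k] / nrm
            v = _rotate_inv(q, ez)
            # measurement model: a_hat ~ v + [v]x dtheta
            H = np.array([[0.0, -v[2], v[1]],
                          [v[2], 0.0, -v[0]],
                          [-v[1], v[0], 0.0]])
            S = H @ P @ H.T + Rm
            K = P @ H.T @ np.linalg.inv(S)
            dtheta = K @ (a_hat - v)
            q = _quat_mul(q, _quat_from_rotvec(dtheta))
            P = (np.eye(3) - K @ H) @ P
        q = q / np.linalg.norm(q)
        quats[k] = q
    return OrientationSeries(quats, gyro.fs)


# ---------------------------------------------------------------------------
# Euler angles and fused ROM
# ---------------------------------------------------------------------------

def euler_zyx(q: OrientationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Intrinsic Z-Y-X Euler decomposition in degrees, unwrapped per series.

    Returns (angles, gimbal_flags): angles is (N, 3) as (yaw, pitch, roll);
    flags mark samples with |pitch| > 89.9 deg (gimbal proximity).
    """
    with warnings.catch_warnings():
        # gimbal proximity is reported through the returned flags instead
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = q.as_rotation().as_euler("ZYX", degrees=True)
    flags = np.abs(ang[:, 1]) > 89.9
    ang = np.unwrap(ang, period=360.0, axis=0)
    return ang, flags


def rom_by_fusion(q: OrientationSeries, cal: SegmentCalibration,
                  events: np.ndarray, method: str = "complementary",
                  t0: float = 0.0) -> list[CycleROM]:
    """Per-cycle sagittal ROM from fused orientations.

    The orientation is expressed in the calibrated segment frame, the
    sagittal angle is the Euler rotation about the calibrated medio-lateral
    axis (the pitch of the ZYX triplet), and ROM is its range within each
    half-open cycle.
    """
    R_sens = q.as_rotation()
    R_seg = R_sens * Rotation.from_matrix(cal.rotation.T)
    seg_q = R_seg.as_quat(scalar_first=True)
    seg_q /= np.linalg.norm(seg_q, axis=1, keepdims=True)
    ang, flags = euler_zyx(OrientationSeries(seg_q, q.fs))
    sagittal = ang[:, 1]

    t = t0 + np.arange(len(sagittal)) / q.fs
    ev = np.asarray(events, dtype=float)
    if len(ev) < 2:
        return []
    idx = np.searchsorted(t, ev, side="left")
    out = []
    for i, (i0, i1) in enumerate(zip(idx[:-1], idx[1:])):
        if i1 - i0 < 2:
            raise ValueError(f"cycle {i} contains fewer than 2 samples")
        out.append(CycleROM(i, float(np.ptp(sagittal[i0:i1])), method,
                            gimbal_warning=bool(flags[i0:i1].any())))
    return out


def select_best_method(candidates: dict[str, list[CycleROM] | np.ndarray],
                       reference: np.ndarray
                       ) -> tuple[str, pd.DataFrame]:
    """Pick the ROM method with the lowest MAE against a reference.

    Ties are broken by the canonical order strapdown, complementary, kalman,
    then by insertion order for any additional methods.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    ref = np.asarray(reference, dtype=float)
    order = [m for m in METHOD_ORDER if m in candidates]
    order += [m for m in candidates if m not in order]
    rows = []
    for name in order:
        vals = candidates[name]
        if len(vals) and isinstance(vals[0], CycleROM):
            roms = np.array([c.thigh_rom for c in vals], dtype=float)
        else:
            roms = np.asarray(vals, dtype=float)
        if len(roms) != len(ref):
            raise ValueError(f"method {name!r} does not cover all cycles")
        rows.append({"method": name,
                     "mae": float(np.mean(np.abs(roms - ref)))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mae"].idxmin(), "method"]  # idxmin: first min
    return str(best), table
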