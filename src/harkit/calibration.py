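"""Sensor-to-segment calibration and lower-limb joint angles.

The anatomical segment frame is right-handed with X pointing head-ward
(vertical while standing), Y medial and Z forward.  Because wearable
units are strapped on with poorly repeatable orientation, the rotation
``R_seg_sen`` between each segment frame and its sensor frame must be
identified from the data itself:

* the segment X axis in sensor coordinates is the direction of the mean
  gravity reaction measured during the quiet standing phase;
* for the lower back, the Z (forward) axis comes from the lying phase
  the same way, orthogonalized against X (Gram–Schmidt);
* for thigh and shank, the Y axis is the knee flexion/extension axis,
  identified by the hinge-constraint self-calibration: the joint axis
  pair (j1, j2) minimizes ``sum((|g1 x j1| - |g2 x j2|)^2)`` over a
  motion window, since a hinge forces the angular-velocity components
  orthogonal to the axis to agree in magnitude on both sides;
* the remaining axis is the cross product of the other two.

With ``R_seg_sen`` in hand, IMU samples are rotated into segment
coordinates ("calibrated" data), and joint angles follow from composing
each sensor's attitude quaternion with its calibration, referencing all
segment frames to identity at a standing snapshot, and measuring the
angle between the longitudinal (X) axes of the two segments flanking
the joint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .quaternion import MahonyFilter
from .recording import Channel, SignalRecording

__all__ = [
    "SegmentCalibration",
    "JointAngleTrace",
    "calibrate_axes",
    "estimate_knee_axis",
    "correct_imu",
    "estimate_attitudes",
    "joint_angles",
    "CalibrationError",
]

_AXIS_ORDER = ("x", "y", "z")


class CalibrationError(RuntimeError):
    pass


@dataclass
class SegmentCalibration:
    """Axes of the segment frame expressed in the sensor frame."""

    segment: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """R_seg_sen: columns are the segment axes in sensor coordinates.

        Maps segment coordinates to sensor coordinates; its transpose
        takes raw sensor samples into the anatomical segment frame.
        """
        return np.column_stack([self.x, self.y, self.z])

    def __post_init__(self) -> None:
        R = np.column_stack([self.x, self.y, self.z])
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError(f"segment {self.segment!r}: axes not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError(f"segment {self.segment!r}: left-handed axes")

    def to_dict(self) -> dict:
        return {
            "segment": self.segment,
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "z": self.z.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentCalibration":
        return cls(
            segment=d["segment"],
            x=np.asarray(d["x"], dtype=float),
            y=np.asarray(d["y"], dtype=float),
            z=np.asarray(d["z"], dtype=float),
        )


@dataclass
class JointAngleTrace:
    joint: str
    time: np.ndarray
    angle_deg: np.ndarray
    rate: float


def _sensor_matrix(rec: SignalRecording, segment: str, modality: str) -> tuple[np.ndarray, float]:
    """(n, 3) sample matrix in axis order x, y, z for one segment/modality."""
    chans = [
        ch
        for ch in rec.channels.values()
        if ch.segment == segment and ch.modality == modality
    ]
    if len(chans) != 3:
        raise CalibrationError(
            f"segment {segment!r}: expected 3 {modality} channels, found {len(chans)}"
        )
    chans.sort(key=lambda ch: _AXIS_ORDER.index(ch.axis))
    return np.stack([ch.data for ch in chans], axis=1), chans[0].rate


def _phase_mean(data: np.ndarray, rate: float, phase: tuple[float, float]) -> np.ndarray:
    i0, i1 = int(round(phase[0] * rate)), int(round(phase[1] * rate))
    return data[i0:i1].mean(axis=0), data[i0:i1]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise CalibrationError("zero-norm axis")
    return v / n


def _orthogonalize(second: np.ndarray, first: np.ndarray, what: str) -> np.ndarray:
    """Project `second` orthogonal to `first` (Gram–Schmidt) and renormalize."""
    angle = np.degrees(np.arccos(np.clip(abs(second @ first), 0.0, 1.0)))
    if angle < 15.0:
        raise CalibrationError(
            f"{what}: measured axes nearly parallel ({angle:.1f} deg apart)"
        )
    return _unit(second - (second @ first) * first)


def estimate_knee_axis(
    gyro_a: np.ndarray,
    gyro_b: np.ndarray,
    excitation_threshold: float = 0.2,
    max_nfev: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Hinge-axis self-calibration from two synchronized gyroscope streams.

    Returns unit axes (j_a, j_b), one per sensor frame, minimizing the
    hinge residual ``|g_a x j_a| - |g_b x j_b|`` by nonlinear least
    squares on spherical coordinates, multi-started from four initial
    axes to escape local minima.  Axis signs are not identifiable from
    the residual and are normalized so the largest-magnitude component
    is positive; callers with an anatomical reference fix signs
    afterwards.
    """
    ga = np.asarray(gyro_a, dtype=float)
    gb = np.asarray(gyro_b, dtype=float)
    if ga.shape != gb.shape or ga.ndim != 2 or ga.shape[1] != 3:
        raise ValueError("gyro streams must be matching (n, 3) arrays")
    energy = max(np.linalg.norm(ga, axis=1).mean(), np.linalg.norm(gb, axis=1).mean())
    if energy < excitation_threshold:
        raise CalibrationError(
            f"insufficient gyroscope excitation ({energy:.3g} rad/s mean)"
        )

    def sph(theta: float, phi: float) -> np.ndarray:
        return np.array(
            [np.cos(phi) * np.cos(theta), np.cos(phi) * np.sin(theta), np.sin(phi)]
        )

    def residual(p: np.ndarray) -> np.ndarray:
        ja, jb = sph(p[0], p[1]), sph(p[2], p[3])
        return np.linalg.norm(np.cross(ga, ja), axis=1) - np.linalg.norm(
            np.cross(gb, jb), axis=1
        )

    inits = [
        np.array([0.0, 0.0, 0.0, 0.0]),
        np.array([np.pi / 2, 0.0, np.pi / 2, 0.0]),
        np.array([0.0, np.pi / 2, 0.0, np.pi / 2]),
        np.array([np.pi / 4, np.pi / 4, np.pi / 4, np.pi / 4]),
    ]
    best = None
    for p0 in inits:
        sol = least_squares(residual, p0, xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    ja, jb = sph(best.x[0], best.x[1]), sph(best.x[2], best.x[3])

    def fix_sign(j: np.ndarray) -> np.ndarray:
        k = int(np.argmax(np.abs(j)))
        return j if j[k] >= 0 else -j

    return fix_sign(ja), fix_sign(jb)


def calibrate_axes(
    rec: SignalRecording,
    medial_reference: dict[str, np.ndarray] | None = None,
    static_threshold: float = 0.1,
) -> dict[str, SegmentCalibration]:
    """Identify R_seg_sen for every IMU-bearing segment.

    Requires a standing phase; a lying phase for the lower back; and a
    knee flexion/extension motion phase (``rec.motion_phase``, falling
    back to everything after standing) when thigh and shank are present.
    ``medial_reference`` optionally gives, per segment, a sensor-frame
    vector with positive dot product against the true medial (Y) axis,
    resolving the hinge axis sign.
    """
    if rec.standing_phase is None:
        raise CalibrationError("calibration requires a standing phase")
    segments = sorted(
        {ch.segment for ch in rec.channels.values() if ch.modality in ("acc", "gyr") and ch.segment}
    )
    out: dict[str, SegmentCalibration] = {}

    x_axes: dict[str, np.ndarray] = {}
    for seg in segments:
        acc, rate = _sensor_matrix(rec, seg, "acc")
        mean_vec, window = _phase_mean(acc, rate, rec.standing_phase)
        norms = np.linalg.norm(window, axis=1)
        if norms.std() > static_threshold * max(norms.mean(), 1e-12):
            raise CalibrationError(f"segment {seg!r}: standing phase not static")
        x_axes[seg] = _unit(mean_vec)

    knee_axes: dict[str, np.ndarray] = {}
    if "thigh" in segments and "shank" in segments:
        phase = rec.motion_phase or (rec.standing_phase[1], rec.duration)
        gt, rt = _sensor_matrix(rec, "thigh", "gyr")
        gs, rs = _sensor_matrix(rec, "shank", "gyr")
        _, wt = _phase_mean(gt, rt, phase)
        _, ws = _phase_mean(gs, rs, phase)
        ja, jb = estimate_knee_axis(wt, ws)
        knee_axes["thigh"], knee_axes["shank"] = ja, jb

    for seg in segments:
        x = x_axes[seg]
        if seg in knee_axes:
            y_raw = knee_axes[seg]
            if medial_reference and seg in medial_reference:
                if y_raw @ medial_reference[seg] < 0:
                    y_raw = -y_raw
            y = _orthogonalize(y_raw, x, f"segment {seg!r} (x vs knee axis)")
            z = np.cross(x, y)
        else:
            if rec.lying_phase is None:
                raise CalibrationError(
                    f"segment {seg!r}: lying phase required for the z axis"
                )
            acc, rate = _sensor_matrix(rec, seg, "acc")
            z_raw, _ = _phase_mean(acc, rate, rec.lying_phase)
            z = _orthogonalize(_unit(z_raw), x, f"segment {seg!r} (x vs lying axis)")
            y = np.cross(z, x)
        out[seg] = SegmentCalibration(segment=seg, x=x, y=y, z=z)
    return out


def correct_imu(
    rec: SignalRecording, calibrations: dict[str, SegmentCalibration]
) -> SignalRecording:
    """Rotate accelerometer/gyroscope channels into segment frames.

    Each tri-axial sample v becomes ``R_seg_sen.T @ v``.  With identity
    calibrations the output equals the input — the "without calibration"
    arm of a calibrated-vs-uncalibrated comparison.
    """
    out = rec.copy()
    for seg in sorted(
        {ch.segment for ch in rec.channels.values() if ch.modality in ("acc", "gyr") and ch.segment}
    ):
        if seg not in calibrations:
            raise CalibrationError(f"missing calibration for segment {seg!r}")
        R = calibrations[seg].rotation
        for modality in ("acc", "gyr"):
            chans = [
                ch
                for ch in out.channels.values()
                if ch.segment == seg and ch.modality == modality
            ]
            if not chans:
                continue
            chans.sort(key=lambda ch: _AXIS_ORDER.index(ch.axis))
            data = np.stack([ch.data for ch in chans], axis=1)
            corrected = data @ R  # == (R.T @ v) per row
            for i, ch in enumerate(chans):
                ch.data = corrected[:, i]
    return out


def estimate_attitudes(
    rec: SignalRecording,
    kp: float = 0.5,
    ki: float = 0.0,
) -> dict[str, np.ndarray]:
    """Mahony attitude trace per IMU-bearing segment.

    The filter is initialized from the mean standing accelerometer
    sample (tilt only, zero heading).  Returns, per segment, an (n, 4)
    quaternion trace aligned with the IMU sample clock.
    """
    if rec.standing_phase is None:
        raise CalibrationError("attitude estimation requires a standing phase")
    traces: dict[str, np.ndarray] = {}
    segments = sorted(
        {ch.segment for ch in rec.channels.values() if ch.modality in ("acc", "gyr") and ch.segment}
    )
    for seg in segments:
        acc, rate = _sensor_matrix(rec, seg, "acc")
        gyr, _ = _sensor_matrix(rec, seg, "gyr")
        mean_acc, _ = _phase_mean(acc, rate, rec.standing_phase)
        filt = MahonyFilter(kp=kp, ki=ki)
        filt.initialize_from_accel(mean_acc)
        traces[seg] = filt.run(gyr, acc, 1.0 / rate)
    return traces


def joint_angles(
    rec: SignalRecording,
    calibrations: dict[str, SegmentCalibration],
    traces: dict[str, np.ndarray],
    joints: list[tuple[str, str, str]] | None = None,
) -> dict[str, JointAngleTrace]:
    """Unsigned joint angles between segment longitudinal axes.

    ``joints`` lists (proximal_segment, distal_segment, joint_name);
    the default covers hip flexion (lower back vs thigh) and knee
    flexion (thigh vs shank), keeping whichever pair is present.

    All segment frames are referenced to identity at the end of the
    standing phase, so angles are zero there by construction; the
    arccos form does not distinguish flexion from extension.
    """
    if joints is None:
        joints = [
            ("lower_back", "thigh", "hip_flexion"),
            ("thigh", "shank", "knee_flexion"),
        ]
        joints = [j for j in joints if j[0] in traces and j[1] in traces]
    _, rate = _sensor_matrix(rec, joints[0][0], "acc")
    i0 = int(round(rec.standing_phase[1] * rate)) - 1

    seg_rot: dict[str, np.ndarray] = {}
    for seg in {s for a, b, _ in joints for s in (a, b)}:
        q = traces[seg]
        if not np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-6):
            raise ValueError(f"segment {seg!r}: non-unit quaternion in trace")
        Rsen = Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()
        Rcal = calibrations[seg].rotation
        Rseg = Rsen @ Rcal  # sensor attitude composed with calibration
        # zero the segment frame at the standing snapshot
        seg_rot[seg] = np.einsum("ij,njk->nik", Rseg[i0].T, Rseg)

    out: dict[str, JointAngleTrace] = {}
    n = min(len(seg_rot[a]) for a, b, _ in joints for _ in (0,))
    for prox, dist, name in joints:
        R1, R2 = seg_rot[prox], seg_rot[dist]
        if len(R1) != len(R2):
            raise ValueError(f"joint {name!r}: misaligned time bases")
        rel = np.einsum("nij,njk->nik", R1.transpose(0, 2, 1), R2)
        j2 = rel[:, :, 0]  # distal X axis expressed in the proximal frame
        cosang = np.clip(j2[:, 0], -1.0, 1.0)  # dot with proximal X = e_x
        out[name] = JointAngleTrace(
            joint=name,
            time=np.arange(len(rel)) / rate,
            angle_deg=np.degrees(np.arccos(cosang)),
            rate=rate,
        )
    return out
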