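"""Synthetic test-bed generators.

Three generators stand in for instrumented recordings so the whole
pipeline is testable without wearable hardware:

* :func:`generate_signals` — class-structured multichannel signals
  (per class and channel: a sinusoid of configurable amplitude,
  frequency and Gaussian noise), tiled into labelled epochs, with an
  optional leading quiet standing segment.
* :func:`generate_rigid_body` — a two-segment hinge (knee-style) rigid
  body: both segments rotate about a shared joint axis, each carrying a
  virtual IMU with a known (configurable) sensor mount rotation.
  Gyroscopes report exact segment angular velocity in sensor
  coordinates; accelerometers report the gravity reaction only (no
  linear-acceleration term), since the calibration algorithms under
  test rely on quasi-static information.  Ground-truth joint angles and
  mount rotations are returned alongside the streams.
* :func:`generate_feature_table` — Gaussian feature tables with a known
  set of informative columns.  The default class-mean pattern assigns
  each informative feature one inter-class boundary (cycling through
  the ``n_classes - 1`` adjacent boundaries), so every informative
  feature either separates a class pair on its own or sharpens a
  boundary covered by a colleague — a structure under which a good
  selector is rewarded for finding all of them.

All generators are deterministic under their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .features import FeatureDef, FeatureTable
from .recording import Channel, LabelInterval, SignalRecording

__all__ = [
    "ChannelSpec",
    "ClassSignalParams",
    "SyntheticSignalSpec",
    "RigidBodySpec",
    "SyntheticFeatureSpec",
    "generate_signals",
    "generate_rigid_body",
    "generate_feature_table",
    "boundary_means",
]


class InvalidSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# class-structured signals


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    modality: str
    rate: float
    sensor: str | None = None
    axis: str | None = None
    segment: str | None = None


@dataclass(frozen=True)
class ClassSignalParams:
    amplitude: float
    freq_hz: float
    noise_sd: float = 0.0


@dataclass
class SyntheticSignalSpec:
    n_classes: int
    channels: list[ChannelSpec]
    #: per class, a mapping channel name -> signal parameters
    class_params: list[dict[str, ClassSignalParams]]
    epoch_duration: float = 10.4
    epochs_per_class: int = 1
    standing_duration: float = 0.0
    standing_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_duration <= 0:
            raise InvalidSpecError("epoch_duration must be positive")
        if self.epochs_per_class < 1:
            raise InvalidSpecError("epochs_per_class must be at least 1")
        if any(c.rate <= 0 for c in self.channels):
            raise InvalidSpecError("channel rates must be positive")
        if len(self.class_params) != self.n_classes:
            raise InvalidSpecError("class_params must list one entry per class")


def generate_signals(spec: SyntheticSignalSpec) -> SignalRecording:
    """Class-dependent sinusoid-plus-noise channels with tiling labels.

    Epochs cycle through the classes round-robin ``epochs_per_class``
    times; label intervals tile the post-standing span exactly.
    """
    rng = np.random.default_rng(spec.seed)
    t_stand = spec.standing_duration
    n_epochs = spec.n_classes * spec.epochs_per_class
    total = t_stand + n_epochs * spec.epoch_duration
    channels: dict[str, Channel] = {}
    epoch_classes = [e % spec.n_classes for e in range(n_epochs)]
    for cs in spec.channels:
        n = int(round(total * cs.rate))
        t = np.arange(n) / cs.rate
        data = np.zeros(n)
        if t_stand > 0 and spec.standing_noise_sd > 0:
            i1 = int(round(t_stand * cs.rate))
            data[:i1] = rng.normal(0.0, spec.standing_noise_sd, i1)
        for e, c in enumerate(epoch_classes):
            p = spec.class_params[c][cs.name]
            t0 = t_stand + e * spec.epoch_duration
            i0 = int(round(t0 * cs.rate))
            i1 = int(round((t0 + spec.epoch_duration) * cs.rate))
            seg_t = t[i0:i1]
            data[i0:i1] = p.amplitude * np.sin(2 * np.pi * p.freq_hz * seg_t)
            if p.noise_sd > 0:
                data[i0:i1] += rng.normal(0.0, p.noise_sd, i1 - i0)
        channels[cs.name] = Channel(
            cs.name, data, cs.rate, cs.modality,
            sensor=cs.sensor, axis=cs.axis, segment=cs.segment,
        )
    labels = [
        LabelInterval(
            t_stand + e * spec.epoch_duration,
            t_stand + (e + 1) * spec.epoch_duration,
            f"class{c}",
        )
        for e, c in enumerate(epoch_classes)
    ]
    return SignalRecording(
        channels=channels,
        labels=labels,
        standing_phase=(0.0, t_stand) if t_stand > 0 else None,
    )


# ---------------------------------------------------------------------------
# rigid-body hinge


@dataclass
class RigidBodySpec:
    #: knee-style flexion trajectory in degrees, of time since motion onset
    angle_trajectory: Callable[[np.ndarray], np.ndarray]
    duration: float
    joint_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    #: true R_seg_sen per segment (columns = segment axes in sensor coords)
    mount_rotations: dict[str, np.ndarray] = field(default_factory=dict)
    gravity: float = 9.81
    rate: float = 200.0
    standing_duration: float = 30.0
    #: peak fraction of the flexion carried by the proximal segment.  The
    #: proximal share ramps up linearly over the motion, so the two
    #: segments' angular-rate profiles are not proportional — with
    #: proportional profiles the hinge-axis objective is degenerate
    #: (any axis pair with a matching sine ratio is an exact minimum)
    proximal_fraction: float = 0.4
    acc_noise_sd: float = 0.0  # m/s^2
    gyr_noise_sd: float = 0.0  # rad/s
    segments: tuple[str, str] = ("thigh", "shank")
    seed: int = 0

    def __post_init__(self) -> None:
        self.joint_axis = np.asarray(self.joint_axis, dtype=float)
        if abs(np.linalg.norm(self.joint_axis) - 1.0) > 1e-6:
            raise InvalidSpecError("joint_axis must be a unit vector")
        if self.rate <= 0 or self.duration <= 0:
            raise InvalidSpecError("rate and duration must be positive")
        for seg in self.segments:
            self.mount_rotations.setdefault(seg, np.eye(3))
        for seg, R in self.mount_rotations.items():
            R = np.asarray(R, dtype=float)
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
                raise InvalidSpecError(
                    f"mount rotation for {seg!r} must be orthonormal with det +1"
                )
            self.mount_rotations[seg] = R
        theta0 = float(np.atleast_1d(self.angle_trajectory(np.array([0.0])))[0])
        if abs(theta0) > 1e-6:
            raise InvalidSpecError("angle trajectory must start at 0 degrees")


def generate_rigid_body(
    spec: RigidBodySpec,
) -> tuple[SignalRecording, np.ndarray, dict[str, np.ndarray]]:
    """Forward-simulate the hinge; returns (recording, truth angles, mounts).

    The truth angle trace (degrees, one value per IMU sample) is the
    angle between the two segments' longitudinal (X) axes computed from
    the exact rotation matrices, so it is valid for any joint axis.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    n_stand = int(round(spec.standing_duration * rate))
    n_motion = int(round(spec.duration * rate))
    n = n_stand + n_motion
    t = np.arange(n) / rate
    theta = np.zeros(n)
    theta[n_stand:] = np.asarray(
        spec.angle_trajectory(t[n_stand:] - t[n_stand]), dtype=float
    )
    theta_rad = np.radians(theta)
    prox, dist = spec.segments
    ramp = np.zeros(n)
    if n_motion > 0:
        ramp[n_stand:] = (t[n_stand:] - t[n_stand]) / max(spec.duration, 1e-12)
    prox_share = spec.proximal_fraction * ramp
    seg_angle = {
        prox: prox_share * theta_rad,
        dist: (prox_share - 1.0) * theta_rad,
    }
    g_ref = np.array([spec.gravity, 0.0, 0.0])  # gravity reaction, up = +X

    channels: dict[str, Channel] = {}
    x_axes = {}
    for seg in spec.segments:
        R_seg_ref = Rotation.from_rotvec(
            np.outer(seg_angle[seg], spec.joint_axis)
        ).as_matrix()  # (n, 3, 3)
        mount = spec.mount_rotations[seg]
        omega_seg = np.outer(np.gradient(seg_angle[seg], t), spec.joint_axis)
        a_seg = np.einsum("nij,j->ni", R_seg_ref.transpose(0, 2, 1), g_ref)
        a_sen = a_seg @ mount.T
        w_sen = omega_seg @ mount.T
        if spec.acc_noise_sd > 0:
            a_sen = a_sen + rng.normal(0.0, spec.acc_noise_sd, a_sen.shape)
        if spec.gyr_noise_sd > 0:
            w_sen = w_sen + rng.normal(0.0, spec.gyr_noise_sd, w_sen.shape)
        for k, axis in enumerate("xyz"):
            channels[f"acc_{seg}_{axis}"] = Channel(
                f"acc_{seg}_{axis}", a_sen[:, k], rate, "acc",
                sensor=f"acc_{seg}", axis=axis, segment=seg,
            )
            channels[f"gyr_{seg}_{axis}"] = Channel(
                f"gyr_{seg}_{axis}", w_sen[:, k], rate, "gyr",
                sensor=f"gyr_{seg}", axis=axis, segment=seg,
            )
        x_axes[seg] = R_seg_ref[:, :, 0]  # segment X axis in the reference frame

    cosang = np.clip(np.sum(x_axes[prox] * x_axes[dist], axis=1), -1.0, 1.0)
    truth_angle = np.degrees(np.arccos(cosang))

    standing = (0.0, spec.standing_duration) if spec.standing_duration > 0 else None
    labels = [LabelInterval(spec.standing_duration, spec.duration + spec.standing_duration, "motion")]
    rec = SignalRecording(
        channels=channels,
        labels=labels,
        standing_phase=standing,
        motion_phase=(spec.standing_duration, spec.standing_duration + spec.duration),
    )
    return rec, truth_angle, dict(spec.mount_rotations)


# ---------------------------------------------------------------------------
# feature tables


def boundary_means(n_classes: int, n_informative: int, gap: float) -> np.ndarray:
    """Default class-mean pattern: informative feature j guards adjacent
    class boundary ``j % (n_classes - 1)`` — classes above the boundary
    are shifted by ``gap``."""
    means = np.zeros((n_classes, n_informative))
    for j in range(n_informative):
        b = j % (n_classes - 1)
        means[b + 1 :, j] = gap
    return means


@dataclass
class SyntheticFeatureSpec:
    n_features: int = 100
    n_informative: int = 5
    n_redundant: int = 0
    n_classes: int = 4
    #: (n_classes, n_informative) matrix; None = boundary pattern at `gap`
    class_means: np.ndarray | None = None
    gap: float = 3.0
    noise_sd: float = 1.0
    samples_per_class: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise InvalidSpecError(
                "n_informative + n_redundant must not exceed n_features"
            )
        if self.samples_per_class is None:
            self.samples_per_class = tuple([100] * self.n_classes)
        if len(self.samples_per_class) != self.n_classes:
            raise InvalidSpecError("samples_per_class must list one count per class")
        if self.class_means is None:
            if self.n_informative > 0:
                self.class_means = boundary_means(
                    self.n_classes, self.n_informative, self.gap
                )
            else:
                self.class_means = np.zeros((self.n_classes, 0))
        self.class_means = np.asarray(self.class_means, dtype=float)
        if self.class_means.shape != (self.n_classes, self.n_informative):
            raise InvalidSpecError("class_means shape must be (n_classes, n_informative)")


def generate_feature_table(
    spec: SyntheticFeatureSpec,
) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Gaussian feature table with known informative structure.

    Returns the table and a truth dict with the ``informative`` and
    ``redundant`` column names.  Redundant columns copy informative
    ones (cycled) plus noise at a tenth of ``noise_sd``; the remaining
    columns are class-independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(sum(spec.samples_per_class))
    labels = np.concatenate(
        [np.full(k, f"class{c}") for c, k in enumerate(spec.samples_per_class)]
    )
    width = len(str(max(spec.n_features - 1, 1)))
    names = [f"f{j:0{width}d}" for j in range(spec.n_features)]
    X = rng.normal(0.0, spec.noise_sd, (n_total, spec.n_features))
    row = 0
    for c, k in enumerate(spec.samples_per_class):
        X[row : row + k, : spec.n_informative] += spec.class_means[c]
        row += k
    for r in range(spec.n_redundant):
        src = r % spec.n_informative
        j = spec.n_informative + r
        X[:, j] = X[:, src] + rng.normal(0.0, spec.noise_sd / 10.0, n_total)
    provenance = {
        name: FeatureDef(name, name, 0, "synthetic", "synthetic", name)
        for name in names
    }
    table = FeatureTable(
        X=pd.DataFrame(X, columns=names), labels=labels, provenance=provenance
    )
    truth = {
        "informative": names[: spec.n_informative],
        "redundant": names[spec.n_informative : spec.n_informative + spec.n_redundant],
    }
    return table, truth
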