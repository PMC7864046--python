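"""Shared fixtures: small synthetic recordings and tables."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import harkit as hk
from harkit.synthetic import ChannelSpec, ClassSignalParams


def raised_cosine(amplitude_deg: float, period_s: float = 2.0):
    """Smooth flexion trajectory: 0 -> amplitude -> 0 each period."""
    return lambda t: amplitude_deg * 0.5 * (1 - np.cos(2 * np.pi * t / period_s))


def hinge_spec(
    amplitude_deg: float = 45.0,
    mounts: dict | None = None,
    standing: float = 5.0,
    duration: float = 10.0,
    acc_noise: float = 0.0,
    gyr_noise: float = 0.0,
    joint_axis: np.ndarray | None = None,
    seed: int = 0,
) -> hk.RigidBodySpec:
    kwargs = {}
    if joint_axis is not None:
        kwargs["joint_axis"] = joint_axis
    return hk.RigidBodySpec(
        angle_trajectory=raised_cosine(amplitude_deg),
        duration=duration,
        mount_rotations=mounts or {},
        standing_duration=standing,
        acc_noise_sd=acc_noise,
        gyr_noise_sd=gyr_noise,
        seed=seed,
        **kwargs,
    )


def random_mounts(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        seg: Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
        for seg in ("thigh", "shank")
    }


@pytest.fixture(scope="session")
def two_class_recording() -> hk.SignalRecording:
    """Two activity classes over one sEMG channel and one tri-axial ACC."""
    spec = hk.SyntheticSignalSpec(
        n_classes=2,
        channels=[
            ChannelSpec("emg1", "emg", 2000.0, "emg1"),
            ChannelSpec("acc1_x", "acc", 200.0, "acc1", "x", "thigh"),
            ChannelSpec("acc1_y", "acc", 200.0, "acc1", "y", "thigh"),
            ChannelSpec("acc1_z", "acc", 200.0, "acc1", "z", "thigh"),
        ],
        class_params=[
            {
                "emg1": ClassSignalParams(1.0, 50.0, 0.1),
                "acc1_x": ClassSignalParams(1.0, 2.0, 0.05),
                "acc1_y": ClassSignalParams(0.5, 3.0, 0.05),
                "acc1_z": ClassSignalParams(0.2, 1.0, 0.05),
            },
            {
                "emg1": ClassSignalParams(3.0, 80.0, 0.1),
                "acc1_x": ClassSignalParams(3.0, 4.0, 0.05),
                "acc1_y": ClassSignalParams(1.5, 2.0, 0.05),
                "acc1_z": ClassSignalParams(0.6, 5.0, 0.05),
            },
        ],
        epoch_duration=5.2,
        epochs_per_class=4,
        standing_duration=2.0,
        seed=5,
    )
    return hk.generate_signals(spec)


@pytest.fixture(scope="session")
def two_class_features(two_class_recording) -> hk.FeatureTable:
    ws = hk.segment(two_class_recording, 1040, 0.8)
    return hk.extract_features(ws)


@pytest.fixture(scope="session")
def imbalanced_table() -> hk.FeatureTable:
    spec = hk.SyntheticFeatureSpec(
        n_features=10, n_informative=2, n_classes=2,
        samples_per_class=(600, 100), seed=3,
    )
    table, _ = hk.generate_feature_table(spec)
    return table
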