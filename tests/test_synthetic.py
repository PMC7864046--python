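"""Synthetic generators: determinism, closed forms, separability."""

import numpy as np
import pytest

import harkit as hk
from harkit.synthetic import (
    ChannelSpec,
    ClassSignalParams,
    InvalidSpecError,
    boundary_means,
)
from conftest import hinge_spec, random_mounts, raised_cosine


def _mono_spec(noise=0.0, seed=0, standing=0.0, amp1=3.0):
    return hk.SyntheticSignalSpec(
        n_classes=2,
        channels=[ChannelSpec("ch", "emg", 200.0, "ch")],
        class_params=[
            {"ch": ClassSignalParams(1.0, 5.0, noise)},
            {"ch": ClassSignalParams(amp1, 5.0, noise)},
        ],
        epoch_duration=2.0,
        epochs_per_class=2,
        standing_duration=standing,
        seed=seed,
    )


def test_noise_free_channel_is_exact_sinusoid():
    """With unit amplitude in every class and no noise, the channel is
    exactly sin(2 pi f t) on the global time axis."""
    rec = hk.generate_signals(_mono_spec(amp1=1.0))
    ch = rec.channels["ch"]
    t = ch.times()
    np.testing.assert_allclose(ch.data, np.sin(2 * np.pi * 5.0 * t), atol=1e-12)


def test_signal_generator_deterministic():
    r1 = hk.generate_signals(_mono_spec(noise=0.3, seed=9))
    r2 = hk.generate_signals(_mono_spec(noise=0.3, seed=9))
    np.testing.assert_array_equal(r1.channels["ch"].data, r2.channels["ch"].data)


def test_labels_tile_epochs_round_robin():
    rec = hk.generate_signals(_mono_spec())
    assert [iv.label for iv in rec.labels] == ["class0", "class1"] * 2
    spans = [(iv.start, iv.end) for iv in rec.labels]
    assert spans == [(0, 2), (2, 4), (4, 6), (6, 8)]


def test_invalid_signal_spec_rejected():
    with pytest.raises(InvalidSpecError):
        hk.SyntheticSignalSpec(
            n_classes=1,
            channels=[ChannelSpec("ch", "emg", -5.0)],
            class_params=[{"ch": ClassSignalParams(1, 1)}],
        )
    with pytest.raises(InvalidSpecError, match="epoch_duration"):
        _s = _mono_spec()
        hk.SyntheticSignalSpec(
            n_classes=2, channels=_s.channels, class_params=_s.class_params,
            epoch_duration=0.0,
        )


def test_amplitude_contrast_separates_classes_by_rms(two_class_features):
    rep = hk.fisher_index(two_class_features)
    assert rep.fi_of("emg1:RMS") > 1.0


# ---------------------------------------------------------------------------
# rigid body


def test_constant_zero_trajectory_statics():
    spec = hk.RigidBodySpec(
        angle_trajectory=lambda t: np.zeros_like(t),
        duration=3.0, standing_duration=2.0,
    )
    rec, truth, _ = hk.generate_rigid_body(spec)
    for seg in ("thigh", "shank"):
        gyr = np.stack([rec.channels[f"gyr_{seg}_{a}"].data for a in "xyz"])
        np.testing.assert_array_equal(gyr, 0.0)
        acc = np.stack([rec.channels[f"acc_{seg}_{a}"].data for a in "xyz"])
        np.testing.assert_allclose(np.linalg.norm(acc, axis=0), 9.81, atol=1e-12)
    np.testing.assert_allclose(truth, 0.0, atol=1e-12)


def test_identity_mounts_truth_reaches_amplitude():
    rec, truth, mounts = hk.generate_rigid_body(hinge_spec(amplitude_deg=45.0))
    assert abs(truth.max() - 45.0) < 1e-6
    np.testing.assert_array_equal(mounts["thigh"], np.eye(3))


def test_non_unit_joint_axis_rejected():
    with pytest.raises(InvalidSpecError, match="unit"):
        hk.RigidBodySpec(
            angle_trajectory=lambda t: np.zeros_like(t),
            duration=1.0, joint_axis=np.array([0.0, 2.0, 0.0]),
        )


def test_non_orthonormal_mount_rejected():
    with pytest.raises(InvalidSpecError, match="orthonormal"):
        hk.RigidBodySpec(
            angle_trajectory=lambda t: np.zeros_like(t),
            duration=1.0, mount_rotations={"thigh": np.eye(3) * 2.0},
        )


def test_trajectory_must_start_at_zero():
    with pytest.raises(InvalidSpecError, match="start at 0"):
        hk.RigidBodySpec(angle_trajectory=lambda t: t + 30.0, duration=1.0)


def test_rigid_body_deterministic_with_noise():
    spec1 = hinge_spec(acc_noise=0.3, gyr_noise=0.01, seed=12)
    spec2 = hinge_spec(acc_noise=0.3, gyr_noise=0.01, seed=12)
    r1, t1, _ = hk.generate_rigid_body(spec1)
    r2, t2, _ = hk.generate_rigid_body(spec2)
    np.testing.assert_array_equal(t1, t2)
    for name in r1.channels:
        np.testing.assert_array_equal(r1.channels[name].data, r2.channels[name].data)


def test_end_to_end_pipeline_recovers_60_degrees():
    mounts = random_mounts(21)
    spec = hinge_spec(amplitude_deg=60.0, mounts=mounts, seed=21)
    rec, truth, true_mounts = hk.generate_rigid_body(spec)
    calib = hk.calibrate_axes(
        rec, medial_reference={s: true_mounts[s][:, 1] for s in true_mounts}
    )
    angles = hk.joint_angles(rec, calib, hk.estimate_attitudes(rec))
    peak = angles["knee_flexion"].angle_deg.max()
    assert abs(peak - 60.0) < 1.0


# ---------------------------------------------------------------------------
# feature tables


def test_no_informative_features_fi_near_zero():
    spec = hk.SyntheticFeatureSpec(
        n_features=20, n_informative=0, n_classes=2,
        samples_per_class=(200, 200), seed=0,
    )
    table, truth = hk.generate_feature_table(spec)
    assert truth["informative"] == []
    rep = hk.fisher_index(table)
    assert rep.fi.max() < 0.1


def test_informative_fi_exceeds_noise_fi():
    """Monte-Carlo: informative columns must out-rank pure noise."""
    wins = 0
    trials = 50
    for seed in range(trials):
        spec = hk.SyntheticFeatureSpec(
            n_features=30, n_informative=3, n_classes=3, gap=3.0,
            samples_per_class=(50, 50, 50), seed=seed,
        )
        table, truth = hk.generate_feature_table(spec)
        rep = hk.fisher_index(table)
        inf_fi = min(rep.fi_of(n) for n in truth["informative"])
        noise_fi = max(
            rep.fi_of(n) for n in table.feature_names
            if n not in truth["informative"]
        )
        wins += inf_fi > noise_fi
    assert wins >= trials - 1


def test_redundant_features_track_informative():
    spec = hk.SyntheticFeatureSpec(
        n_features=10, n_informative=2, n_redundant=2, n_classes=2,
        samples_per_class=(100, 100), seed=1,
    )
    table, truth = hk.generate_feature_table(spec)
    X = table.X
    for r, src in zip(truth["redundant"], truth["informative"]):
        assert np.corrcoef(X[r], X[src])[0, 1] > 0.95


def test_imbalanced_spec_ratio_six(imbalanced_table):
    _, counts = np.unique(imbalanced_table.labels, return_counts=True)
    assert counts.max() / counts.min() == 6.0


def test_boundary_means_pattern():
    m = boundary_means(4, 5, 3.0)
    assert m.shape == (4, 5)
    np.testing.assert_array_equal(m[:, 0], [0, 3, 3, 3])  # boundary 0
    np.testing.assert_array_equal(m[:, 2], [0, 0, 0, 3])  # boundary 2
    np.testing.assert_array_equal(m[:, 3], m[:, 0])  # cycles


def test_feature_table_deterministic():
    spec = dict(n_features=15, n_informative=3, n_classes=2,
                samples_per_class=(20, 30), seed=5)
    t1, _ = hk.generate_feature_table(hk.SyntheticFeatureSpec(**spec))
    t2, _ = hk.generate_feature_table(hk.SyntheticFeatureSpec(**spec))
    np.testing.assert_array_equal(t1.X.to_numpy(), t2.X.to_numpy())
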