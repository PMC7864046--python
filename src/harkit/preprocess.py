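"""Filtering, standing-phase normalization and window segmentation.

The preprocessing chain mirrors common practice for lower-limb wearable
recordings:

* sEMG: 4th-order Butterworth band-pass (10–500 Hz) followed by a 50 ms
  centered moving average.
* Accelerometer: 8th-order Butterworth low-pass at 10 Hz, then every
  sample divided by the mean resultant (vector-norm) acceleration over
  the standing phase — so a resting sensor reads 1 g.
* Gyroscope: 8th-order Butterworth low-pass at 30 Hz, then the per-axis
  mean over the standing phase subtracted (static bias removal; this is
  also the default stand-in for an ellipsoid static-error correction,
  for which a user hook is provided).

All filters are applied zero-phase (forward–backward), which halves the
effective roll-off but introduces no phase shift — appropriate for
offline windowed analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal

from .recording import Channel, SignalRecording, WindowSet

__all__ = ["PreprocessConfig", "preprocess", "segment"]


@dataclass
class PreprocessConfig:
    emg_band: tuple[float, float] = (10.0, 500.0)
    emg_order: int = 4
    emg_smooth_ms: float = 50.0
    acc_lowpass: float = 10.0
    gyr_lowpass: float = 30.0
    imu_order: int = 8
    normalize_standing: bool = True
    #: optional user-supplied static-error correction applied to raw IMU
    #: samples before filtering, mapping (channel_name, data) -> data
    static_correction: Callable[[str, np.ndarray], np.ndarray] | None = None


def _bandpass(x: np.ndarray, lo: float, hi: float, rate: float, order: int) -> np.ndarray:
    nyq = rate / 2.0
    if hi >= nyq:
        if lo >= nyq:
            raise ValueError(
                f"band edges ({lo}, {hi}) Hz infeasible at rate {rate} Hz"
            )
        # upper edge at/above Nyquist: degrade to high-pass
        sos = signal.butter(order, lo / nyq, btype="highpass", output="sos")
    else:
        sos = signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def _lowpass(x: np.ndarray, cutoff: float, rate: float, order: int) -> np.ndarray:
    nyq = rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"low-pass cutoff {cutoff} Hz infeasible at rate {rate} Hz")
    sos = signal.butter(order, cutoff / nyq, btype="lowpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, span_ms: float, rate: float) -> np.ndarray:
    k = max(1, int(round(span_ms * rate / 1000.0)))
    if k % 2 == 0:
        k += 1  # centered window
    kernel = np.ones(k) / k
    pad = k // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def preprocess(rec: SignalRecording, config: PreprocessConfig | None = None) -> SignalRecording:
    """Filter and normalize a recording; returns a new recording."""
    cfg = config or PreprocessConfig()
    if cfg.normalize_standing and rec.standing_phase is None:
        raise ValueError("standing-phase normalization requires a standing phase")
    out: dict[str, Channel] = {}
    for name, ch in rec.channels.items():
        x = ch.data
        if cfg.static_correction is not None and ch.modality in ("acc", "gyr"):
            x = cfg.static_correction(name, x)
        if ch.modality == "emg":
            x = _bandpass(x, cfg.emg_band[0], cfg.emg_band[1], ch.rate, cfg.emg_order)
            x = _moving_average(x, cfg.emg_smooth_ms, ch.rate)
        elif ch.modality == "acc":
            x = _lowpass(x, cfg.acc_lowpass, ch.rate, cfg.imu_order)
        elif ch.modality == "gyr":
            x = _lowpass(x, cfg.gyr_lowpass, ch.rate, cfg.imu_order)
        out[name] = replace(ch, data=x)

    if cfg.normalize_standing:
        s0, s1 = rec.standing_phase
        # accelerometer: divide by mean resultant norm per sensor unit
        for sensor, chans in rec.sensors().items():
            acc = [out[c.name] for c in chans if c.modality == "acc"]
            if acc:
                i0 = int(round(s0 * acc[0].rate))
                i1 = int(round(s1 * acc[0].rate))
                stack = np.stack([c.data[i0:i1] for c in acc])
                resultant = float(np.mean(np.linalg.norm(stack, axis=0)))
                if resultant <= 0:
                    raise ValueError(f"sensor {sensor!r}: zero standing acceleration")
                for c in acc:
                    c.data = c.data / resultant
        # gyroscope: subtract per-axis standing mean
        for name, ch in out.items():
            if ch.modality == "gyr":
                i0 = int(round(s0 * ch.rate))
                i1 = int(round(s1 * ch.rate))
                ch.data = ch.data - float(np.mean(ch.data[i0:i1]))

    return SignalRecording(
        channels=out,
        labels=list(rec.labels),
        standing_phase=rec.standing_phase,
        lying_phase=rec.lying_phase,
        motion_phase=rec.motion_phase,
    )


def segment(
    rec: SignalRecording,
    window_ms: float,
    overlap: float,
    exclude_standing: bool = True,
) -> WindowSet:
    """Slice a recording into fixed-width overlapping windows.

    Windows advance by ``window_ms * (1 - overlap)``.  Each window is
    labelled by the activity covering the majority of its span (ties
    broken toward the earlier label); windows with no label coverage,
    and windows overlapping the standing calibration phase, are dropped.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    duration = rec.duration
    if window_ms / 1000.0 > duration + 1e-9:
        raise ValueError("window longer than recording")
    step_ms = window_ms * (1.0 - overlap)
    w = window_ms / 1000.0
    step = step_ms / 1000.0
    n_wins = int(np.floor((duration - w) / step + 1e-9)) + 1

    starts: list[float] = []
    labels: list[str] = []
    ivs = sorted(rec.labels, key=lambda iv: iv.start)
    for k in range(n_wins):
        t0 = k * step
        t1 = t0 + w
        if exclude_standing and rec.standing_phase is not None:
            s0, s1 = rec.standing_phase
            if t0 < s1 - 1e-9 and t1 > s0 + 1e-9:
                continue
        best_label, best_cov = None, 0.0
        for iv in ivs:
            cov = max(0.0, min(t1, iv.end) - max(t0, iv.start))
            if cov > best_cov + 1e-12:  # strict: ties keep the earlier label
                best_label, best_cov = iv.label, cov
        if best_label is None:
            continue
        starts.append(t0)
        labels.append(best_label)

    arrays: dict[str, np.ndarray] = {}
    meta: dict[str, Channel] = {}
    kept_mask = np.ones(len(starts), dtype=bool)
    for name, ch in rec.channels.items():
        n_samp = int(round(window_ms * ch.rate / 1000.0))
        rows = []
        for i, t0 in enumerate(starts):
            i0 = int(round(t0 * ch.rate))
            if i0 + n_samp > len(ch.data):
                kept_mask[i] = False
                rows.append(None)
                continue
            rows.append(ch.data[i0 : i0 + n_samp])
        arrays[name] = rows  # finalized below once the mask is known
        meta[name] = replace(ch, data=np.empty(0))
    for name in arrays:
        arrays[name] = np.array(
            [r for r, keep in zip(arrays[name], kept_mask) if keep]
        ).reshape(int(kept_mask.sum()), -1)
    starts_arr = np.array([s for s, keep in zip(starts, kept_mask) if keep])
    labels = [l for l, keep in zip(labels, kept_mask) if keep]

    return WindowSet(
        arrays=arrays,
        channel_meta=meta,
        labels=labels,
        starts=starts_arr,
        window_ms=window_ms,
        overlap=overlap,
    )
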