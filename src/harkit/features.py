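"""Time-, frequency- and time-frequency-domain window features.

Per channel the bank computes the classic EMG/IMU descriptor set: mean
value, standard deviation, variance, RMS, skewness, kurtosis,
interquartile range, peak-to-peak, mean absolute value, waveform
length, log detector, 4th-order autoregressive coefficients (Burg),
energy, modified mean absolute value, zero crossings, slope sign
changes and Wilson amplitude (the latter three only for sEMG and
gyroscope channels); spectral descriptors mean power frequency, median
frequency, first/third-quartile frequencies, spectral entropy and the
three largest DFT magnitudes; and the wavelet-band energies of a
4-level sym4 decomposition (final approximation plus all four details).
Tri-axial sensors additionally contribute inter-axis correlation
coefficients, jerk (accelerometers only) and signal magnitude area.

The noise thresholds gating zero crossings, slope sign changes and
Wilson amplitude default to 1% of each window's RMS — a noise-floor-
relative choice common in the sEMG literature — and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .recording import Channel, WindowSet

__all__ = [
    "FeatureParams",
    "FeatureDef",
    "FeatureTable",
    "compute_td",
    "compute_fd",
    "compute_tfd",
    "compute_sensor_level",
    "enumerate_features",
    "extract_features",
    "normalize_minmax",
    "apply_minmax",
    "burg_ar",
    "study_inventory",
]

# per-channel scalar features shared by every modality
_COMMON_SINGLE = [
    "MV", "SD", "VAR", "RMS", "SKE", "KUR", "IQR", "P2P", "MAV", "WL",
    "LD", "Energy", "MMAV", "MPF", "MDF", "Entropy", "F25", "F75",
]
# threshold-gated features, present for sEMG and gyroscope channels
_GATED = ["ZC", "SSC", "WAMP"]


@dataclass
class FeatureParams:
    """Tunable knobs of the feature bank."""

    delta_z: float | None = None  # zero-crossing gate; None = 0.01 * window RMS
    delta_s: float | None = None  # slope-sign-change gate
    delta_w: float | None = None  # Wilson-amplitude gate
    threshold_rms_fraction: float = 0.01
    ar_order: int = 4
    wavelet: str = "sym4"
    wavelet_level: int = 4
    wavelet_mode: str = "symmetric"


@dataclass(frozen=True)
class FeatureDef:
    """One named feature with its provenance."""

    name: str  # full column name, e.g. "acc_LT_x:ARC1"
    feature: str  # base feature, e.g. "ARC"
    component: int  # 0 for scalars, 1-based otherwise
    modality: str
    sensor: str
    channel: str | None  # None for sensor-level features


@dataclass
class FeatureTable:
    """Windows-by-features matrix with labels and provenance."""

    X: pd.DataFrame
    labels: np.ndarray
    provenance: dict[str, FeatureDef] = field(default_factory=dict)
    norm_params: dict[str, tuple[float, float]] | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.X):
            raise ValueError("labels and feature matrix length mismatch")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(
            X=self.X[list(names)].copy(),
            labels=self.labels.copy(),
            provenance={n: self.provenance[n] for n in names if n in self.provenance},
            norm_params=self.norm_params,
        )

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# scalar helpers


def burg_ar(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by Burg's method, model x_k = sum a_i x_{k-i} + e_k."""
    x = np.asarray(x, dtype=float)
    if len(x) <= order + 1:
        raise ValueError(f"window too short for AR order {order}")
    a = np.array([1.0])
    f_err = x[1:].copy()
    b_err = x[:-1].copy()
    for _ in range(order):
        den = f_err @ f_err + b_err @ b_err
        k = -2.0 * (f_err @ b_err) / den if den > 1e-300 else 0.0
        a_ext = np.concatenate([a, [0.0]])
        a = a_ext + k * a_ext[::-1]
        f_new = f_err[1:] + k * b_err[1:]
        b_new = b_err[:-1] + k * f_err[:-1]
        f_err, b_err = f_new, b_new
    return -a[1:]  # flip sign: polynomial -> prediction coefficients


def _resolve_threshold(x: np.ndarray, explicit: float | None, frac: float) -> float:
    if explicit is not None:
        return explicit
    return frac * float(np.sqrt(np.mean(x**2)))


def compute_td(x: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """Time-domain features of a single window."""
    p = params or FeatureParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.ar_order + 4:
        raise ValueError("window too short for time-domain features")
    out: dict[str, float] = {}
    mean = float(np.mean(x))
    centered = x - mean
    out["MV"] = mean
    out["SD"] = float(np.std(x, ddof=1))
    out["VAR"] = float(np.var(x, ddof=1))
    out["RMS"] = float(np.sqrt(np.mean(x**2)))
    if np.allclose(centered, 0.0):
        out["SKE"] = 0.0  # undefined on a constant window
        out["KUR"] = 0.0
    else:
        out["SKE"] = float(stats.skew(x, bias=True))
        out["KUR"] = float(stats.kurtosis(x, fisher=False, bias=True))
    q1, q3 = np.percentile(x, [25, 75])
    out["IQR"] = float(q3 - q1)
    out["P2P"] = float(np.max(x) - np.min(x))
    out["MAV"] = float(np.mean(np.abs(x)))
    diffs = np.diff(x)
    out["WL"] = float(np.sum(np.abs(diffs)))
    out["LD"] = float(np.exp(np.mean(np.log(np.maximum(np.abs(x), 1e-12)))))
    out["Energy"] = float(np.mean(x**2))
    # central-half weighting (1-based index i with 0.25N <= i <= 0.75N)
    i = np.arange(1, n + 1)
    w = ((i >= 0.25 * n) & (i <= 0.75 * n)).astype(float)
    out["MMAV"] = float(np.sum(w * np.abs(x)) / n)

    dz = _resolve_threshold(x, p.delta_z, p.threshold_rms_fraction)
    ds = _resolve_threshold(x, p.delta_s, p.threshold_rms_fraction)
    dw = _resolve_threshold(x, p.delta_w, p.threshold_rms_fraction)
    out["ZC"] = float(np.sum((x[:-1] * x[1:] < 0) & (np.abs(x[:-1] - x[1:]) > dz)))
    mid, prev, nxt = x[1:-1], x[:-2], x[2:]
    out["SSC"] = float(
        np.sum(
            ((mid - prev) * (mid - nxt) > 0)
            & (np.abs(mid - nxt) > ds)
            & (np.abs(mid - prev) > ds)
        )
    )
    out["WAMP"] = float(np.sum(np.abs(diffs) > dw))

    try:
        arc = burg_ar(x, p.ar_order)
    except ValueError:
        arc = np.zeros(p.ar_order)
    for k in range(p.ar_order):
        out[f"ARC{k + 1}"] = float(arc[k])
    return out


def compute_fd(x: np.ndarray, rate: float) -> dict[str, float]:
    """Frequency-domain features from the one-sided FFT power spectrum.

    DC is excluded; quartile frequencies are the bins splitting the
    cumulative power 1:3 (F25), 1:1 (MDF) and 3:1 (F75).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 16:
        raise ValueError("window too short for spectral features")
    spec = np.fft.rfft(x)
    mags = np.abs(spec)[1:]
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)[1:]
    power = mags**2
    total = float(np.sum(power))
    out: dict[str, float] = {}
    if total <= 0:
        out.update({k: 0.0 for k in ("MPF", "MDF", "F25", "F75", "Entropy")})
    else:
        out["MPF"] = float(np.sum(power * freqs) / total)
        cum = np.cumsum(power)
        out["F25"] = float(freqs[int(np.argmax(cum >= 0.25 * total))])
        out["MDF"] = float(freqs[int(np.argmax(cum >= 0.5 * total))])
        out["F75"] = float(freqs[int(np.argmax(cum >= 0.75 * total))])
        phat = power / total
        nz = phat[phat > 0]
        out["Entropy"] = float(-np.sum(nz * np.log(nz)))
    top = np.sort(mags)[::-1][:3]
    if len(top) < 3:
        top = np.pad(top, (0, 3 - len(top)))
    for k in range(3):
        out[f"3LVD{k + 1}"] = float(top[k])
    return out


def compute_tfd(x: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """Wavelet-band energies: mean squared coefficient of A4, D4..D1."""
    p = params or FeatureParams()
    x = np.asarray(x, dtype=float)
    wavelet = pywt.Wavelet(p.wavelet)
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    if max_level < p.wavelet_level:
        min_len = (wavelet.dec_len - 1) * 2**p.wavelet_level
        raise ValueError(
            f"window of {len(x)} samples too short for a level-{p.wavelet_level} "
            f"decomposition; needs at least {min_len}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=p.wavelet_level, mode=p.wavelet_mode)
    # coeffs = [A4, D4, D3, D2, D1]
    return {
        f"EWC{k + 1}": float(np.mean(c**2)) for k, c in enumerate(coeffs)
    }


def compute_sensor_level(
    axes: dict[str, np.ndarray], modality: str
) -> dict[str, float]:
    """Per-sensor features over a tri-axial window: CC, Jerk, SMA."""
    ax = [np.asarray(axes[k], dtype=float) for k in ("x", "y", "z")]
    out: dict[str, float] = {}
    for (i, a), (j, b) in (((0, ax[0]), (1, ax[1])),
                           ((0, ax[0]), (2, ax[2])),
                           ((1, ax[1]), (2, ax[2]))):
        da, db = a - a.mean(), b - b.mean()
        den = np.sqrt(np.sum(da**2) * np.sum(db**2))
        name = f"CC_{'xyz'[i]}{'xyz'[j]}"
        out[name] = float(np.sum(da * db) / den) if den > 0 else 0.0
    if modality == "acc":
        out["Jerk"] = 0.5 * float(sum(np.sum(np.diff(a) ** 2) for a in ax))
    out["SMA"] = float(np.mean(np.abs(ax[0]) + np.abs(ax[1]) + np.abs(ax[2])))
    return out


# ---------------------------------------------------------------------------
# layout


def _channel_feature_list(modality: str) -> list[tuple[str, int]]:
    """(base feature, arity) pairs for one channel of the given modality."""
    feats: list[tuple[str, int]] = [(f, 1) for f in _COMMON_SINGLE]
    if modality in ("emg", "gyr"):
        feats += [(f, 1) for f in _GATED]
    feats += [("ARC", 4), ("3LVD", 3)]
    if modality != "angle":
        feats += [("EWC", 5)]
    return feats


def _sensor_feature_list(modality: str) -> list[tuple[str, int]]:
    if modality == "acc":
        return [("CC", 3), ("Jerk", 1), ("SMA", 1)]
    if modality == "gyr":
        return [("CC", 3), ("SMA", 1)]
    return []


_CC_NAMES = ["CC_xy", "CC_xz", "CC_yz"]


def enumerate_features(channels: list[Channel]) -> list[FeatureDef]:
    """Expand a sensor inventory into the full named feature list.

    ``channels`` carry name/modality/sensor metadata (their data arrays
    are ignored).  Per-sensor features are emitted once per tri-axial
    unit, after that unit's last channel.
    """
    defs: list[FeatureDef] = []
    seen_sensors: set[str] = set()
    by_sensor: dict[str, list[Channel]] = {}
    for ch in channels:
        by_sensor.setdefault(ch.sensor or ch.name, []).append(ch)
    for ch in channels:
        if ch.modality not in ("emg", "acc", "gyr", "angle"):
            raise ValueError(f"unknown modality {ch.modality!r} for {ch.name!r}")
        sensor = ch.sensor or ch.name
        for feat, arity in _channel_feature_list(ch.modality):
            if arity == 1:
                defs.append(
                    FeatureDef(f"{ch.name}:{feat}", feat, 0, ch.modality, sensor, ch.name)
                )
            else:
                for k in range(1, arity + 1):
                    defs.append(
                        FeatureDef(
                            f"{ch.name}:{feat}{k}", feat, k, ch.modality, sensor, ch.name
                        )
                    )
        group = by_sensor[sensor]
        if ch is group[-1] and sensor not in seen_sensors and len(group) == 3:
            seen_sensors.add(sensor)
            for feat, arity in _sensor_feature_list(ch.modality):
                if feat == "CC":
                    for cc in _CC_NAMES:
                        defs.append(
                            FeatureDef(f"{sensor}:{cc}", "CC", 0, ch.modality, sensor, None)
                        )
                else:
                    defs.append(
                        FeatureDef(f"{sensor}:{feat}", feat, 0, ch.modality, sensor, None)
                    )
    return defs


def study_inventory() -> list[Channel]:
    """The reference inventory: 4 sEMG channels, 3 tri-axial ACC units,
    3 tri-axial GYR units and 2 joint-angle channels."""
    empty = np.empty(0)
    chans: list[Channel] = []
    for muscle in ("LRF", "LSEM", "LTA", "LLGA"):
        chans.append(Channel(f"emg_{muscle}", empty, 2000.0, "emg", sensor=f"emg_{muscle}"))
    for modality in ("acc", "gyr"):
        for site, seg in (("LB", "lower_back"), ("LT", "thigh"), ("LS", "shank")):
            for axis in "xyz":
                chans.append(
                    Channel(
                        f"{modality}_{site}_{axis}", empty, 200.0, modality,
                        sensor=f"{modality}_{site}", axis=axis, segment=seg,
                    )
                )
    for joint in ("hip_flexion", "knee_flexion"):
        chans.append(Channel(f"angle_{joint}", empty, 200.0, "angle", sensor=f"angle_{joint}"))
    return chans


# ---------------------------------------------------------------------------
# extraction


def extract_features(
    windows: WindowSet, params: FeatureParams | None = None
) -> FeatureTable:
    """Compute the full feature bank over a window set."""
    p = params or FeatureParams()
    channels = list(windows.channel_meta.values())
    defs = enumerate_features(channels)
    n = windows.n_windows
    cols: dict[str, np.ndarray] = {d.name: np.empty(n) for d in defs}
    flags: dict[str, str] = {}

    by_sensor: dict[str, list[Channel]] = {}
    for ch in channels:
        by_sensor.setdefault(ch.sensor or ch.name, []).append(ch)

    for w in range(n):
        for ch in channels:
            x = windows.arrays[ch.name][w]
            vals = compute_td(x, p)
            vals.update(compute_fd(x, ch.rate))
            if ch.modality != "angle":
                vals.update(compute_tfd(x, p))
            for feat, arity in _channel_feature_list(ch.modality):
                if arity == 1:
                    cols[f"{ch.name}:{feat}"][w] = vals[feat]
                else:
                    for k in range(1, arity + 1):
                        cols[f"{ch.name}:{feat}{k}"][w] = vals[f"{feat}{k}"]
        for sensor, group in by_sensor.items():
            if len(group) != 3 or group[0].modality not in ("acc", "gyr"):
                continue
            axes = {ch.axis: windows.arrays[ch.name][w] for ch in group}
            svals = compute_sensor_level(axes, group[0].modality)
            for feat, arity in _sensor_feature_list(group[0].modality):
                if feat == "CC":
                    for cc in _CC_NAMES:
                        cols[f"{sensor}:{cc}"][w] = svals[cc]
                else:
                    cols[f"{sensor}:{feat}"][w] = svals[feat]

    X = pd.DataFrame(cols, columns=[d.name for d in defs])
    return FeatureTable(
        X=X,
        labels=np.asarray(windows.labels),
        provenance={d.name: d for d in defs},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# normalization


def normalize_minmax(
    table: FeatureTable, fit_on: np.ndarray | None = None
) -> FeatureTable:
    """Column-wise min–max scaling, fitted on ``fit_on`` rows (default all).

    Constant columns map to zero and are flagged.  The fitted (min, max)
    pairs are stored on the returned table so held-out data can be
    transformed with :func:`apply_minmax`; out-of-range values are not
    clipped.
    """
    idx = np.arange(len(table.X)) if fit_on is None else np.asarray(fit_on)
    fit = table.X.iloc[idx]
    params = {
        name: (float(fit[name].min()), float(fit[name].max()))
        for name in table.X.columns
    }
    out = apply_minmax(table, params)
    return out


def apply_minmax(
    table: FeatureTable, params: dict[str, tuple[float, float]]
) -> FeatureTable:
    X = table.X.copy()
    flags = dict(table.flags)
    for name, (lo, hi) in params.items():
        if hi - lo <= 0:
            X[name] = 0.0
            flags[name] = "constant"
        else:
            X[name] = (X[name] - lo) / (hi - lo)
    return FeatureTable(
        X=X,
        labels=table.labels.copy(),
        provenance=dict(table.provenance),
        norm_params=dict(params),
        flags=flags,
    )
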