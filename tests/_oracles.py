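"""Independent naive reference implementations used as oracles.

Everything here is written directly from the mathematical definitions
with explicit loops / O(n^2) transforms, deliberately avoiding the code
paths (and, where feasible, the libraries) used by the package itself.
"""

from __future__ import annotations

import math

import numpy as np


def naive_quantile(xs: list[float], q: float) -> float:
    """Linear-interpolation quantile on the sorted sample (type 7)."""
    s = sorted(xs)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def naive_td(x, dz, ds, dw):
    """Time-domain features by direct summation."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    rms = math.sqrt(sum(v * v for v in x) / n)
    sigma = math.sqrt(sum((v - mean) ** 2 for v in x) / n)  # population
    if sigma == 0:
        ske = kur = 0.0
    else:
        ske = sum((v - mean) ** 3 for v in x) / (n * sigma**3)
        kur = sum((v - mean) ** 4 for v in x) / (n * sigma**4)
    iqr = naive_quantile(x, 0.75) - naive_quantile(x, 0.25)
    p2p = max(x) - min(x)
    mav = sum(abs(v) for v in x) / n
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    ld = math.exp(sum(math.log(max(abs(v), 1e-12)) for v in x) / n)
    energy = sum(v * v for v in x) / n
    mmav = sum(
        abs(x[i - 1]) for i in range(1, n + 1) if 0.25 * n <= i <= 0.75 * n
    ) / n
    zc = sum(
        1
        for i in range(n - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) > dz
    )
    ssc = sum(
        1
        for i in range(1, n - 1)
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
        and abs(x[i] - x[i + 1]) > ds
        and abs(x[i] - x[i - 1]) > ds
    )
    wamp = sum(1 for i in range(n - 1) if abs(x[i + 1] - x[i]) > dw)
    return {
        "MV": mean, "SD": sd, "VAR": var, "RMS": rms, "SKE": ske, "KUR": kur,
        "IQR": iqr, "P2P": p2p, "MAV": mav, "WL": wl, "LD": ld,
        "Energy": energy, "MMAV": mmav, "ZC": float(zc), "SSC": float(ssc),
        "WAMP": float(wamp),
    }


def naive_dft_mags(x):
    """One-sided DFT magnitudes (DC excluded) by the O(n^2) definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ks = np.arange(1, n // 2 + 1)
    mags = []
    for k in ks:
        re = sum(x[t] * math.cos(-2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(-2 * math.pi * k * t / n) for t in range(n))
        mags.append(math.hypot(re, im))
    return np.array(mags), ks


def naive_fd(x, rate):
    mags, ks = naive_dft_mags(x)
    freqs = ks * rate / len(x)
    power = mags**2
    total = power.sum()
    out = {}
    if total <= 0:
        out.update({k: 0.0 for k in ("MPF", "MDF", "F25", "F75", "Entropy")})
    else:
        out["MPF"] = float((power * freqs).sum() / total)
        for name, frac in (("F25", 0.25), ("MDF", 0.5), ("F75", 0.75)):
            acc = 0.0
            for p, f in zip(power, freqs):
                acc += p
                if acc >= frac * total:
                    out[name] = float(f)
                    break
        phat = power / total
        out["Entropy"] = float(-sum(p * math.log(p) for p in phat if p > 0))
    top = sorted(mags, reverse=True)[:3]
    top += [0.0] * (3 - len(top))
    for k in range(3):
        out[f"3LVD{k + 1}"] = float(top[k])
    return out


def naive_dwt_step(x, dec_lo, dec_hi):
    """One symmetric-extension DWT level by explicit convolution."""
    x = np.asarray(x, dtype=float)
    flen = len(dec_lo)
    ext = np.concatenate([x[: flen - 1][::-1], x, x[-1 : -flen : -1]])
    n_out = (len(x) + flen - 1) // 2
    cA = np.convolve(ext, dec_lo)[flen::2][:n_out]
    cD = np.convolve(ext, dec_hi)[flen::2][:n_out]
    return cA, cD


def naive_ewc(x, dec_lo, dec_hi, level=4):
    """Wavelet-band mean-square energies [A_L, D_L, ..., D_1]."""
    details = []
    approx = np.asarray(x, dtype=float)
    for _ in range(level):
        approx, cD = naive_dwt_step(approx, dec_lo, dec_hi)
        details.append(cD)
    bands = [approx] + details[::-1]
    return [float(np.mean(b**2)) for b in bands]


def naive_fisher_index(X, y):
    """Two-loop Fisher Index per feature."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    n, p = X.shape
    fi = []
    for j in range(p):
        col = X[:, j]
        m = sum(col) / n
        sb = 0.0
        sw = 0.0
        for c in classes:
            vals = [col[i] for i in range(n) if y[i] == c]
            pi = len(vals) / n
            mi = sum(vals) / len(vals)
            vi = sum((v - mi) ** 2 for v in vals) / len(vals)
            sb += pi * (mi - m) ** 2
            sw += pi * vi
        fi.append(sb / sw if sw > 0 else (0.0 if sb == 0 else float("inf")))
    return np.array(fi)


def naive_f_measure(cm):
    """Per-class precision/recall/F-measure from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    k = cm.shape[0]
    fms = []
    for i in range(k):
        col = sum(cm[j][i] for j in range(k))
        row = sum(cm[i][j] for j in range(k))
        p = cm[i][i] / col if col > 0 else 0.0
        r = cm[i][i] / row if row > 0 else 0.0
        fms.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    return np.array(fms)


def naive_adasyn_allocation(X, y, class_c, k_nn, g):
    """Brute-force ADASYN per-sample synthetic counts (largest remainder)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority = [i for i in range(len(y)) if y[i] == class_c]
    r = []
    for i in minority:
        d = np.sum((X - X[i]) ** 2, axis=1)
        order = np.argsort(d, kind="stable")
        neigh = [j for j in order if j != i][:k_nn]
        r.append(sum(1 for j in neigh if y[j] != class_c) / k_nn)
    r = np.array(r)
    density = r / r.sum() if r.sum() > 0 else np.full(len(r), 1 / len(r))
    raw = density * g
    counts = np.floor(raw).astype(int)
    rem = g - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts
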