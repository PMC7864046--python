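"""Imbalance-aware resampling: ADASYN oversampling + undersampling ensemble.

Activity recordings are strongly imbalanced (locomotion produces many
more windows than held postures; the largest-to-smallest class ratio in
typical protocols exceeds 5).  Every class is brought to a common
target size, the geometric mean of the largest and smallest class
counts:

* classes above the target are undersampled by random sampling with
  replacement — repeated k times with different draws, giving k groups
  that average out the sampling deviation;
* classes below the target are oversampled once with ADASYN (adaptive
  synthetic sampling), and the same synthetic rows are shared by all k
  groups.

ADASYN allocates synthetic counts to minority samples in proportion to
the fraction of out-of-class neighbours among their k nearest
neighbours, then interpolates each synthetic row between the sample and
one of its in-class neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import FeatureTable

__all__ = ["ResampledEnsemble", "adasyn_oversample", "build_ensemble"]


@dataclass
class ResampledEnsemble:
    groups: list[FeatureTable]
    target: int
    seed: int
    #: per class below target, the synthetic rows shared across groups
    synthetic_rows: dict[str, np.ndarray] = field(default_factory=dict)
    #: per group and class, the source-row indices drawn from the input
    group_indices: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.groups)


def adasyn_oversample(
    table: FeatureTable,
    class_c: str,
    target_n: int,
    k_nn: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic minority rows for ``class_c``, shape (target_n - n_c, p).

    Follows the adaptive-synthetic recipe: per minority sample, the
    fraction r_i of out-of-class neighbours among its k nearest
    neighbours (whole data set) is normalized into an allocation
    density; all-zero densities fall back to uniform allocation.  Each
    synthetic row is x + lambda (x_nn - x) with lambda ~ U[0, 1] and
    x_nn one of the sample's k nearest in-class neighbours.  A class too
    small for the neighbourhood falls back to random duplication with a
    warning.
    """
    rng = np.random.default_rng(seed)
    X = table.X.to_numpy(dtype=float)
    y = np.asarray(table.labels)
    minority = np.nonzero(y == class_c)[0]
    n_c = len(minority)
    if n_c == 0:
        raise ValueError(f"class {class_c!r} not present")
    g = int(target_n) - n_c
    if g < 0:
        raise ValueError("target_n must be at least the current class size")
    if g == 0:
        return np.empty((0, X.shape[1]))
    Xmin = X[minority]
    if n_c < k_nn + 1:
        warnings.warn(
            f"class {class_c!r} too small ({n_c}) for {k_nn}-NN synthesis; "
            "falling back to random duplication",
            stacklevel=2,
        )
        picks = rng.integers(0, n_c, size=g)
        return Xmin[picks].copy()

    nn_all = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    _, idx_all = nn_all.kneighbors(Xmin)
    neigh = idx_all[:, 1:]  # drop self
    r = np.array([(y[row] != class_c).mean() for row in neigh])
    if r.sum() > 0:
        density = r / r.sum()
    else:
        density = np.full(n_c, 1.0 / n_c)
    # largest-remainder allocation of the g synthetic rows
    raw = density * g
    counts = np.floor(raw).astype(int)
    remainder = g - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(-(raw - counts), kind="stable")
        counts[frac_order[:remainder]] += 1

    nn_min = NearestNeighbors(n_neighbors=min(k_nn + 1, n_c)).fit(Xmin)
    _, idx_min = nn_min.kneighbors(Xmin)
    rows = []
    for i, gi in enumerate(counts):
        if gi == 0:
            continue
        neighbours = idx_min[i, 1:]
        picks = rng.integers(0, len(neighbours), size=gi)
        lam = rng.random(gi)[:, None]
        xi = Xmin[i]
        xn = Xmin[neighbours[picks]]
        rows.append(xi + lam * (xn - xi))
    return np.vstack(rows) if rows else np.empty((0, X.shape[1]))


def build_ensemble(
    table: FeatureTable, k: int = 10, k_nn: int = 5, seed: int = 0
) -> ResampledEnsemble:
    """k resampled groups, every class at the geometric-mean target size."""
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("resampling requires at least 2 classes")
    target = int(round(np.sqrt(counts.max() * counts.min())))
    rng = np.random.default_rng(seed)

    synthetic: dict[str, np.ndarray] = {}
    for c, n_c in zip(classes, counts):
        if n_c < target:
            synthetic[str(c)] = adasyn_oversample(
                table, c, target, k_nn=k_nn,
                seed=int(rng.integers(0, 2**31 - 1)),
            )

    groups: list[FeatureTable] = []
    group_indices: list[dict[str, np.ndarray]] = []
    cols = table.feature_names
    for _ in range(k):
        blocks: list[np.ndarray] = []
        labels: list[np.ndarray] = []
        indices: dict[str, np.ndarray] = {}
        for c, n_c in zip(classes, counts):
            members = np.nonzero(y == c)[0]
            if n_c > target:
                chosen = rng.choice(members, size=target, replace=True)
            else:
                chosen = members
            indices[str(c)] = chosen
            blocks.append(table.X.to_numpy(dtype=float)[chosen])
            labels.append(np.full(len(chosen), c))
            if str(c) in synthetic and len(synthetic[str(c)]):
                blocks.append(synthetic[str(c)])
                labels.append(np.full(len(synthetic[str(c)]), c))
        Xg = np.vstack(blocks)
        yg = np.concatenate(labels)
        groups.append(
            FeatureTable(
                X=pd.DataFrame(Xg, columns=cols),
                labels=yg,
                provenance=dict(table.provenance),
            )
        )
        group_indices.append(indices)
    return ResampledEnsemble(
        groups=groups,
        target=target,
        seed=seed,
        synthetic_rows=synthetic,
        group_indices=group_indices,
    )
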