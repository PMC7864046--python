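"""Baseline feature selectors: Relief-F + correlation filter, and SFS.

Both are the standard comparison points for a wrapper GA: a pure filter
(Relief-F relevance weights with redundancy pruning by pairwise
correlation) and a pure wrapper (greedy sequential forward selection
under the same LDA/naive-Bayes F-measure criterion the GA optimizes).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureTable
from .gfsfan import WrapperFitness
from .resampling import ResampledEnsemble

__all__ = ["relief_f_weights", "relief_filter", "sfs"]


def relief_f_weights(
    table: FeatureTable, k: int = 10, seed: int = 0, n_samples: int | None = None
) -> np.ndarray:
    """Multi-class Relief-F relevance weights.

    Features are range-normalized for the distance computations.  For
    each reference sample the k nearest same-class hits decrease the
    weight of features on which they differ; the k nearest misses from
    each other class increase it, weighted by that class's prior among
    the alternatives.  Weights are averaged over all reference samples
    (or a random subsample of ``n_samples``).
    """
    X = table.X.to_numpy(dtype=float)
    y = np.asarray(table.labels)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / span
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    refs = np.arange(n)
    if n_samples is not None and n_samples < n:
        refs = rng.choice(n, size=n_samples, replace=False)
    members = {c: np.nonzero(y == c)[0] for c in classes}
    W = np.zeros(p)
    for r in refs:
        xr = Xn[r]
        cls = y[r]
        for c in classes:
            idx = members[c]
            idx = idx[idx != r]
            if len(idx) == 0:
                continue
            d = np.linalg.norm(Xn[idx] - xr, axis=1)
            kk = min(k, len(idx))
            near = idx[np.argsort(d, kind="stable")[:kk]]
            diff = np.abs(Xn[near] - xr).mean(axis=0)
            if c == cls:
                W -= diff
            else:
                W += priors[c] / (1.0 - priors[cls]) * diff
    return W / len(refs)


def relief_filter(
    table: FeatureTable,
    relief_k: int = 10,
    corr_threshold: float = 0.9,
    seed: int = 0,
    n_samples: int | None = None,
) -> list[str]:
    """Relief-F relevance gate followed by correlation-redundancy pruning.

    Features with non-positive Relief-F weight are dropped; among
    features whose pairwise |Pearson r| exceeds ``corr_threshold`` only
    the highest-weight member survives.
    """
    W = relief_f_weights(table, k=relief_k, seed=seed, n_samples=n_samples)
    names = table.feature_names
    keep_order = np.argsort(-W, kind="stable")
    X = table.X.to_numpy(dtype=float)
    sd = X.std(axis=0)
    selected: list[int] = []
    for j in keep_order:
        if W[j] <= 0:
            continue
        redundant = False
        for s in selected:
            if sd[j] == 0 or sd[s] == 0:
                r = 1.0 if np.allclose(X[:, j], X[:, s]) else 0.0
            else:
                r = np.corrcoef(X[:, j], X[:, s])[0, 1]
            if abs(r) > corr_threshold:
                redundant = True
                break
        if not redundant:
            selected.append(int(j))
    selected.sort()
    return [names[j] for j in selected]


def sfs(
    table: FeatureTable,
    ensemble: ResampledEnsemble | None = None,
    n_folds: int = 10,
    tol: float = 1e-4,
    max_features: int | None = None,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Sequential forward selection under the wrapper F-measure.

    Greedily adds the feature maximizing the mean per-class F-measure
    of the LDA/naive-Bayes wrappers (cross-validated, averaged over
    resampled groups); stops when the best addition improves FM_all by
    no more than ``tol``.  Returns the selected names and the FM_all
    trajectory.
    """
    groups = ensemble.groups if ensemble is not None else [table]
    evaluate = WrapperFitness(groups, n_folds=n_folds, seed=seed)
    m = table.n_features
    limit = max_features or m
    chosen: list[int] = []
    trajectory: list[float] = []
    best_fm = -np.inf
    mask = np.zeros(m, dtype=bool)
    while len(chosen) < limit:
        best_j, best_candidate = None, best_fm
        for j in range(m):
            if mask[j]:
                continue
            mask[j] = True
            _, fm_all, _ = evaluate(mask)
            mask[j] = False
            if fm_all > best_candidate:
                best_candidate, best_j = fm_all, j
        if best_j is None or best_candidate - best_fm <= tol and chosen:
            break
        mask[best_j] = True
        chosen.append(best_j)
        best_fm = best_candidate
        trajectory.append(best_fm)
    return [table.feature_names[j] for j in chosen], trajectory
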