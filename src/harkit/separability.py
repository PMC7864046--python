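"""Fisher-Index class-separability scoring.

For a scalar feature x with classes i = 1..k, priors p_i (class
frequencies), class means m_i, grand mean m and within-class population
variances v_i:

    S_b = sum_i p_i (m_i - m)^2          (between-class scatter)
    S_w = sum_i p_i v_i                  (within-class scatter)
    FI  = S_b / S_w

Higher is more separable.  Traces are additive over features, so the
summed Fisher Index (SFI) of a feature set is simply the sum of the
per-feature indices; SFI is the criterion used to compare windowing
parameter choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureTable

__all__ = ["SeparabilityReport", "fisher_index", "sfi"]


@dataclass
class SeparabilityReport:
    feature_names: list[str]
    fi: np.ndarray  # aligned with feature_names; +inf where S_w == 0
    ranking: np.ndarray  # feature indices, descending FI, ties by index
    flags: dict[str, str] = field(default_factory=dict)

    def fi_of(self, name: str) -> float:
        return float(self.fi[self.feature_names.index(name)])

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.ranking]


def fisher_index(table: FeatureTable) -> SeparabilityReport:
    """Per-feature Fisher Index with a descending, tie-stable ranking.

    A feature that is constant within every class but differs between
    classes has zero within-class scatter; its index is reported as
    +inf, ranked first, and flagged.
    """
    X = table.X.to_numpy(dtype=float)
    y = table.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("Fisher Index requires at least 2 classes")
    n = len(y)
    priors = np.array([np.sum(y == c) / n for c in classes])
    if np.any(np.array([np.sum(y == c) for c in classes]) < 2):
        raise ValueError("every class needs at least 2 samples")
    grand = X.mean(axis=0)
    sb = np.zeros(X.shape[1])
    sw = np.zeros(X.shape[1])
    for c, p in zip(classes, priors):
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        sb += p * (mi - grand) ** 2
        sw += p * Xi.var(axis=0)  # population variance within class
    flags: dict[str, str] = {}
    fi = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        fi = np.where(sw > 0, sb / np.where(sw > 0, sw, 1.0), np.inf)
    fi = np.where((sw == 0) & (sb == 0), 0.0, fi)
    names = table.feature_names
    for j in np.nonzero(np.isinf(fi))[0]:
        flags[names[j]] = "zero-within-class-scatter"
    order = np.lexsort((np.arange(len(fi)), -fi))  # descending, ties by index
    return SeparabilityReport(
        feature_names=list(names), fi=fi, ranking=order, flags=flags
    )


def sfi(report: SeparabilityReport, feature_set: Iterable[str]) -> float:
    """Summed Fisher Index of a feature set."""
    names = set(report.feature_names)
    total = 0.0
    for f in feature_set:
        if f not in names:
            raise KeyError(f"unknown feature {f!r}")
        total += report.fi_of(f)
    return total
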