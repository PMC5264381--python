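"""Collinearity analysis: prune the 36-variable table to the network inputs.

Highly correlated descriptors carry no independent information and inflate
the search space of the downstream classifier, so the pipeline drops, from
every pair whose Pearson |r| exceeds a threshold, the member that is on
average more redundant with everything else.  An optional target dimension
continues the same ranking until a fixed input size is reached; the
reference configuration uses threshold 0.9 and target 24.

The reduction is fitted on training rows only and then applied by feature
name, so validation/test rows never influence which variables survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, SchemaError
from .features import FEATURE_NAMES, FeatureVector

DEFAULT_THRESHOLD = 0.9
DEFAULT_TARGET_DIM = 24


@dataclass
class ReductionReport:
    retained: list[str]
    dropped: list[tuple[str, str, str, float]]  # (name, reason, partner, |r|)
    threshold: float
    target_dim: int | None

    def to_dict(self) -> dict:
        return {"retained": list(self.retained),
                "dropped": [list(d) for d in self.dropped],
                "threshold": self.threshold, "target_dim": self.target_dim}


def correlation_matrix(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix; constant columns correlate 0 with
    everything (diagonal stays 1)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InsufficientDataError("need at least 3 rows")
    sd = X.std(axis=0)
    corr = np.zeros((X.shape[1], X.shape[1]))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    return corr


def collinearity_prune(corr: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                       target_dim: int | None = DEFAULT_TARGET_DIM,
                       names: list[str] | None = None) -> ReductionReport:
    """Greedy correlation pruning with a deterministic tie-break.

    Phase 1: while any retained pair has |r| > threshold, take the pair
    with the largest |r| (ties: lowest registry indices) and drop its
    member with the larger mean |r| to all other retained features (ties:
    the later registry entry).  Phase 2 (only when ``target_dim`` is set):
    keep dropping the feature with the largest mean |r| by the same rule
    until exactly ``target_dim`` remain.

    ``target_dim`` is a floor as well as a target: phase 1 stops early if
    it would drop below it, so a set target is always met exactly.  The
    guarantee that no retained pair exceeds the threshold holds only in the
    purely data-driven mode (``target_dim=None``).
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if names is None:
        names = list(FEATURE_NAMES[:p]) if p <= len(FEATURE_NAMES) \
            else [f"f{i}" for i in range(p)]
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError("threshold must lie in (0, 1]")
    if target_dim is not None and not 1 <= target_dim <= p:
        raise ConfigurationError(f"target_dim must lie in [1, {p}]")

    retained = list(range(p))
    dropped: list[tuple[str, str, str, float]] = []
    a = np.abs(corr)

    def mean_abs(i: int) -> float:
        others = [k for k in retained if k != i]
        return float(np.mean(a[i, others])) if others else 0.0

    while target_dim is None or len(retained) > target_dim:
        worst, pair = -1.0, None
        for ii, i in enumerate(retained):
            for j in retained[ii + 1:]:
                if a[i, j] > threshold and a[i, j] > worst:
                    worst, pair = a[i, j], (i, j)
        if pair is None:
            break
        i, j = pair
        mi, mj = mean_abs(i), mean_abs(j)
        victim, partner = (i, j) if mi > mj else (j, i) if mj > mi \
            else (max(i, j), min(i, j))
        retained.remove(victim)
        dropped.append((names[victim], "collinear", names[partner], worst))

    if target_dim is not None:
        while len(retained) > target_dim:
            scores = [(mean_abs(i), i) for i in retained]
            best = max(scores, key=lambda t: (t[0], t[1]))
            victim = best[1]
            retained.remove(victim)
            dropped.append((names[victim], "target_dim", "", best[0]))

    return ReductionReport(retained=[names[i] for i in retained],
                           dropped=dropped, threshold=threshold,
                           target_dim=target_dim)


def fit_reduction(features: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                  target_dim: int | None = DEFAULT_TARGET_DIM) -> ReductionReport:
    """Correlation matrix + prune on a named feature table."""
    corr = correlation_matrix(features.to_numpy())
    return collinearity_prune(corr, threshold, target_dim,
                              names=list(features.columns))


def apply_reduction(vector: FeatureVector | pd.DataFrame,
                    report: ReductionReport):
    """Select the retained features, in retained order, by name."""
    if isinstance(vector, pd.DataFrame):
        missing = [n for n in report.retained if n not in vector.columns]
        if missing:
            raise SchemaError(f"missing features: {missing}")
        return vector[report.retained]
    lookup = dict(zip(vector.names, vector.values))
    missing = [n for n in report.retained if n not in lookup]
    if missing:
        raise SchemaError(f"missing features: {missing}")
    return np.array([lookup[n] for n in report.retained], dtype=float)
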