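"""Parameter-recovery metrics for simulated hybrid classes.

Accuracy is the relative closeness of the class mean to its expectation,
1 - |mean(observed) - expected| / expected; precision is the mean distance
of estimates from their own centroid (mean absolute deviation for scalars,
mean Euclidean distance for triangle-plot points); MAE is the mean absolute
deviation from the expectation and, unlike accuracy, is defined when the
expectation is 0 (parental classes).  The folded hybrid index and the
log-fold change support misassignment analyses: negative values mean a
shift toward the nearest parental extreme.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


def accuracy(observed, expected: float) -> float:
    """1 - |mean(observed) - expected| / expected.

    Unclamped: gross errors can go negative.  Undefined at ``expected = 0``;
    use :func:`mean_absolute_error` for parental classes.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ParameterError("accuracy needs at least one observation")
    if expected <= 0:
        raise ParameterError(
            "accuracy is relative to the expectation and undefined at 0; "
            "use mean_absolute_error"
        )
    return 1.0 - abs(obs.mean() - expected) / expected


def precision(observed) -> float:
    """Mean distance of observations from their centroid (smaller = tighter).

    Accepts scalars (mean absolute deviation) or an ``(n, d)`` array of
    points (mean Euclidean distance, the units of the triangle plot).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ParameterError("precision needs at least one observation")
    if obs.ndim == 1:
        return float(np.abs(obs - obs.mean()).mean())
    centroid = obs.mean(axis=0)
    return float(np.linalg.norm(obs - centroid, axis=1).mean())


def mean_absolute_error(observed, expected: float) -> float:
    """Mean of |observed_i - expected|; defined for any expectation."""
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ParameterError("MAE needs at least one observation")
    return float(np.abs(obs - expected).mean())


def fold_hybrid_index(h: float) -> float:
    """Distance of a hybrid index from its nearest parental extreme.

    Values above 0.5 are reflected (1 - h), so folded values lie in
    [0, 0.5] and are symmetric: fold(h) == fold(1 - h).
    """
    if not 0.0 <= h <= 1.0:
        raise ParameterError("hybrid index must lie in [0, 1]")
    return 1.0 - h if h > 0.5 else h


def log_fold_change(est_mis: float, est_ref: float, epsilon: float = 1e-6) -> float:
    """log((est_mis + eps) / (est_ref + eps)), natural log.

    ``est_mis`` is the estimate under parental misassignment, ``est_ref``
    the reference estimate; hybrid indices should be pre-folded with
    :func:`fold_hybrid_index`.  Negative values mean the misassigned
    estimate sits closer to the parental extreme than the reference.
    """
    if est_mis < 0 or est_ref < 0:
        raise ParameterError("estimates must be nonnegative")
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    return float(np.log((est_mis + epsilon) / (est_ref + epsilon)))
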