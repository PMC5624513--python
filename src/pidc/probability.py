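"""Estimation of discrete distributions and entropies from frequency tables.

Frequency tables are plain numpy integer arrays over 1-3 bin axes.  Four
estimators are supported:

* ``ml`` — maximum likelihood, the empirical frequencies;
* ``dirichlet`` — posterior mean under a symmetric Dirichlet prior
  (pseudocount 1 per cell unless stated otherwise);
* ``shrinkage`` — James-Stein shrinkage of the ML estimate toward the
  uniform target, with the closed-form optimal intensity;
* ``miller_madow`` — a direct entropy bias correction; it never produces a
  probability table and is therefore valid only for entropy-combination
  measures (MI, CMI), not for the partial information decomposition.

All entropies are in bits (log base 2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ESTIMATORS",
    "joint_counts",
    "ml_probabilities",
    "dirichlet_probabilities",
    "shrinkage_probabilities",
    "estimate_probabilities",
    "entropy",
    "entropy_from_counts",
    "miller_madow_entropy",
]

ESTIMATORS = ("ml", "miller_madow", "dirichlet", "shrinkage")

_LN2 = np.log(2.0)


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim < 1 or counts.ndim > 3:
        raise ValueError("frequency tables have rank 1-3")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() < 1:
        raise ValueError("frequency table must contain at least one observation")
    return counts.astype(float)


def joint_counts(*labels, n_bins=None) -> np.ndarray:
    """Joint frequency table from 1-3 aligned integer label vectors.

    ``n_bins`` optionally gives the bin count per axis; otherwise
    ``max(label) + 1`` is used.  Accepts :class:`DiscretizedVariable`
    instances or plain arrays.
    """
    arrays, shapes = [], []
    for i, lab in enumerate(labels):
        arr = np.asarray(getattr(lab, "labels", lab), dtype=np.int64)
        b = getattr(lab, "n_bins", None)
        if n_bins is not None:
            b = n_bins[i] if np.iterable(n_bins) else n_bins
        if b is None:
            b = int(arr.max()) + 1 if arr.size else 1
        arrays.append(arr)
        shapes.append(int(b))
    if not 1 <= len(arrays) <= 3:
        raise ValueError("joint tables support 1-3 variables")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("label vectors must have equal length")
    flat = np.ravel_multi_index(arrays, shapes)
    return np.bincount(flat, minlength=int(np.prod(shapes))).reshape(shapes)


def ml_probabilities(counts: np.ndarray) -> np.ndarray:
    """Empirical frequencies ``counts / n``."""
    counts = _check_counts(counts)
    return counts / counts.sum()


def dirichlet_probabilities(counts: np.ndarray, prior_weight: float = 1.0) -> np.ndarray:
    """Posterior mean ``(counts_k + a) / (n + a K)`` under Dirichlet(a,...,a)."""
    if prior_weight <= 0:
        raise ValueError("prior_weight must be positive")
    counts = _check_counts(counts)
    n = counts.sum()
    k = counts.size
    return (counts + prior_weight) / (n + prior_weight * k)


def shrinkage_lambda(counts: np.ndarray) -> float:
    """Closed-form optimal James-Stein intensity toward the uniform target,

    ``lambda* = (1 - sum theta^2) / ((n - 1) sum (1/K - theta)^2)``,
    clipped to [0, 1]; defined as 1 for n = 1 or when the ML estimate already
    equals the target.
    """
    counts = _check_counts(counts)
    n = counts.sum()
    if n <= 1:
        return 1.0
    theta = counts.ravel() / n
    k = counts.size
    denom = (n - 1) * np.sum((1.0 / k - theta) ** 2)
    if denom == 0.0:
        return 1.0
    lam = (1.0 - np.sum(theta ** 2)) / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrinkage_probabilities(counts: np.ndarray) -> np.ndarray:
    """Convex blend ``lambda/K + (1 - lambda) * theta`` of uniform and ML."""
    counts = _check_counts(counts)
    lam = shrinkage_lambda(counts)
    theta = counts / counts.sum()
    return lam / counts.size + (1.0 - lam) * theta


def estimate_probabilities(counts: np.ndarray, estimator: str = "ml",
                           prior_weight: float = 1.0) -> np.ndarray:
    """Dispatch to the named probability estimator.

    Raises for ``miller_madow``, which corrects entropies directly and has no
    associated probability distribution.
    """
    if estimator == "ml":
        return ml_probabilities(counts)
    if estimator == "dirichlet":
        return dirichlet_probabilities(counts, prior_weight=prior_weight)
    if estimator == "shrinkage":
        return shrinkage_probabilities(counts)
    if estimator == "miller_madow":
        raise ValueError(
            "the Miller-Madow estimator corrects entropies directly and does not "
            "estimate a probability distribution; it cannot be used where a "
            "probability table is required (e.g. partial information decomposition)"
        )
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits, ``-sum p log2 p`` over nonzero entries."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < -1e-12):
        raise ValueError("probabilities must be non-negative")
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1 (got {total})")
    p = probs[probs > 0]
    return float(-np.sum(p * np.log2(p)))


def miller_madow_entropy(counts: np.ndarray) -> float:
    """ML entropy plus the bias correction ``(B - 1) / (2 n)`` nats (B =
    occupied bins), reported in bits."""
    counts = _check_counts(counts)
    n = counts.sum()
    occupied = int(np.count_nonzero(counts))
    return entropy(counts / n) + (occupied - 1) / (2.0 * n * _LN2)


def entropy_from_counts(counts: np.ndarray, estimator: str = "ml",
                        prior_weight: float = 1.0) -> float:
    """Entropy of a frequency table under the named estimator (bits)."""
    if estimator == "miller_madow":
        return miller_madow_entropy(counts)
    return entropy(estimate_probabilities(counts, estimator, prior_weight))
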