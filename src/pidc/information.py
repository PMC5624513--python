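"""Multivariate information measures on discretized gene triplets.

Implements mutual information (MI), conditional mutual information (CMI),
interaction information, specific information, and the partial information
decomposition (PID) that splits the information two *source* genes carry
about a *target* gene into redundant, unique (one per source) and
synergistic parts:

    I({X,Y}; Z) = Redundancy + Unique_X + Unique_Y + Synergy

Redundancy is the target-probability-weighted minimum over sources of the
specific information; each unique term is the corresponding pairwise MI
minus the redundancy; synergy is the remainder (equivalently, redundancy
plus the interaction information).  "Source" and "target" carry no
mechanistic meaning — they only say which gene's states are being informed
about.

All measures are in bits.  For the Dirichlet and shrinkage estimators every
marginal is obtained by marginalizing the single estimated joint table, so
the decomposition identities hold exactly for every estimator that yields a
probability table.  Miller-Madow corrects entropies directly and is allowed
only for the entropy-combination measures (MI, CMI, interaction
information), never for PID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probability import (
    entropy,
    estimate_probabilities,
    joint_counts,
    miller_madow_entropy,
)

__all__ = [
    "PIDResult",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "specific_information",
    "pid",
    "mi_from_counts",
    "pid_from_counts",
]

_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class PIDResult:
    """Four-term decomposition (bits) for one (target; source, source) triplet."""

    target: str
    sources: tuple[str, str]
    redundancy: float
    unique_x: float
    unique_y: float
    synergy: float

    @property
    def total(self) -> float:
        """I({X,Y}; Z): sum of the four terms."""
        return self.redundancy + self.unique_x + self.unique_y + self.synergy


def _labels(v) -> np.ndarray:
    return np.asarray(getattr(v, "labels", v), dtype=np.int64)


def _check_lengths(*vs) -> None:
    n = _labels(vs[0]).size
    if any(_labels(v).size != n for v in vs):
        raise ValueError("variables must have equal observation counts")


def _clip_nonneg(value: float, what: str) -> float:
    if value < -_CLIP_TOL:
        raise ArithmeticError(
            f"internal consistency error: {what} = {value} is negative beyond tolerance"
        )
    return max(value, 0.0)


def _entropy_of(counts: np.ndarray, axes: tuple[int, ...], estimator: str,
                prior_weight: float, probs: np.ndarray | None) -> float:
    """Entropy of the marginal over ``axes`` of a joint table.

    Probability estimators marginalize the shared estimated joint ``probs``;
    Miller-Madow sums the counts and corrects per marginal table.
    """
    drop = tuple(i for i in range(counts.ndim) if i not in axes)
    if estimator == "miller_madow":
        return miller_madow_entropy(counts.sum(axis=drop))
    return entropy(probs.sum(axis=drop))


def _joint(counts_or_vars, estimator, prior_weight):
    counts = np.asarray(counts_or_vars, dtype=float)
    probs = None
    if estimator != "miller_madow":
        probs = estimate_probabilities(counts, estimator, prior_weight)
    return counts, probs


def mi_from_counts(counts: np.ndarray, estimator: str = "ml",
                   prior_weight: float = 1.0) -> float:
    """MI (bits) from a 2-d joint frequency table: H(X) + H(Y) - H(X,Y)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("MI requires a 2-d joint table")
    counts, probs = _joint(counts, estimator, prior_weight)
    hx = _entropy_of(counts, (0,), estimator, prior_weight, probs)
    hy = _entropy_of(counts, (1,), estimator, prior_weight, probs)
    hxy = _entropy_of(counts, (0, 1), estimator, prior_weight, probs)
    mi = hx + hy - hxy
    return mi if estimator == "miller_madow" else _clip_nonneg(mi, "mutual information")


def mutual_information(x, y, estimator: str = "ml", prior_weight: float = 1.0) -> float:
    """MI (bits) between two discretized variables."""
    _check_lengths(x, y)
    return mi_from_counts(joint_counts(x, y), estimator, prior_weight)


def conditional_mutual_information(x, y, z, estimator: str = "ml",
                                   prior_weight: float = 1.0) -> float:
    """CMI I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z), in bits."""
    _check_lengths(x, y, z)
    counts, probs = _joint(joint_counts(x, y, z), estimator, prior_weight)
    hxz = _entropy_of(counts, (0, 2), estimator, prior_weight, probs)
    hyz = _entropy_of(counts, (1, 2), estimator, prior_weight, probs)
    hxyz = _entropy_of(counts, (0, 1, 2), estimator, prior_weight, probs)
    hz = _entropy_of(counts, (2,), estimator, prior_weight, probs)
    cmi = hxz + hyz - hxyz - hz
    if estimator == "miller_madow":
        return cmi
    return _clip_nonneg(cmi, "conditional mutual information")


def interaction_information(x, y, z, estimator: str = "ml",
                            prior_weight: float = 1.0) -> float:
    """Interaction information II = I(X;Y|Z) - I(X;Y); may be negative.

    Symmetric under any rotation of the three variables, because every term
    is an entropy of a marginal of the same joint table.
    """
    _check_lengths(x, y, z)
    counts, probs = _joint(joint_counts(x, y, z), estimator, prior_weight)

    def h(axes):
        return _entropy_of(counts, axes, estimator, prior_weight, probs)

    # I(X;Y|Z) - I(X;Y) expanded in joint entropies
    return (h((0, 1)) + h((0, 2)) + h((1, 2))
            - h((0,)) - h((1,)) - h((2,)) - h((0, 1, 2)))


def _specific_information_vector(p_sz: np.ndarray) -> np.ndarray:
    """I_spec(z; S) for every state z, from a joint p(source, target).

    I_spec(z;S) = sum_s p(s|z) log2( p(s|z) / p(s) ), the KL divergence of
    the source distribution conditioned on state z from its marginal.
    """
    p_z = p_sz.sum(axis=0)
    p_s = p_sz.sum(axis=1)
    out = np.zeros(p_sz.shape[1])
    for zi in range(p_sz.shape[1]):
        if p_z[zi] <= 0:
            continue
        cond = p_sz[:, zi] / p_z[zi]
        mask = cond > 0
        out[zi] = float(np.sum(cond[mask] * np.log2(cond[mask] / p_s[mask])))
    return out


def specific_information(z_state: int, z, x, estimator: str = "ml",
                         prior_weight: float = 1.0) -> float:
    """Information source X provides about one particular state of target Z."""
    _check_lengths(z, x)
    counts = joint_counts(x, z)
    probs = estimate_probabilities(counts, estimator, prior_weight)
    p_z = probs.sum(axis=0)
    if z_state < 0 or z_state >= p_z.size or p_z[z_state] <= 0:
        raise ValueError(f"target state {z_state} has zero probability")
    return float(_specific_information_vector(probs)[z_state])


def pid_from_counts(counts: np.ndarray, estimator: str = "ml",
                    prior_weight: float = 1.0,
                    target: str = "Z", sources: tuple[str, str] = ("X", "Y")) -> PIDResult:
    """PID from a 3-d joint table with axes (source X, source Y, target Z)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("PID requires a 3-d joint table (X, Y, target)")
    probs = estimate_probabilities(counts, estimator, prior_weight)

    p_xz = probs.sum(axis=1)
    p_yz = probs.sum(axis=0)
    p_z = probs.sum(axis=(0, 1))

    spec_x = _specific_information_vector(p_xz)
    spec_y = _specific_information_vector(p_yz)
    redundancy = float(np.sum(p_z * np.minimum(spec_x, spec_y)))

    # Pairwise MI terms from the same joint table; note the identity
    # I(S;Z) = sum_z p(z) I_spec(z;S).
    i_xz = float(np.sum(p_z * spec_x))
    i_yz = float(np.sum(p_z * spec_y))
    unique_x = _clip_nonneg(i_xz - redundancy, "unique information")
    unique_y = _clip_nonneg(i_yz - redundancy, "unique information")

    def h(axes):
        drop = tuple(i for i in range(3) if i not in axes)
        return entropy(probs.sum(axis=drop))

    i_joint = h((0, 1)) + h((2,)) - h((0, 1, 2))
    synergy = _clip_nonneg(i_joint - redundancy - unique_x - unique_y, "synergy")
    redundancy = _clip_nonneg(redundancy, "redundancy")
    return PIDResult(target=target, sources=tuple(sources), redundancy=redundancy,
                     unique_x=unique_x, unique_y=unique_y, synergy=synergy)


def pid(target, x, y, estimator: str = "ml", prior_weight: float = 1.0) -> PIDResult:
    """Partial information decomposition for sources (x, y) about ``target``.

    ``unique_x`` is the unique information carried by source ``x`` about the
    target, and symmetrically for ``unique_y``.
    """
    _check_lengths(target, x, y)
    counts = joint_counts(x, y, target)
    return pid_from_counts(
        counts, estimator, prior_weight,
        target=getattr(target, "source_gene", "Z") or "Z",
        sources=(getattr(x, "source_gene", "X") or "X",
                 getattr(y, "source_gene", "Y") or "Y"),
    )
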