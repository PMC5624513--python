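"""Discretization of continuous expression vectors.

Information measures on expression data require discrete states.  Two
partition schemes are provided:

* **uniform width** — equal-width bins spanning the observed range, with the
  bin count defaulting to the nearest integer to the square root of the
  sample size;
* **Bayesian blocks** — an adaptive, variable-width partition chosen by
  maximising the Scargle point-measures fitness function, which places
  change-points where the empirical density changes and thereby adapts the
  bin widths to the data.

Each gene is discretized once from its full marginal; joint frequency
tables over gene pairs/triplets are built on the product of these per-gene
partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BinEdges",
    "DiscretizedVariable",
    "uniform_width_edges",
    "bayesian_blocks_edges",
    "discretize",
    "discretize_matrix",
    "ExpressionDiscretizer",
    "DISCRETIZERS",
]

DISCRETIZERS = ("bayesian_blocks", "uniform_width")


@dataclass(frozen=True)
class BinEdges:
    """A 1-d partition: ``B + 1`` strictly increasing boundaries for ``B`` bins."""

    edges: np.ndarray
    method: str

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-d array of at least 2 boundaries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.method not in DISCRETIZERS:
            raise ValueError(f"unknown discretization method {self.method!r}")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclass(frozen=True)
class DiscretizedVariable:
    """Integer bin labels (0-based) for one gene's observations."""

    labels: np.ndarray
    n_bins: int
    source_gene: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-d")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_bins):
            raise ValueError("labels out of range [0, n_bins)")

    def __len__(self) -> int:
        return self.labels.size


def _check_finite(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite values at indices {bad[:10].tolist()}")
    return values


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def uniform_width_edges(values: Sequence[float], n_bins: int | None = None) -> BinEdges:
    """Equal-width partition of ``[min, max]``.

    When ``n_bins`` is omitted it defaults to ``round(sqrt(n))`` (half away
    from zero), the usual heuristic for sample size ``n``, with a minimum of
    one bin.  A constant vector yields a single degenerate bin.
    """
    values = _check_finite(values)
    if n_bins is None:
        n_bins = max(1, _round_half_away(math.sqrt(values.size)))
    if n_bins < 1:
        raise ValueError("n_bins must be a positive integer")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # Degenerate range: one bin of nominal unit width around the value.
        return BinEdges(np.array([lo - 0.5, hi + 0.5]), "uniform_width")
    return BinEdges(np.linspace(lo, hi, n_bins + 1), "uniform_width")


def _bayesian_blocks_ncp_prior(n: int, p0: float) -> float:
    # Scargle (2013) eq. 21 calibration of the change-point prior for a
    # false-alarm probability p0.
    return 4.0 - math.log(73.53 * p0 * n ** -0.478)


def bayesian_blocks_edges(values: Sequence[float], p0: float = 0.05) -> BinEdges:
    """Adaptive variable-width partition via the Bayesian-blocks algorithm.

    Dynamic-programming optimisation of the point-measures fitness
    ``sum_k N_k log(N_k / T_k)`` minus a per-block prior penalty calibrated
    for false-alarm probability ``p0`` (default 0.05).  Runs in O(n^2) on the
    number of distinct values.
    """
    values = _check_finite(values)
    if values.size < 2:
        raise ValueError("Bayesian blocks requires at least 2 observations")
    t, counts = np.unique(values, return_counts=True)
    n_unique = t.size
    if n_unique == 1:
        v = t[0]
        return BinEdges(np.array([v - 0.5, v + 0.5]), "bayesian_blocks")

    # Voronoi cell edges around the distinct values.
    edges = np.concatenate([[t[0]], 0.5 * (t[1:] + t[:-1]), [t[-1]]])
    block_length = t[-1] - edges  # length from each edge to the data end
    ncp_prior = _bayesian_blocks_ncp_prior(values.size, p0)

    best = np.zeros(n_unique)
    last = np.zeros(n_unique, dtype=np.int64)
    cum_counts = np.concatenate([[0], np.cumsum(counts)])
    for r in range(n_unique):
        # widths of candidate blocks [k..r] and their event counts
        width = block_length[: r + 1] - block_length[r + 1]
        nk = cum_counts[r + 1] - cum_counts[: r + 1]
        width = np.maximum(width, 1e-300)
        fitness = nk * np.log(nk / width) - ncp_prior
        fitness[1:] += best[:r]
        imax = int(np.argmax(fitness))
        last[r] = imax
        best[r] = fitness[imax]

    # Walk the change-points back from the end.
    change_points = []
    ind = n_unique
    while ind > 0:
        change_points.append(ind)
        ind = last[ind - 1]
    change_points.append(0)
    change_points = np.array(change_points[::-1])
    return BinEdges(edges[change_points], "bayesian_blocks")


def discretize(values: Sequence[float], edges: BinEdges) -> DiscretizedVariable:
    """Assign each value to its bin: half-open bins, last bin closed on the
    right, values outside the fitted range clamped to the nearest end bin."""
    values = _check_finite(values)
    labels = np.searchsorted(edges.edges, values, side="right") - 1
    labels = np.clip(labels, 0, edges.n_bins - 1)
    return DiscretizedVariable(labels, edges.n_bins)


def fit_edges(values: Sequence[float], method: str = "bayesian_blocks",
              n_bins: int | None = None) -> BinEdges:
    """Dispatch to the named discretizer."""
    if method == "bayesian_blocks":
        return bayesian_blocks_edges(values)
    if method == "uniform_width":
        return uniform_width_edges(values, n_bins=n_bins)
    raise ValueError(f"unknown discretizer {method!r}; choose from {DISCRETIZERS}")


def discretize_matrix(values: np.ndarray, method: str = "bayesian_blocks",
                      n_bins: int | None = None,
                      gene_names: Sequence[str] | None = None) -> list[DiscretizedVariable]:
    """Discretize each row (gene) of a genes x cells matrix independently."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-d genes x cells matrix")
    names = list(gene_names) if gene_names is not None else [f"G{i}" for i in range(values.shape[0])]
    out = []
    for name, row in zip(names, values):
        edges = fit_edges(row, method=method, n_bins=n_bins)
        dv = discretize(row, edges)
        out.append(DiscretizedVariable(dv.labels, dv.n_bins, source_gene=name))
    return out


class ExpressionDiscretizer(TransformerMixin, BaseEstimator):
    """Per-feature discretizer with the sklearn transformer interface.

    Parameters
    ----------
    method : {"bayesian_blocks", "uniform_width"}
        Partition scheme; Bayesian blocks is the recommended default.
    n_bins : int or None
        Overrides the sqrt(n) heuristic for uniform-width binning.

    Attributes
    ----------
    bin_edges_ : list of BinEdges, one per feature (column of X).
    n_bins_ : ndarray of bin counts per feature.
    """

    def __init__(self, method: str = "bayesian_blocks", n_bins: int | None = None):
        self.method = method
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_cells, n_genes)")
        self.n_features_in_ = X.shape[1]
        self.bin_edges_ = [fit_edges(X[:, j], method=self.method, n_bins=self.n_bins)
                           for j in range(X.shape[1])]
        self.n_bins_ = np.array([e.n_bins for e in self.bin_edges_])
        return self

    def transform(self, X):
        check_is_fitted(self, "bin_edges_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fit")
        out = np.empty(X.shape, dtype=np.int64)
        for j, edges in enumerate(self.bin_edges_):
            out[:, j] = discretize(X[:, j], edges).labels
        return out
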