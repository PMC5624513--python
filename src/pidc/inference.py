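"""Network inference from single-cell expression matrices.

The algorithms all start from per-gene discretized expression and rank the
C(n,2) undirected gene pairs:

* **relevance** — rank by raw pairwise MI;
* **CLR** — combine per-gene z-scores of MI against each gene's own MI
  background, ``sqrt(z_X^2 + z_Y^2)``;
* **ARACNE** — prune, in every gene triangle, the weakest MI edge via the
  data processing inequality with tolerance ``tau``;
* **PUC** — for each pair (X, Y), sum over every third gene Z the ratio of
  unique information to MI, with each of X and Y treated as the target in
  turn (the proportional unique contribution, ``u_{X,Y}``);
* **PIDC** — PUC plus network context: per gene, an empirical CDF (Gamma by
  default, Gaussian optionally or as fallback) is fitted to its PUC scores,
  and the edge confidence is ``c = F_X(u_{X,Y}) + F_Y(u_{X,Y})``.

Each algorithm is exposed both as a scikit-learn style estimator class
(``fit(X)`` with ``X`` of shape (n_cells, n_genes), fitted attributes with
trailing underscores) and as a module-level function taking a genes x cells
matrix (the orientation expression files use).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .discretization import DiscretizedVariable, discretize_matrix
from .information import _specific_information_vector, mi_from_counts
from .probability import estimate_probabilities, joint_counts

__all__ = [
    "Edge",
    "RankedEdgeList",
    "GeneScoreDistribution",
    "mi_matrix",
    "relevance_network",
    "clr_network",
    "aracne_network",
    "puc_matrix",
    "fit_gene_distribution",
    "pidc_network",
    "threshold_top_percent",
    "infer_network",
    "RelevanceNetwork",
    "CLRNetwork",
    "AracneNetwork",
    "PUCNetwork",
    "PIDCNetwork",
    "ALGORITHMS",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("pidc", "puc", "clr", "mi", "aracne")

_MI_FLOOR = 1e-12  # pairs below this MI contribute nothing to PUC (0/0 rule)


class Edge(NamedTuple):
    gene_a: str
    gene_b: str
    score: float


@dataclass(frozen=True)
class RankedEdgeList:
    """Scored undirected edges in deterministic order.

    Within each edge ``gene_a < gene_b`` lexicographically; edges are sorted
    by score descending with ties broken by gene-pair lexicographic order.
    """

    genes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.gene_a == e.gene_b:
                raise ValueError(f"self-edge on {e.gene_a!r}")
            if e.gene_a > e.gene_b:
                raise ValueError("edges must store gene_a < gene_b")
            pair = (e.gene_a, e.gene_b)
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def n_possible_edges(self) -> int:
        n = len(self.genes)
        return n * (n - 1) // 2

    @classmethod
    def from_score_matrix(cls, genes: Sequence[str], scores: np.ndarray) -> "RankedEdgeList":
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("edge scores must be finite")
        edges = []
        for i, j in combinations(range(len(genes)), 2):
            a, b = sorted((str(genes[i]), str(genes[j])))
            edges.append(Edge(a, b, float(scores[i, j])))
        edges.sort(key=lambda e: (-e.score, e.gene_a, e.gene_b))
        return cls(tuple(str(g) for g in genes), tuple(edges))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.edges, columns=["gene_a", "gene_b", "score"])
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def _as_gene_matrix(data, gene_names=None) -> tuple[np.ndarray, list[str]]:
    """Coerce input to (values genes x cells, gene names)."""
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(g) for g in data.index]
    values = np.asarray(data, dtype=float)
    if values.ndim != 2:
        raise ValueError("expression data must be 2-d (genes x cells)")
    if gene_names is None:
        gene_names = [f"G{i + 1}" for i in range(values.shape[0])]
    return values, [str(g) for g in gene_names]


def _check_variability(values: np.ndarray, genes: Sequence[str]) -> None:
    flat = [g for g, row in zip(genes, values) if np.ptp(row) == 0]
    if flat:
        raise ValueError(
            "genes with no variability are uninformative and must be removed "
            f"before inference: {flat}"
        )


def _discretize(values, genes, discretizer, n_bins) -> list[DiscretizedVariable]:
    return discretize_matrix(values, method=discretizer, n_bins=n_bins, gene_names=genes)


def _mi_matrix_from_discrete(disc: Sequence[DiscretizedVariable], estimator: str,
                             prior_weight: float) -> np.ndarray:
    n = len(disc)
    mi = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mi[i, j] = mi[j, i] = mi_from_counts(
            joint_counts(disc[i], disc[j]), estimator, prior_weight)
    return mi


def mi_matrix(data, discretizer: str = "bayesian_blocks", estimator: str = "ml",
              n_bins: int | None = None, prior_weight: float = 1.0,
              gene_names=None) -> pd.DataFrame:
    """Symmetric pairwise MI matrix (bits) with zero diagonal.

    ``data`` is genes x cells (DataFrame indexed by gene, or array).  Genes
    with zero variance are rejected by name.
    """
    values, genes = _as_gene_matrix(data, gene_names)
    if len(genes) < 2:
        raise ValueError("MI matrix requires at least 2 genes")
    _check_variability(values, genes)
    disc = _discretize(values, genes, discretizer, n_bins)
    mi = _mi_matrix_from_discrete(disc, estimator, prior_weight)
    return pd.DataFrame(mi, index=genes, columns=genes)


def _mi_df_to_parts(mi) -> tuple[np.ndarray, list[str]]:
    if isinstance(mi, pd.DataFrame):
        return mi.to_numpy(dtype=float), [str(g) for g in mi.index]
    m = np.asarray(mi, dtype=float)
    return m, [f"G{i + 1}" for i in range(m.shape[0])]


def relevance_network(mi) -> RankedEdgeList:
    """Rank edges by raw pairwise MI (relevance network)."""
    m, genes = _mi_df_to_parts(mi)
    return RankedEdgeList.from_score_matrix(genes, m)


def _clr_z(mi: np.ndarray) -> np.ndarray:
    """Per-gene background z-scores of the MI matrix, self excluded,
    negative z clipped to 0; rows with zero spread contribute zero."""
    n = mi.shape[0]
    z = np.zeros_like(mi)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = mi[i, off[i]]
        sd = row.std()
        if sd > 0:
            z[i, off[i]] = np.maximum(0.0, (row - row.mean()) / sd)
    return z


def clr_network(mi) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores sqrt(z_X^2 + z_Y^2)."""
    m, genes = _mi_df_to_parts(mi)
    if len(genes) < 3:
        raise ValueError("CLR requires at least 3 genes")
    z = _clr_z(m)
    scores = np.sqrt(z ** 2 + z.T ** 2)
    return RankedEdgeList.from_score_matrix(genes, scores)


def aracne_network(mi, tau: float = 0.1) -> RankedEdgeList:
    """DPI pruning: in every gene triangle the minimum-MI edge is removed if
    it is below ``(1 - tau)`` times the second-smallest MI in the triangle.
    Surviving edges are ranked by MI; removed edges trail with score 0."""
    if not 0 <= tau < 1:
        raise ValueError("tau must satisfy 0 <= tau < 1")
    m, genes = _mi_df_to_parts(mi)
    n = len(genes)
    removed = np.zeros((n, n), dtype=bool)
    for i, j, k in combinations(range(n), 3):
        trio = [(m[i, j], (i, j)), (m[i, k], (i, k)), (m[j, k], (j, k))]
        trio.sort(key=lambda t: t[0])
        if trio[0][0] < (1.0 - tau) * trio[1][0]:
            a, b = trio[0][1]
            removed[a, b] = removed[b, a] = True
    scores = np.where(removed, 0.0, m)
    return RankedEdgeList.from_score_matrix(genes, scores)


def _redundancies_all_targets(probs: np.ndarray) -> np.ndarray:
    """Redundancy with each of the three axes of a joint p(x0, x1, x2)
    treated as the target in turn; returns array of length 3."""
    out = np.empty(3)
    for t in range(3):
        s1, s2 = [a for a in range(3) if a != t]
        # marginals p(source, target)
        p_1t = probs.sum(axis=s2) if s1 < t else probs.sum(axis=s2).T
        p_2t = probs.sum(axis=s1) if s2 < t else probs.sum(axis=s1).T
        p_t = probs.sum(axis=tuple(a for a in range(3) if a != t))
        spec1 = _specific_information_vector(p_1t)
        spec2 = _specific_information_vector(p_2t)
        out[t] = float(np.sum(p_t * np.minimum(spec1, spec2)))
    return out


def _puc_from_discrete(disc: Sequence[DiscretizedVariable], estimator: str,
                       prior_weight: float) -> tuple[np.ndarray, np.ndarray]:
    """PUC matrix u and the pairwise MI matrix it is built on."""
    n = len(disc)
    mi = _mi_matrix_from_discrete(disc, estimator, prior_weight)
    u = np.zeros((n, n))
    for i, j, k in combinations(range(n), 3):
        counts = joint_counts(disc[i], disc[j], disc[k])
        probs = estimate_probabilities(counts, estimator, prior_weight)
        red = _redundancies_all_targets(probs)
        for (a, b), c in (((i, j), k), ((i, k), j), ((j, k), i)):
            pair_mi = mi[a, b]
            if pair_mi < _MI_FLOOR:
                continue
            # Unique_{third}(a;b) = I(a;b) - Redundancy(target a), clipped >= 0.
            trio = [i, j, k]
            ra = red[trio.index(a)]
            rb = red[trio.index(b)]
            ua = max(pair_mi - ra, 0.0)
            ub = max(pair_mi - rb, 0.0)
            contrib = (ua + ub) / pair_mi
            u[a, b] += contrib
            u[b, a] += contrib
    return u, mi


def puc_matrix(data, discretizer: str = "bayesian_blocks", estimator: str = "ml",
               n_bins: int | None = None, prior_weight: float = 1.0,
               gene_names=None) -> pd.DataFrame:
    """Proportional unique contribution u_{X,Y} for every gene pair.

    For each pair the unique-to-MI ratio is summed over all n - 2 third
    genes with each pair member treated as the target in turn, so
    0 <= u_{X,Y} <= 2 (n - 2).  Pairs with MI below tolerance contribute 0.
    """
    values, genes = _as_gene_matrix(data, gene_names)
    if len(genes) < 3:
        raise ValueError("PUC requires at least 3 genes (n - 2 triplets per pair)")
    _check_variability(values, genes)
    disc = _discretize(values, genes, discretizer, n_bins)
    u, _ = _puc_from_discrete(disc, estimator, prior_weight)
    return pd.DataFrame(u, index=genes, columns=genes)


@dataclass(frozen=True)
class GeneScoreDistribution:
    """Fitted empirical distribution of one gene's PUC scores.

    ``family`` records the distribution actually used ("gamma" or
    "gaussian"; the Gamma method-of-moments fit falls back to Gaussian when
    the moments are invalid, and a zero-variance Gaussian degenerates to a
    step CDF at the common value).
    """

    gene: str
    family: str
    params: dict
    support: np.ndarray = field(repr=False)

    def cdf(self, u) -> np.ndarray | float:
        u = np.asarray(u, dtype=float)
        if self.family == "gamma":
            out = stats.gamma.cdf(u, a=self.params["shape"], scale=self.params["scale"])
        else:
            sd = self.params["sd"]
            if sd > 0:
                out = stats.norm.cdf(u, loc=self.params["mean"], scale=sd)
            else:
                out = (u >= self.params["mean"]).astype(float)
        return float(out) if out.ndim == 0 else out


def fit_gene_distribution(scores, family: str = "gamma",
                          gene: str = "") -> GeneScoreDistribution:
    """Fit a Gamma (method of moments) or Gaussian CDF to a gene's scores.

    Gamma: shape = mean^2 / var, scale = var / mean.  Invalid moments
    (non-positive mean or variance) fall back to Gaussian with a warning;
    zero variance yields a step CDF.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 2:
        raise ValueError("need at least 2 scores to fit a distribution")
    if family not in ("gamma", "gaussian"):
        raise ValueError("family must be 'gamma' or 'gaussian'")
    mean = float(scores.mean())
    var = float(scores.var())
    if family == "gamma":
        if mean <= 0 or var <= 0:
            logger.warning(
                "gene %s: invalid Gamma moments (mean=%.4g, var=%.4g); "
                "falling back to Gaussian", gene, mean, var)
            family = "gaussian"
        else:
            return GeneScoreDistribution(gene, "gamma",
                                         {"shape": mean ** 2 / var, "scale": var / mean},
                                         scores)
    return GeneScoreDistribution(gene, "gaussian",
                                 {"mean": mean, "sd": math.sqrt(max(var, 0.0))},
                                 scores)


def _pidc_scores(u: np.ndarray, genes: Sequence[str],
                 family: str) -> tuple[np.ndarray, list[GeneScoreDistribution]]:
    n = len(genes)
    off = ~np.eye(n, dtype=bool)
    dists = [fit_gene_distribution(u[i, off[i]], family=family, gene=genes[i])
             for i in range(n)]
    c = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        c[i, j] = c[j, i] = float(dists[i].cdf(u[i, j]) + dists[j].cdf(u[i, j]))
    return c, dists


def pidc_network(data, discretizer: str = "bayesian_blocks", estimator: str = "ml",
                 family: str = "gamma", n_bins: int | None = None,
                 prior_weight: float = 1.0, gene_names=None) -> RankedEdgeList:
    """Full PIDC ranking: PUC scores placed in each gene's network context.

    The confidence of edge (X, Y) is ``F_X(u_{X,Y}) + F_Y(u_{X,Y})`` where
    F is the per-gene fitted CDF of PUC scores; c lies in [0, 2].
    """
    values, genes = _as_gene_matrix(data, gene_names)
    est = PIDCNetwork(discretizer=discretizer, estimator=estimator,
                      edge_distribution=family, n_bins=n_bins,
                      prior_weight=prior_weight)
    est.fit(values.T, gene_names=genes)
    return est.ranked_edges_


def threshold_top_percent(ranked: RankedEdgeList, percent: float) -> RankedEdgeList:
    """Keep the ceil(percent% of n(n-1)/2) highest-ranked edges."""
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    keep = math.ceil(percent / 100.0 * ranked.n_possible_edges)
    return RankedEdgeList(ranked.genes, ranked.edges[:keep])


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

class _BaseNetworkEstimator(BaseEstimator):
    """Shared fit machinery: X is (n_cells, n_genes), continuous.

    Fitted attributes: ``gene_names_``, ``mi_matrix_`` (bits),
    ``scores_`` (symmetric edge-score matrix), ``ranked_edges_``.
    """

    _min_genes = 2

    def __init__(self, discretizer="bayesian_blocks", estimator="ml",
                 n_bins=None, prior_weight=1.0):
        self.discretizer = discretizer
        self.estimator = estimator
        self.n_bins = n_bins
        self.prior_weight = prior_weight

    def fit(self, X, y=None, gene_names=None):
        if isinstance(X, pd.DataFrame):
            if gene_names is None:
                gene_names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_cells, n_genes)")
        n_cells, n_genes = X.shape
        if n_genes < self._min_genes:
            raise ValueError(f"this algorithm requires >= {self._min_genes} genes")
        if n_cells < 20:
            logger.warning("only %d cells: information estimates will be noisy", n_cells)
        self.n_features_in_ = n_genes
        values = X.T  # genes x cells
        genes = ([f"G{i + 1}" for i in range(n_genes)]
                 if gene_names is None else [str(g) for g in gene_names])
        _check_variability(values, genes)
        self.gene_names_ = tuple(genes)
        disc = _discretize(values, genes, self.discretizer, self.n_bins)
        self._fit_scores(disc)
        self.ranked_edges_ = RankedEdgeList.from_score_matrix(genes, self.scores_)
        return self

    def _fit_scores(self, disc):  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, X=None):
        """Return the fitted symmetric edge-score matrix."""
        check_is_fitted(self, "scores_")
        return self.scores_


class RelevanceNetwork(_BaseNetworkEstimator):
    """Relevance network: edges scored by raw pairwise MI."""

    def _fit_scores(self, disc):
        self.mi_matrix_ = _mi_matrix_from_discrete(disc, self.estimator, self.prior_weight)
        self.scores_ = self.mi_matrix_.copy()


class CLRNetwork(_BaseNetworkEstimator):
    """Context likelihood of relatedness on the MI matrix."""

    _min_genes = 3

    def _fit_scores(self, disc):
        self.mi_matrix_ = _mi_matrix_from_discrete(disc, self.estimator, self.prior_weight)
        z = _clr_z(self.mi_matrix_)
        self.scores_ = np.sqrt(z ** 2 + z.T ** 2)


class AracneNetwork(_BaseNetworkEstimator):
    """ARACNE: MI ranking after data-processing-inequality pruning."""

    _min_genes = 3

    def __init__(self, discretizer="bayesian_blocks", estimator="ml",
                 n_bins=None, prior_weight=1.0, tau=0.1):
        super().__init__(discretizer, estimator, n_bins, prior_weight)
        self.tau = tau

    def _fit_scores(self, disc):
        self.mi_matrix_ = _mi_matrix_from_discrete(disc, self.estimator, self.prior_weight)
        genes = [d.source_gene for d in disc]
        ranked = aracne_network(pd.DataFrame(self.mi_matrix_, index=genes, columns=genes),
                                tau=self.tau)
        idx = {g: i for i, g in enumerate(genes)}
        scores = np.zeros_like(self.mi_matrix_)
        for e in ranked:
            scores[idx[e.gene_a], idx[e.gene_b]] = e.score
            scores[idx[e.gene_b], idx[e.gene_a]] = e.score
        self.scores_ = scores


class PUCNetwork(_BaseNetworkEstimator):
    """Raw proportional-unique-contribution scores."""

    _min_genes = 3

    def _fit_scores(self, disc):
        u, mi = _puc_from_discrete(disc, self.estimator, self.prior_weight)
        self.mi_matrix_ = mi
        self.puc_matrix_ = u
        self.scores_ = u.copy()


class PIDCNetwork(_BaseNetworkEstimator):
    """PIDC: PUC scores ranked through per-gene empirical CDFs.

    Parameters
    ----------
    edge_distribution : {"gamma", "gaussian"}
        Family for the per-gene PUC score distribution (Gamma by default,
        with automatic Gaussian fallback on invalid moments).
    """

    _min_genes = 3

    def __init__(self, discretizer="bayesian_blocks", estimator="ml",
                 n_bins=None, prior_weight=1.0, edge_distribution="gamma"):
        super().__init__(discretizer, estimator, n_bins, prior_weight)
        self.edge_distribution = edge_distribution

    def _fit_scores(self, disc):
        u, mi = _puc_from_discrete(disc, self.estimator, self.prior_weight)
        self.mi_matrix_ = mi
        self.puc_matrix_ = u
        genes = [d.source_gene for d in disc]
        self.scores_, self.gene_distributions_ = _pidc_scores(
            u, genes, self.edge_distribution)


_ALGORITHM_CLASSES = {
    "mi": RelevanceNetwork,
    "clr": CLRNetwork,
    "aracne": AracneNetwork,
    "puc": PUCNetwork,
    "pidc": PIDCNetwork,
}


def infer_network(data, algorithm: str = "pidc", gene_names=None,
                  **params) -> RankedEdgeList:
    """One-call inference on a genes x cells matrix with the named algorithm."""
    if algorithm not in _ALGORITHM_CLASSES:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    values, genes = _as_gene_matrix(data, gene_names)
    est = _ALGORITHM_CLASSES[algorithm](**params)
    est.fit(values.T, gene_names=genes)
    return est.ranked_edges_
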