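"""Scoring inferred networks against gold standards.

Inferred rankings are undirected, so a predicted pair counts as a true
positive when the directed gold standard contains an edge in either
direction.  AUPR uses step-wise precision interpolation (linear
interpolation overstates the area on sparse gold standards); AUROC uses the
trapezoid rule.  Ties in the ranking are resolved by the deterministic
order of the ranked edge list itself, and gold-standard pairs missing from
the ranking are appended as the lowest-ranked predictions.

Also provides the six-way topology classification of gene triplets in a
DAG gold standard (unconnected, one-edge, chain, fan-out, fan-in,
feed-forward loop) and the subset-network comparison / connectivity curves
used to characterise inferred networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np

from .inference import RankedEdgeList, threshold_top_percent

__all__ = [
    "GoldStandardNetwork",
    "ConfusionCounts",
    "TripletClass",
    "pr_and_roc",
    "confusion_at_top",
    "classify_triplet",
    "triplet_census",
    "compare_subset_networks",
    "connected_fraction_curve",
]


@dataclass(frozen=True)
class GoldStandardNetwork:
    """Directed gold-standard edges plus the undirected pair set used for
    scoring.  ``known_negatives`` records explicitly flagged non-edges."""

    genes: tuple[str, ...]
    directed_edges: tuple[tuple[str, str], ...]
    known_negatives: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene names in gold standard")
        for src, dst in self.directed_edges:
            if src == dst:
                raise ValueError(f"self-edge on {src!r} in gold standard")
            if src not in gene_set or dst not in gene_set:
                raise ValueError(f"edge ({src}, {dst}) references unknown gene")

    @classmethod
    def from_topology(cls, topology, gene_names=None) -> "GoldStandardNetwork":
        names = list(gene_names) if gene_names is not None else topology.gene_names()
        return cls(tuple(names),
                   tuple((names[s], names[d]) for s, d, _ in topology.edges))

    @property
    def positive_pairs(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.directed_edges)

    def all_pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted(p)) for p in combinations(sorted(self.genes), 2)]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def _ranked_labels(ranked: RankedEdgeList, gold: GoldStandardNetwork) -> np.ndarray:
    """0/1 gold labels of all gene pairs in prediction order.

    The pair universe is the union of the ranking's and the gold standard's
    genes (edge-list gold files do not mention isolated genes); pairs absent
    from the ranking are appended last in lexicographic order."""
    universe = sorted(set(gold.genes) | set(ranked.genes))
    positives = gold.positive_pairs
    seen = set()
    order = []
    for e in ranked:
        order.append((e.gene_a, e.gene_b))
        seen.add((e.gene_a, e.gene_b))
    for pair in combinations(universe, 2):
        pair = tuple(sorted(pair))
        if pair not in seen:
            order.append(pair)
    return np.array([frozenset(p) in positives for p in order], dtype=float)


def pr_and_roc(ranked: RankedEdgeList, gold: GoldStandardNetwork):
    """(AUPR, AUROC, curves) for a ranking against a gold standard.

    ``curves`` holds the swept recall/precision and FPR/TPR arrays.
    """
    labels = _ranked_labels(ranked, gold)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard needs at least one positive and one "
                         "negative gene pair")
    tp = np.cumsum(labels)
    fp = np.arange(1, labels.size + 1) - tp
    precision = tp / np.arange(1, labels.size + 1)
    recall = tp / n_pos
    tpr = recall
    fpr = fp / n_neg
    # Step-wise AUPR: recall increments by 1/n_pos exactly at the positives.
    aupr = float(np.sum(precision[labels == 1]) / n_pos)
    auroc = float(np.trapezoid(np.concatenate([[0.0], tpr]),
                               np.concatenate([[0.0], fpr])))
    curves = {"precision": precision, "recall": recall, "fpr": fpr, "tpr": tpr}
    return aupr, auroc, curves


def confusion_at_top(ranked: RankedEdgeList, gold: GoldStandardNetwork,
                     k: int) -> ConfusionCounts:
    """Confusion counts when the top ``k`` ranked pairs are called edges."""
    labels = _ranked_labels(ranked, gold)
    n_pos = int(labels.sum())
    k = min(k, labels.size)
    tp = int(labels[:k].sum())
    fp = k - tp
    fn = n_pos - tp
    tn = labels.size - k - fn
    return ConfusionCounts(tp, fp, tn, fn)


class TripletClass(str, Enum):
    UNCONNECTED = "unconnected"
    ONE_EDGE = "one_edge"
    CHAIN = "chain"
    FAN_OUT = "fan_out"
    FAN_IN = "fan_in"
    FEED_FORWARD_LOOP = "feed_forward_loop"


def classify_triplet(gold: GoldStandardNetwork, triplet) -> TripletClass:
    """Classify a gene triplet by its directed connectivity in the gold
    standard.  The six classes are exhaustive for triplets drawn from a
    network with no self-loops, no 2-cycles and no feedback loops."""
    trio = [str(g) for g in triplet]
    if len(set(trio)) != 3:
        raise ValueError("triplet must contain three distinct genes")
    gene_set = set(gold.genes)
    if not set(trio) <= gene_set:
        raise ValueError("triplet genes missing from gold standard")
    edges = [(s, d) for s, d in gold.directed_edges if s in trio and d in trio]
    for s, d in edges:
        if (d, s) in edges:
            raise ValueError(f"2-cycle between {s} and {d}: not a DAG triplet")
    n = len(edges)
    if n == 0:
        return TripletClass.UNCONNECTED
    if n == 1:
        return TripletClass.ONE_EDGE
    if n == 2:
        sources = [s for s, _ in edges]
        targets = [d for _, d in edges]
        if sources[0] == sources[1]:
            return TripletClass.FAN_OUT
        if targets[0] == targets[1]:
            return TripletClass.FAN_IN
        return TripletClass.CHAIN
    if n == 3:
        # acyclic iff some node has out-degree 2 (the FFL master regulator)
        out_deg = {g: sum(1 for s, _ in edges if s == g) for g in trio}
        if max(out_deg.values()) == 2:
            return TripletClass.FEED_FORWARD_LOOP
        raise ValueError(f"3-cycle among {trio}: not a DAG triplet")
    raise ValueError(f"more than 3 edges among {trio}")


def triplet_census(gold: GoldStandardNetwork) -> dict:
    """Counts and fractions of the six triplet classes over all C(n, 3)
    triplets of the gold standard."""
    counts = {c: 0 for c in TripletClass}
    total = 0
    for trio in combinations(sorted(gold.genes), 3):
        counts[classify_triplet(gold, trio)] += 1
        total += 1
    return {c: {"count": counts[c],
                "fraction": counts[c] / total if total else 0.0}
            for c in TripletClass}


def compare_subset_networks(full: RankedEdgeList, subset_a: RankedEdgeList,
                            subset_b: RankedEdgeList, percent: float) -> dict:
    """Label each retained edge of the full network by its presence in the
    top-``percent`` edge sets of two data-subset networks.

    Labels: ``A_specific`` (in A's top set only), ``B_specific`` (B only),
    ``shared_or_full_only`` otherwise.
    """
    universes = {tuple(sorted(r.genes)) for r in (full, subset_a, subset_b)}
    if len(universes) != 1:
        raise ValueError("the three rankings must share one gene universe")
    top_full = threshold_top_percent(full, percent)
    in_a = {(e.gene_a, e.gene_b) for e in threshold_top_percent(subset_a, percent)}
    in_b = {(e.gene_a, e.gene_b) for e in threshold_top_percent(subset_b, percent)}
    labels = {}
    for e in top_full:
        pair = (e.gene_a, e.gene_b)
        if pair in in_a and pair not in in_b:
            labels[pair] = "A_specific"
        elif pair in in_b and pair not in in_a:
            labels[pair] = "B_specific"
        else:
            labels[pair] = "shared_or_full_only"
    return labels


def connected_fraction_curve(ranked: RankedEdgeList,
                             n_genes: int | None = None):
    """Fraction of nodes connected as the edge-inclusion threshold sweeps
    from 0% to 100% of possible edges.

    Returns (percents, fractions), both of length len(ranked) + 1, with the
    fraction after each successive edge; nondecreasing in the threshold.
    """
    n = n_genes if n_genes is not None else len(ranked.genes)
    total_pairs = n * (n - 1) // 2
    touched: set = set()
    fractions = [0.0]
    for e in ranked:
        touched.update((e.gene_a, e.gene_b))
        fractions.append(len(touched) / n)
    percents = np.array([100.0 * k / total_pairs for k in range(len(ranked) + 1)])
    return percents, np.array(fractions)
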