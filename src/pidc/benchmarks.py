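"""Reusable benchmark analyses over the simulators and inference algorithms.

These compose the simulation, decomposition, inference and evaluation
layers into the two study designs used to validate the method:

* the three-gene PID profile — decompose every triplet arrangement of a
  small circuit's pooled time-course records and summarise unique
  information between connected vs unconnected gene pairs against the
  redundancy (the signature that motivates scoring edges by unique
  information);
* the n-gene algorithm benchmark — simulate snapshot data from random
  signed DAGs with the mass-action model, optionally inject dropouts, and
  score each inference algorithm's ranking against the generating topology
  by AUPR.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .discretization import discretize_matrix
from .evaluation import GoldStandardNetwork, pr_and_roc
from .inference import infer_network
from .information import pid
from .simulate import (
    CircuitTopology,
    MassActionParams,
    ThermoParams,
    TrajectoryEnsemble,
    add_dropouts,
    random_dag,
    sample_cells,
    simulate_mass_action,
    simulate_stimulus_sweep,
)

__all__ = [
    "pid_profile_summary",
    "one_edge_pattern_hits",
    "algorithm_aupr_benchmark",
]


def _restrict_times(ens: TrajectoryEnsemble, keep: np.ndarray) -> TrajectoryEnsemble:
    return TrajectoryEnsemble(ens.species, ens.times[keep], ens.states[:, keep],
                              ens.gene_names, ens.mrna_indices, ens.seed)


def pid_profile_summary(topology: CircuitTopology, seed: int = 0,
                        model: str = "thermo", repeats: int | None = None,
                        discretizer: str = "bayesian_blocks",
                        estimator: str = "ml",
                        steady_state: bool = False) -> dict:
    """Mean PID terms for a small circuit, split by pair connectivity.

    Runs the full stimulus-sweep protocol (ligand targeting each gene in
    turn), pools each sweep's recorded mRNA states, decomposes every
    (target; source, source) arrangement of every gene triplet, and returns
    the mean unique information between connected and unconnected pairs and
    the mean redundancy.

    With ``steady_state`` the stimulus never arrives and only records after
    a long burn-in are kept, the regime in which the statistical
    relationships between genes fade.
    """
    params = None
    if steady_state:
        if model != "thermo":
            raise NotImplementedError("steady-state variant defined for thermo")
        params = ThermoParams(stimulus_on_time=1e12, t_end=2000.0, n_records=81)
    ensembles = simulate_stimulus_sweep(model, topology, params=params,
                                        repeats=repeats, seed=seed)
    if steady_state:
        ensembles = [_restrict_times(e, e.times >= 1000.0) for e in ensembles]
    connected = topology.undirected_pairs()
    names = topology.gene_names()
    u_conn, u_unconn, reds = [], [], []
    for ens in ensembles:
        data = ens.to_expression()
        disc = {v.source_gene: v for v in discretize_matrix(
            data.to_numpy(), method=discretizer, gene_names=list(data.index))}
        for trio in combinations(range(topology.n_genes), 3):
            for tgt in trio:
                x, y = [g for g in trio if g != tgt]
                r = pid(disc[names[tgt]], disc[names[x]], disc[names[y]],
                        estimator=estimator)
                reds.append(r.redundancy)
                for src, u in ((x, r.unique_x), (y, r.unique_y)):
                    pair = frozenset((tgt, src))
                    (u_conn if pair in connected else u_unconn).append(u)
    return {
        "mean_unique_connected": float(np.mean(u_conn)) if u_conn else np.nan,
        "mean_unique_unconnected": float(np.mean(u_unconn)) if u_unconn else np.nan,
        "mean_redundancy": float(np.mean(reds)),
    }


def one_edge_pattern_hits(n_seed_sets: int = 5, seed: int = 0,
                          repeats: int = 25) -> int:
    """How many of ``n_seed_sets`` initial-condition sets show the one-edge
    signature: unique information between the connected pair exceeding both
    the redundancy and the unique information between unconnected pairs."""
    topology = CircuitTopology(3, ((0, 1, "activate"),))
    children = np.random.SeedSequence(seed).spawn(n_seed_sets)
    hits = 0
    for child in children:
        s = int(child.generate_state(1)[0] >> np.uint32(1))
        prof = pid_profile_summary(topology, seed=s, repeats=repeats)
        if prof["mean_unique_connected"] > max(prof["mean_unique_unconnected"],
                                               prof["mean_redundancy"]):
            hits += 1
    return hits


def algorithm_aupr_benchmark(algorithms=("mi", "puc", "pidc"), n_seeds: int = 10,
                             seed: int = 0, n_genes: int = 10,
                             mean_degree: float = 2.0, repeats: int = 100,
                             scheme: str = "medium",
                             dropout_quantile: float | None = None,
                             discretizer: str = "bayesian_blocks",
                             estimator: str = "ml") -> pd.DataFrame:
    """AUPR of each algorithm over ``n_seeds`` random-DAG benchmark runs.

    Each run draws a signed DAG, simulates the mass-action generalisation
    over [0, 1000] with the ligand rotating across repeats, samples cells
    under the named scheme, optionally injects dropouts (values below the
    per-gene ``dropout_quantile`` zeroed with probability 0.5), infers a
    ranking per algorithm and scores it against the generating topology.
    Returns a (seed x algorithm) AUPR table.
    """
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    rows = []
    for child in children:
        s = int(child.generate_state(1)[0] >> np.uint32(1))
        topo = random_dag(n_genes, mean_degree=mean_degree, seed=s)
        if not topo.undirected_pairs():  # degenerate draw: no gold positives
            topo = random_dag(n_genes, mean_degree=mean_degree, seed=s + 1)
        ens = simulate_mass_action(topo, MassActionParams.benchmark(),
                                   repeats=repeats, seed=s, rotate_stimulus=True)
        data = sample_cells(ens, scheme=scheme, seed=s)
        if dropout_quantile is not None:
            data = add_dropouts(data, quantile=dropout_quantile,
                                drop_prob=0.5, seed=s)
        gold = GoldStandardNetwork.from_topology(topo)
        row = {}
        for algo in algorithms:
            ranked = infer_network(data, algorithm=algo,
                                   discretizer=discretizer, estimator=estimator)
            row[algo], _, _ = pr_and_roc(ranked, gold)
        rows.append(row)
    return pd.DataFrame(rows)
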