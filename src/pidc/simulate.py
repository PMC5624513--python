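"""Stochastic simulation of small gene circuits for benchmark data.

Two exact-SSA (Gillespie) models of transcriptional regulation are
implemented:

* a **thermodynamic** three-gene model with species mRNA ``x_i``, protein
  ``y_i`` (i = 1..3) and a stimulating ligand ``s``; transcription
  propensities are thermodynamic averages over promoter occupancy states
  (at most two regulators bound at once), translation saturates, and mRNA
  and protein decay linearly;
* a **mass-action** model with species gene copies ``g_i``, combined
  mRNA/protein ``x_i``, bound complexes ``g_i x_j`` and the ligand ``s``;
  translation is instantaneous and a gene is bound by at most one protein
  at a time.  Its reactions are local to (regulator, target) pairs, so the
  same scheme generalises unchanged to n-gene circuits for benchmark
  harnessing.

In both models the stimulating ligand appears at a constant clamped level
halfway through the time course, perturbing the system away from steady
state — without that perturbation the statistical relationships between
genes are largely undetectable.

Single cells are emulated by sampling recorded time points across repeat
simulations (:func:`sample_cells`), and technical dropouts by zeroing
low-expression values probabilistically (:func:`add_dropouts`).

The inner SSA loops are numba-compiled; :func:`gillespie` is a plain-Python
reference SSA over arbitrary propensity callables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "ACTIVATE",
    "INHIBIT",
    "CircuitTopology",
    "ThermoParams",
    "MassActionParams",
    "TrajectoryEnsemble",
    "gillespie",
    "thermo_transcription_rate",
    "simulate_thermo",
    "simulate_mass_action",
    "simulate_stimulus_sweep",
    "pooled_expression",
    "sample_cells",
    "add_dropouts",
    "random_dag",
    "SAMPLING_SCHEMES",
]

ACTIVATE = 1
INHIBIT = -1
_SIGNS = {ACTIVATE, INHIBIT, "activate", "inhibit"}


def _norm_sign(sign) -> int:
    if sign in (ACTIVATE, "activate"):
        return ACTIVATE
    if sign in (INHIBIT, "inhibit"):
        return INHIBIT
    raise ValueError(f"edge sign must be activate/inhibit, got {sign!r}")


@dataclass(frozen=True)
class CircuitTopology:
    """Signed directed circuit: edges are (regulator, target, sign) with
    0-based gene indices; at most one edge per unordered gene pair and no
    self-regulation.  ``stimulus_target`` names the gene the stimulating
    ligand activates."""

    n_genes: int
    edges: tuple[tuple[int, int, int], ...] = ()
    stimulus_target: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        norm = []
        seen_pairs = set()
        for src, dst, sign in self.edges:
            if not (0 <= src < self.n_genes and 0 <= dst < self.n_genes):
                raise ValueError(f"edge ({src}, {dst}) out of range")
            if src == dst:
                raise ValueError(f"self-regulation on gene {src} is not allowed")
            pair = frozenset((src, dst))
            if pair in seen_pairs:
                raise ValueError(f"multiple edges between genes {src} and {dst}")
            seen_pairs.add(pair)
            norm.append((int(src), int(dst), _norm_sign(sign)))
        object.__setattr__(self, "edges", tuple(norm))
        if not 0 <= self.stimulus_target < self.n_genes:
            raise ValueError("stimulus_target out of range")

    def regulators_of(self, gene: int) -> list[tuple[int, int]]:
        """(regulator, sign) pairs with an edge into ``gene``."""
        return [(s, sg) for s, d, sg in self.edges if d == gene]

    def with_stimulus_target(self, gene: int) -> "CircuitTopology":
        return replace(self, stimulus_target=gene)

    def is_dag(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_genes))
        g.add_edges_from((s, d) for s, d, _ in self.edges)
        return nx.is_directed_acyclic_graph(g)

    def undirected_pairs(self) -> set[frozenset]:
        return {frozenset((s, d)) for s, d, _ in self.edges}

    def gene_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic-model rate constants (time in arbitrary units).

    Defaults: decay 0.02, transcription scale 2, translation max 2,
    dissociation constant 50 molecules, relative promoter activities 0.1
    (unbound), 0.001 (any inhibitor bound), 5 (activators only); ligand
    clamped at 20 molecules from t = 500 of a [0, 1000] course recorded at
    41 equally spaced times.
    """

    lambda_decay: float = 0.02
    alpha_transcription: float = 2.0
    alpha_translation: float = 2.0
    k_half: float = 50.0
    alpha_unbound: float = 0.1
    alpha_inhibited: float = 0.001
    alpha_activated: float = 5.0
    stimulus_level: float = 20.0
    stimulus_on_time: float = 500.0
    t_end: float = 1000.0
    n_records: int = 41

    def __post_init__(self) -> None:
        for name in ("lambda_decay", "alpha_transcription", "alpha_translation",
                     "k_half", "alpha_unbound", "alpha_inhibited", "alpha_activated"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.alpha_inhibited <= self.alpha_unbound <= self.alpha_activated):
            raise ValueError("require alpha_inhibited <= alpha_unbound <= alpha_activated")

    @property
    def record_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_records)


@dataclass(frozen=True)
class MassActionParams:
    """Mass-action-model rate constants.

    Defaults: transcription 1 per gene copy, decay 0.05, binding 0.01,
    unbinding 0.25, regulated transcription 10 (activating) or 0.1
    (inhibiting), 2 gene copies; ligand clamped at 20 molecules from
    t = 200 of a [0, 400] course recorded at 21 equally spaced times.
    """

    k_txn: float = 1.0
    k_decay: float = 0.05
    k_on: float = 0.01
    k_off: float = 0.25
    k_regulated_act: float = 10.0
    k_regulated_inh: float = 0.1
    gene_copies: int = 2
    stimulus_level: float = 20.0
    stimulus_on_time: float = 200.0
    t_end: float = 400.0
    n_records: int = 21

    def __post_init__(self) -> None:
        for name in ("k_txn", "k_decay", "k_on", "k_off",
                     "k_regulated_act", "k_regulated_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_copies < 1:
            raise ValueError("gene_copies must be >= 1")

    @classmethod
    def benchmark(cls, **overrides) -> "MassActionParams":
        """Benchmark-harness variant: [0, 1000] course, ligand from t = 500,
        recorded on the canonical 21-point grid (step 50) so the standard
        cell-sampling schemes apply."""
        kw = dict(stimulus_on_time=500.0, t_end=1000.0, n_records=21)
        kw.update(overrides)
        return cls(**kw)

    @property
    def record_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_records)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Recorded SSA states: ``states[repeat, time, species]`` (integer copy
    numbers), with species labels and the indices of the observable mRNA
    species."""

    species: tuple[str, ...]
    times: np.ndarray
    states: np.ndarray
    gene_names: tuple[str, ...]
    mrna_indices: tuple[int, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 3 or states.shape[2] != len(self.species):
            raise ValueError("states must be (repeats, times, species)")
        if np.any(states < 0):
            raise ValueError("copy numbers must be non-negative")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_repeats(self) -> int:
        return self.states.shape[0]

    @property
    def n_records(self) -> int:
        """Total recorded states (repeats x time points)."""
        return self.states.shape[0] * self.states.shape[1]

    def to_expression(self) -> pd.DataFrame:
        """All recorded mRNA states pooled as a genes x cells matrix."""
        mrna = self.states[:, :, list(self.mrna_indices)]  # R x T x G
        r, t, g = mrna.shape
        cells = [f"r{i}_t{self.times[j]:g}" for i in range(r) for j in range(t)]
        return pd.DataFrame(mrna.reshape(r * t, g).T.astype(float),
                            index=list(self.gene_names), columns=cells)


# ---------------------------------------------------------------------------
# Generic (pure-Python) SSA
# ---------------------------------------------------------------------------

def gillespie(propensities: Callable[[np.ndarray, float], np.ndarray],
              transitions: np.ndarray, state0: Sequence[float],
              record_times: Sequence[float], seed: int,
              t0: float = 0.0) -> np.ndarray:
    """Exact SSA over arbitrary propensity callables.

    ``propensities(state, t)`` returns the reaction rates; ``transitions``
    is the (n_reactions, n_species) state-change matrix.  The state recorded
    at each requested time reflects all events up to that time.
    """
    transitions = np.asarray(transitions, dtype=np.int64)
    state = np.asarray(state0, dtype=np.int64).copy()
    record_times = np.asarray(record_times, dtype=float)
    out = np.empty((record_times.size, state.size), dtype=np.int64)
    rng = np.random.default_rng(seed)
    t, ri = float(t0), 0
    while ri < record_times.size:
        a = np.asarray(propensities(state, t), dtype=float)
        if np.any(a < 0):
            raise ValueError(f"negative propensity {a} at state {state.tolist()}, t={t}")
        a_tot = a.sum()
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf
        while ri < record_times.size and record_times[ri] < t_next:
            out[ri] = state
            ri += 1
        if ri >= record_times.size:
            break
        r = rng.choice(a.size, p=a / a_tot)
        state += transitions[r]
        t = t_next
    return out


# ---------------------------------------------------------------------------
# Thermodynamic model (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _thermo_f(gene, y, s, n_regs, reg_idx, reg_act, k_half,
              a_txn, a0, a_inh, a_act):
    """Thermodynamic transcription propensity for one gene.

    Promoter states: unbound (weight 1, activity a0) and every single
    regulator or pair of regulators bound (weight = product of chi = level/k;
    activity a_inh if any inhibitor is bound, else a_act).  At most two of
    the up-to-three eligible regulators bind simultaneously.
    """
    num = a0
    den = 1.0
    for a in range(n_regs[gene]):
        ia = reg_idx[gene, a]
        level_a = s if ia == 3 else y[ia]
        chi_a = level_a / k_half
        num += (a_act if reg_act[gene, a] == 1 else a_inh) * chi_a
        den += chi_a
        for b in range(a + 1, n_regs[gene]):
            ib = reg_idx[gene, b]
            level_b = s if ib == 3 else y[ib]
            chi_b = level_b / k_half
            w = chi_a * chi_b
            both_act = reg_act[gene, a] == 1 and reg_act[gene, b] == 1
            num += (a_act if both_act else a_inh) * w
            den += w
    return a_txn * num / den


@njit(cache=True)
def _thermo_ssa(x0, y0, stim_level, stim_on, lam, a_txn, a_tl, k_half,
                a0, a_inh, a_act, n_regs, reg_idx, reg_act,
                record_times, seed):
    np.random.seed(seed)
    x = x0.astype(np.float64)
    y = y0.astype(np.float64)
    s = 0.0
    n_rec = record_times.size
    out = np.empty((n_rec, 7), dtype=np.int64)
    props = np.empty(12)
    t = 0.0
    ri = 0
    stim_done = False
    while ri < n_rec:
        for i in range(3):
            props[i] = lam * x[i]
            props[3 + i] = lam * y[i]
            props[6 + i] = a_tl * x[i] / (x[i] + k_half) if x[i] > 0 else 0.0
            props[9 + i] = _thermo_f(i, y, s, n_regs, reg_idx, reg_act,
                                     k_half, a_txn, a0, a_inh, a_act)
        a_tot = 0.0
        for r in range(12):
            a_tot += props[r]
        if a_tot > 0:
            t_next = t - np.log(np.random.random()) / a_tot
        else:
            t_next = np.inf
        if not stim_done and t_next >= stim_on:
            while ri < n_rec and record_times[ri] < stim_on:
                for i in range(3):
                    out[ri, i] = np.int64(x[i])
                    out[ri, 3 + i] = np.int64(y[i])
                out[ri, 6] = np.int64(s)
                ri += 1
            t = stim_on
            s = stim_level
            stim_done = True
            continue
        while ri < n_rec and record_times[ri] < t_next:
            for i in range(3):
                out[ri, i] = np.int64(x[i])
                out[ri, 3 + i] = np.int64(y[i])
            out[ri, 6] = np.int64(s)
            ri += 1
        if ri >= n_rec:
            break
        u = np.random.random() * a_tot
        c = 0.0
        chosen = 11
        for r in range(12):
            c += props[r]
            if u <= c:
                chosen = r
                break
        i = chosen % 3
        kind = chosen // 3
        if kind == 0:
            x[i] -= 1.0
        elif kind == 1:
            y[i] -= 1.0
        elif kind == 2:
            y[i] += 1.0
        else:
            x[i] += 1.0
        t = t_next
    return out


def _thermo_regulator_tables(topology: CircuitTopology):
    if topology.n_genes != 3:
        raise ValueError("the thermodynamic model is defined for 3-gene circuits")
    n_regs = np.zeros(3, dtype=np.int64)
    reg_idx = np.full((3, 3), -1, dtype=np.int64)
    reg_act = np.zeros((3, 3), dtype=np.int64)
    for gene in range(3):
        regs = topology.regulators_of(gene)
        if len(regs) > 2:
            raise ValueError(
                f"gene {gene} has {len(regs)} regulators; the thermodynamic "
                "model allows at most 2 protein regulators per gene")
        if gene == topology.stimulus_target:
            regs = regs + [(3, ACTIVATE)]  # ligand, index 3, always activating
        n_regs[gene] = len(regs)
        for a, (src, sign) in enumerate(regs):
            reg_idx[gene, a] = src
            reg_act[gene, a] = 1 if sign == ACTIVATE else 0
    return n_regs, reg_idx, reg_act


def thermo_transcription_rate(gene: int, protein_levels: Sequence[float],
                              stimulus: float, topology: CircuitTopology,
                              params: ThermoParams = ThermoParams()) -> float:
    """Transcription propensity of ``gene`` at the given protein/ligand
    levels (same code path as the simulator kernel)."""
    y = np.asarray(protein_levels, dtype=float)
    if y.size != 3 or np.any(y < 0) or stimulus < 0:
        raise ValueError("protein and ligand levels must be 3 non-negative values")
    n_regs, reg_idx, reg_act = _thermo_regulator_tables(topology)
    return float(_thermo_f(gene, y, float(stimulus), n_regs, reg_idx, reg_act,
                           params.k_half, params.alpha_transcription,
                           params.alpha_unbound, params.alpha_inhibited,
                           params.alpha_activated))


def _kernel_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) >> np.uint32(1)


def simulate_thermo(topology: CircuitTopology, params: ThermoParams = ThermoParams(),
                    repeats: int = 25, seed: int = 0,
                    initial_state: tuple | None = None) -> TrajectoryEnsemble:
    """Repeat SSA runs of the thermodynamic 3-gene model.

    Initial mRNA and protein levels are one U(0, 5) draw (rounded to
    integers) shared by all repeats of the call, emulating one "initial
    condition set"; pass ``initial_state=(x0, y0)`` to fix them.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n_regs, reg_idx, reg_act = _thermo_regulator_tables(topology)
    rng = np.random.default_rng(seed)
    if initial_state is None:
        x0 = np.round(rng.uniform(0, 5, 3)).astype(np.int64)
        y0 = np.round(rng.uniform(0, 5, 3)).astype(np.int64)
    else:
        x0 = np.asarray(initial_state[0], dtype=np.int64)
        y0 = np.asarray(initial_state[1], dtype=np.int64)
    times = params.record_times
    seeds = _kernel_seeds(seed, repeats)
    states = np.empty((repeats, times.size, 7), dtype=np.int64)
    for r in range(repeats):
        states[r] = _thermo_ssa(
            x0, y0, params.stimulus_level, params.stimulus_on_time,
            params.lambda_decay, params.alpha_transcription,
            params.alpha_translation, params.k_half, params.alpha_unbound,
            params.alpha_inhibited, params.alpha_activated,
            n_regs, reg_idx, reg_act, times, int(seeds[r]))
    species = tuple(f"x{i + 1}" for i in range(3)) + \
        tuple(f"y{i + 1}" for i in range(3)) + ("s",)
    return TrajectoryEnsemble(species, times, states,
                              tuple(topology.gene_names()), (0, 1, 2), seed)


# ---------------------------------------------------------------------------
# Mass-action model (generic product-form numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ma_ssa(state0, rates, re1, re2, ch_idx, ch_val, stim_idx, stim_on,
            stim_level, record_times, seed):
    np.random.seed(seed)
    state = state0.astype(np.float64)
    n_rx = rates.size
    n_rec = record_times.size
    n_sp = state.size
    out = np.empty((n_rec, n_sp), dtype=np.int64)
    props = np.empty(n_rx)
    t = 0.0
    ri = 0
    stim_done = False
    while ri < n_rec:
        a_tot = 0.0
        for r in range(n_rx):
            a = rates[r]
            if re1[r] >= 0:
                a *= state[re1[r]]
            if re2[r] >= 0:
                a *= state[re2[r]]
            props[r] = a
            a_tot += a
        if a_tot > 0:
            t_next = t - np.log(np.random.random()) / a_tot
        else:
            t_next = np.inf
        if not stim_done and t_next >= stim_on:
            while ri < n_rec and record_times[ri] < stim_on:
                for k in range(n_sp):
                    out[ri, k] = np.int64(state[k])
                ri += 1
            t = stim_on
            state[stim_idx] = stim_level
            stim_done = True
            continue
        while ri < n_rec and record_times[ri] < t_next:
            for k in range(n_sp):
                out[ri, k] = np.int64(state[k])
            ri += 1
        if ri >= n_rec:
            break
        u = np.random.random() * a_tot
        c = 0.0
        chosen = n_rx - 1
        for r in range(n_rx):
            c += props[r]
            if u <= c:
                chosen = r
                break
        for k in range(4):
            idx = ch_idx[chosen, k]
            if idx >= 0:
                state[idx] += ch_val[chosen, k]
        t = t_next
    return out


def _mass_action_system(topology: CircuitTopology, params: MassActionParams,
                        stimulus_target: int, literal_txn: bool):
    """Reaction tables for the kernel.  Species order: g_1..g_n, x_1..x_n,
    one complex per regulatory edge (incl. the ligand edge), then s."""
    n = topology.n_genes
    edges = list(topology.edges) + [(-1, stimulus_target, ACTIVATE)]  # -1 = ligand
    species = [f"g{i + 1}" for i in range(n)] + [f"x{i + 1}" for i in range(n)]
    cpx_index = {}
    for e, (src, dst, _) in enumerate(edges):
        reg = "s" if src == -1 else f"x{src + 1}"
        cpx_index[e] = len(species)
        species.append(f"g{dst + 1}.{reg}")
    stim_idx = len(species)
    species.append("s")

    def g(i):
        return i

    def x(i):
        return n + i

    reactions = []  # (rate, re1, re2, {species: delta})
    for i in range(n):
        if literal_txn:
            reactions.append((params.k_txn, x(i), -1, {x(i): 1}))
        else:
            reactions.append((params.k_txn, g(i), -1, {x(i): 1}))
        reactions.append((params.k_decay, x(i), -1, {x(i): -1}))
    for e, (src, dst, sign) in enumerate(edges):
        cpx = cpx_index[e]
        if src == -1:
            # ligand is clamped: binding does not consume it
            reactions.append((params.k_on, g(dst), stim_idx, {g(dst): -1, cpx: 1}))
            reactions.append((params.k_off, cpx, -1, {cpx: -1, g(dst): 1}))
        else:
            reactions.append((params.k_on, g(dst), x(src),
                              {g(dst): -1, x(src): -1, cpx: 1}))
            reactions.append((params.k_off, cpx, -1,
                              {cpx: -1, g(dst): 1, x(src): 1}))
        k_reg = params.k_regulated_act if sign == ACTIVATE else params.k_regulated_inh
        reactions.append((k_reg, cpx, -1, {x(dst): 1}))

    n_rx = len(reactions)
    rates = np.array([r[0] for r in reactions])
    re1 = np.array([r[1] for r in reactions], dtype=np.int64)
    re2 = np.array([r[2] for r in reactions], dtype=np.int64)
    ch_idx = np.full((n_rx, 4), -1, dtype=np.int64)
    ch_val = np.zeros((n_rx, 4))
    for r, (_, _, _, changes) in enumerate(reactions):
        for k, (idx, delta) in enumerate(changes.items()):
            ch_idx[r, k] = idx
            ch_val[r, k] = delta
    return species, stim_idx, rates, re1, re2, ch_idx, ch_val


def simulate_mass_action(topology: CircuitTopology,
                         params: MassActionParams = MassActionParams(),
                         repeats: int = 50, seed: int = 0,
                         initial_state: Sequence[float] | None = None,
                         literal_txn: bool = False,
                         rotate_stimulus: bool = False) -> TrajectoryEnsemble:
    """Repeat SSA runs of the mass-action model (any number of genes).

    Initial mRNA/protein levels are one rounded U(0, 50) draw shared across
    repeats; genes start at ``gene_copies`` free copies.  With
    ``rotate_stimulus`` the ligand targets gene ``r mod n`` on repeat r
    (the n-gene analogue of stimulating each gene in turn).
    ``literal_txn`` switches basal transcription to the propensity
    ``k_txn * x_i`` (autocatalytic reading) instead of ``k_txn * g_i``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n = topology.n_genes
    rng = np.random.default_rng(seed)
    if initial_state is None:
        x0 = np.round(rng.uniform(0, 50, n)).astype(np.int64)
    else:
        x0 = np.asarray(initial_state, dtype=np.int64)

    targets = ([r % n for r in range(repeats)] if rotate_stimulus
               else [topology.stimulus_target] * repeats)
    systems = {t: _mass_action_system(topology, params, t, literal_txn)
               for t in sorted(set(targets))}
    species0, stim_idx, *_ = systems[targets[0]]
    n_species = len(species0)

    times = params.record_times
    seeds = _kernel_seeds(seed, repeats)
    states = np.empty((repeats, times.size, n_species), dtype=np.int64)
    for r, tgt in enumerate(targets):
        species, s_idx, rates, re1, re2, ch_idx, ch_val = systems[tgt]
        state0 = np.zeros(n_species, dtype=np.int64)
        state0[:n] = params.gene_copies
        state0[n:2 * n] = x0
        states[r] = _ma_ssa(state0, rates, re1, re2, ch_idx, ch_val,
                            s_idx, params.stimulus_on_time,
                            params.stimulus_level, times, int(seeds[r]))
    return TrajectoryEnsemble(tuple(species0), times, states,
                              tuple(topology.gene_names()),
                              tuple(range(n, 2 * n)), seed)


def simulate_stimulus_sweep(model: str, topology: CircuitTopology, params=None,
                            repeats: int | None = None,
                            seed: int = 0) -> list[TrajectoryEnsemble]:
    """One ensemble per gene with the stimulating ligand targeting that gene
    in turn (the full protocol is repeats x n_genes simulations)."""
    if model == "thermo":
        params = params or ThermoParams()
        repeats = 25 if repeats is None else repeats
        sim = simulate_thermo
    elif model == "mass_action":
        params = params or MassActionParams()
        repeats = 50 if repeats is None else repeats
        sim = simulate_mass_action
    else:
        raise ValueError("model must be 'thermo' or 'mass_action'")
    children = np.random.SeedSequence(seed).spawn(topology.n_genes)
    return [sim(topology.with_stimulus_target(g), params, repeats=repeats,
                seed=int(children[g].generate_state(1)[0] >> np.uint32(1)))
            for g in range(topology.n_genes)]


def pooled_expression(ensembles: Sequence[TrajectoryEnsemble]) -> pd.DataFrame:
    """Concatenate the pooled mRNA records of several ensembles."""
    frames = []
    for i, ens in enumerate(ensembles):
        df = ens.to_expression()
        df.columns = [f"e{i}_{c}" for c in df.columns]
        frames.append(df)
    return pd.concat(frames, axis=1)


# ---------------------------------------------------------------------------
# Cell sampling and dropout
# ---------------------------------------------------------------------------

# Canonical sampling schemes on the default 21-point grid (times 0..1000,
# step 50): cells per sampled time point and the sampled times.
SAMPLING_SCHEMES = {
    "large": (100, np.arange(0.0, 1001.0, 50.0)),    # 2,100 cells
    "medium": (100, np.arange(0.0, 901.0, 150.0)),   # 700 cells
    "small": (20, np.arange(0.0, 301.0, 50.0)),      # 140 cells
}


def sample_cells(ensemble: TrajectoryEnsemble, scheme: str = "medium",
                 seed: int = 0, times: Sequence[float] | None = None,
                 per_time: int | None = None) -> pd.DataFrame:
    """Emulate a single-cell snapshot experiment from a trajectory ensemble.

    For each sampled time point, ``per_time`` distinct repeats are drawn
    without replacement and their mRNA state at that time becomes one cell.
    ``scheme`` picks a canonical (per_time, times) pair; pass ``times`` and
    ``per_time`` for a custom scheme.  Only mRNA species are returned.
    """
    if times is None or per_time is None:
        if scheme not in SAMPLING_SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from "
                             f"{sorted(SAMPLING_SCHEMES)} or give times/per_time")
        per_time, times = SAMPLING_SCHEMES[scheme]
    times = np.asarray(times, dtype=float)
    grid = np.asarray(ensemble.times, dtype=float)
    idx = []
    for t in times:
        hits = np.flatnonzero(np.isclose(grid, t))
        if hits.size == 0:
            raise ValueError(f"time {t} not on the ensemble grid {grid}")
        idx.append(hits[0])
    if ensemble.n_repeats < per_time:
        raise ValueError(
            f"sampling {per_time} cells per time without replacement requires "
            f">= {per_time} repeats (ensemble has {ensemble.n_repeats})")
    rng = np.random.default_rng(seed)
    cols, data = [], []
    mrna = list(ensemble.mrna_indices)
    for t, ti in zip(times, idx):
        reps = rng.choice(ensemble.n_repeats, size=per_time, replace=False)
        for r in reps:
            cols.append(f"t{t:g}_r{r}")
            data.append(ensemble.states[r, ti, mrna])
    return pd.DataFrame(np.array(data, dtype=float).T,
                        index=list(ensemble.gene_names), columns=cols)


DROPOUT_RATES = {"low": 0.2, "high": 0.5}


def add_dropouts(data: pd.DataFrame, quantile: float = 0.5,
                 drop_prob: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Zero-inflate a genes x cells matrix: per gene, values strictly below
    the per-gene empirical ``quantile`` are set to 0 independently with
    probability ``drop_prob``.  quantile 0.2 is the low dropout rate, 0.5
    the high rate."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if not 0 <= drop_prob <= 1:
        raise ValueError("drop_prob must be in [0, 1]")
    values = data.to_numpy(dtype=float).copy()
    rng = np.random.default_rng(seed)
    for i in range(values.shape[0]):
        thresh = np.quantile(values[i], quantile)
        low = values[i] < thresh
        drop = low & (rng.random(values.shape[1]) < drop_prob)
        values[i, drop] = 0.0
    return pd.DataFrame(values, index=data.index, columns=data.columns)


def random_dag(n_genes: int, mean_degree: float = 2.0, sign_prob: float = 0.5,
               seed: int = 0, stimulus_target: int = 0) -> CircuitTopology:
    """Random signed DAG: no self-loops, at most one edge per gene pair, no
    feedback loops.  ``mean_degree`` is the expected undirected degree
    (2 E / n); each edge is activating with probability ``sign_prob``."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if mean_degree < 0:
        raise ValueError("mean_degree must be >= 0")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    p_edge = min(1.0, mean_degree / (n_genes - 1))
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                sign = ACTIVATE if rng.random() < sign_prob else INHIBIT
                edges.append((int(order[i]), int(order[j]), sign))
    return CircuitTopology(n_genes, tuple(edges), stimulus_target=stimulus_target)
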