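# pidc

Gene regulatory network inference from single-cell expression data using
**partial information decomposition (PID)**, together with the stochastic
circuit simulators, discretization schemes, entropy estimators and
evaluation metrics needed to validate it.

## The problem and the method

Single-cell experiments measure mRNA levels in hundreds to thousands of
individual cells. The cell-to-cell variability in these data carries
statistical dependencies between genes that can reveal (co-)regulatory
relationships. Pairwise mutual information (MI) captures arbitrary
nonlinear dependencies, but it cannot tell a direct interaction from a
shared upstream cause. PID looks at gene *triplets*: for sources
X, Y and target Z it splits the joint information into four non-negative
parts

    I({X,Y}; Z) = Redundancy + Unique_X + Unique_Y + Synergy,

where the redundancy is the target-state-weighted minimum of the *specific
information* each source provides, and each unique term satisfies
`I(X;Z) = Unique_X + Redundancy`. "Source" and "target" carry no mechanistic
meaning — they only name the roles in the decomposition.

For every gene pair (X, Y), the **proportional unique contribution (PUC)**
sums the unique-to-MI ratio over all n − 2 third genes, with each pair
member treated as the target in turn:

    u_XY = Σ_Z Unique_Z(X;Y) / I(X;Y)  +  Σ_Z Unique_Z(Y;X) / I(X;Y).

Because PUC scores are distributed differently from gene to gene, a global
threshold would bias the network toward highly variable genes. The **PIDC**
score adds per-gene network context: a Gamma (or Gaussian) CDF `F_X` is
fitted to each gene's n − 1 PUC scores and an edge's confidence is

    c = F_X(u_XY) + F_Y(u_XY)  ∈ [0, 2],

which picks out each gene's most important partners. Relevance networks
(raw MI), CLR (per-gene MI z-scores) and ARACNE (data-processing-inequality
pruning) are provided as baselines; all algorithms consume the same
discretized data (Bayesian-blocks adaptive bins by default) and the same
entropy estimator (maximum likelihood by default; Miller–Madow, Dirichlet
and James–Stein shrinkage are available).

Everything is pure Python on numpy/scipy/pandas, with the Gillespie
simulation kernels JIT-compiled by numba. Inference algorithms are
scikit-learn-style estimators (`PIDCNetwork().fit(X)` with `X` of shape
`(n_cells, n_genes)`); module-level functions accept the genes × cells
orientation used by expression files.

## Worked example

Simulate snapshot data from a known 5-gene circuit, infer a network, and
score it against the generating topology:

```python
from pidc import (CircuitTopology, MassActionParams, simulate_mass_action,
                  sample_cells, pidc_network, GoldStandardNetwork, pr_and_roc)

topo = CircuitTopology(5, ((0, 1, "activate"), (1, 2, "activate"),
                           (0, 3, "inhibit")))
ens = simulate_mass_action(topo, MassActionParams.benchmark(),
                           repeats=100, seed=11, rotate_stimulus=True)
data = sample_cells(ens, scheme="medium", seed=11)   # 5 genes x 700 cells

ranked = pidc_network(data)
for e in ranked.edges[:5]:
    print(f"{e.gene_a}\t{e.gene_b}\t{e.score:.3f}")
aupr, auroc, _ = pr_and_roc(ranked, GoldStandardNetwork.from_topology(topo))
print(f"AUPR = {aupr:.3f}   AUROC = {auroc:.3f}")
```

Output:

```
G1      G2      1.845
G1      G4      1.646
G2      G4      1.293
G4      G5      1.234
G2      G3      1.064
AUPR = 0.867   AUROC = 0.905
```

The two strongest edges are true regulatory links (G1→G2, G1→G4); the
third, G2–G4, is a co-regulation artefact — both genes respond to G1 —
which is exactly the kind of indirect dependency that makes network
inference hard. The true edge G2–G3 is recovered in fifth place, and the
ranking as a whole scores AUPR 0.867 against the known circuit.

The same pipeline is available from the shell:

```bash
pidc simulate --model mass_action --topology topo.json --scheme medium \
     --seed 11 -o matrix.tsv --gold-out gold.tsv
pidc infer matrix.tsv --algorithm pidc > edges.tsv
pidc evaluate edges.tsv gold.tsv
pidc pid matrix.tsv G2 G1 G3      # one triplet decomposition
```

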