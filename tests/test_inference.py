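import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from pidc.inference import (
    AracneNetwork,
    PIDCNetwork,
    PUCNetwork,
    RankedEdgeList,
    RelevanceNetwork,
    aracne_network,
    clr_network,
    fit_gene_distribution,
    infer_network,
    mi_matrix,
    pidc_network,
    puc_matrix,
    relevance_network,
    threshold_top_percent,
)
from pidc.probability import entropy, joint_counts


@pytest.fixture
def copy_pair_data(rng):
    """3 genes: G1 = G2 exactly, G3 independent noise (genes x cells)."""
    g1 = rng.normal(size=300)
    g3 = rng.normal(size=300)
    return pd.DataFrame([g1, g1.copy(), g3], index=["G1", "G2", "G3"])


class TestMIMatrix:
    def test_duplicated_gene_dominates_and_equals_entropy(self, copy_pair_data):
        mi = mi_matrix(copy_pair_data, discretizer="uniform_width", n_bins=4)
        off = mi.to_numpy()[~np.eye(3, dtype=bool)]
        assert mi.loc["G1", "G2"] == off.max()
        labels = np.digitize(copy_pair_data.loc["G1"],
                             np.histogram_bin_edges(copy_pair_data.loc["G1"], 4)[1:-1])
        h = entropy(joint_counts(labels) / 300)
        assert mi.loc["G1", "G2"] == pytest.approx(h, abs=1e-9)

    def test_zero_variance_gene_rejected_by_name(self, rng):
        data = pd.DataFrame([rng.normal(size=50), np.zeros(50)],
                            index=["Gok", "Gflat"])
        with pytest.raises(ValueError, match="Gflat"):
            mi_matrix(data)

    def test_permutation_equivariance(self, copy_pair_data):
        mi = mi_matrix(copy_pair_data, discretizer="uniform_width")
        perm = ["G3", "G1", "G2"]
        mi_p = mi_matrix(copy_pair_data.loc[perm], discretizer="uniform_width")
        pd.testing.assert_frame_equal(mi.loc[perm, perm], mi_p)

    def test_symmetric_nonnegative_zero_diagonal(self, copy_pair_data):
        mi = mi_matrix(copy_pair_data).to_numpy()
        assert np.allclose(mi, mi.T)
        assert (mi >= 0).all() and np.all(np.diag(mi) == 0)


class TestRankedEdgeList:
    def test_deterministic_tie_break_is_lexicographic(self):
        m = np.ones((3, 3))
        ranked = RankedEdgeList.from_score_matrix(["b", "a", "c"], m)
        assert [(e.gene_a, e.gene_b) for e in ranked] == \
            [("a", "b"), ("a", "c"), ("b", "c")]

    def test_rejects_duplicates_and_self_edges(self):
        from pidc.inference import Edge
        with pytest.raises(ValueError):
            RankedEdgeList(("a", "b"), (Edge("a", "a", 1.0),))
        with pytest.raises(ValueError):
            RankedEdgeList(("a", "b"), (Edge("a", "b", 1.0), Edge("a", "b", 0.5)))


class TestRelevance:
    def test_top_edge_is_max_mi(self, copy_pair_data):
        mi = mi_matrix(copy_pair_data)
        ranked = relevance_network(mi)
        assert (ranked.edges[0].gene_a, ranked.edges[0].gene_b) == ("G1", "G2")

    def test_rank_order_invariant_to_monotone_transform(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        r1 = relevance_network(pd.DataFrame(m))
        r2 = relevance_network(pd.DataFrame(m ** 3))
        assert [(e.gene_a, e.gene_b) for e in r1] == [(e.gene_a, e.gene_b) for e in r2]


class TestCLR:
    def test_constant_row_gene_contributes_zero(self):
        m = np.array([[0, .5, .5, .5],
                      [.5, 0, .2, .9],
                      [.5, .2, 0, .4],
                      [.5, .9, .4, 0]])
        ranked = clr_network(pd.DataFrame(m, index=list("abcd"), columns=list("abcd")))
        scores = {(e.gene_a, e.gene_b): e.score for e in ranked}
        # gene 'a' has a constant MI row: its z-contribution is 0 everywhere,
        # so its edges score only through the partner's z
        za = [scores[("a", g)] for g in "bcd"]
        assert all(s >= 0 for s in za)
        zb = np.maximum(0, (m[1, [0, 2, 3]] - m[1, [0, 2, 3]].mean())
                        / m[1, [0, 2, 3]].std())
        assert scores[("a", "b")] == pytest.approx(abs(zb[0]))

    def test_agrees_with_relevance_on_dominant_pair(self, rng):
        m = np.full((4, 4), 0.1) + rng.uniform(0, .02, (4, 4))
        m = (m + m.T) / 2
        m[0, 1] = m[1, 0] = 2.0
        np.fill_diagonal(m, 0)
        genes = list("abcd")
        top_clr = clr_network(pd.DataFrame(m, index=genes, columns=genes)).edges[0]
        top_rel = relevance_network(pd.DataFrame(m, index=genes, columns=genes)).edges[0]
        assert (top_clr.gene_a, top_clr.gene_b) == (top_rel.gene_a, top_rel.gene_b)


class TestAracne:
    def test_weakest_triangle_edge_pruned_on_chain(self, rng):
        n = 4000
        x = rng.integers(0, 2, n)
        y = np.where(rng.random(n) < 0.15, 1 - x, x)
        z = np.where(rng.random(n) < 0.15, 1 - y, y)
        data = pd.DataFrame(np.array([x, y, z], dtype=float) +
                            rng.normal(0, 1e-3, (3, n)),
                            index=["X", "Y", "Z"])
        mi = mi_matrix(data, discretizer="uniform_width", n_bins=2)
        ranked = aracne_network(mi, tau=0.05)
        scores = {(e.gene_a, e.gene_b): e.score for e in ranked}
        assert scores[("X", "Z")] == 0.0
        assert scores[("X", "Y")] > 0 and scores[("Y", "Z")] > 0

    def test_tau_near_one_disables_pruning(self, rng):
        m = np.abs(rng.normal(size=(4, 4)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ranked = aracne_network(pd.DataFrame(m), tau=0.999999)
        assert all(e.score > 0 for e in ranked)

    def test_two_gene_matrix_unchanged(self):
        m = pd.DataFrame([[0, .3], [.3, 0]], index=["a", "b"], columns=["a", "b"])
        ranked = aracne_network(m)
        assert ranked.edges[0].score == pytest.approx(0.3)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            aracne_network(np.zeros((3, 3)), tau=1.0)


class TestPUC:
    def test_identical_pair_with_noise_genes_saturates(self, rng):
        """G1 = G2, all other genes independent: every unique/MI ratio is ~1
        so u = 2 (n - 2)."""
        n_genes, n_cells = 5, 400
        g = rng.normal(size=n_cells)
        rows = [g, g.copy()] + [rng.normal(size=n_cells) for _ in range(n_genes - 2)]
        data = pd.DataFrame(rows, index=[f"G{i+1}" for i in range(n_genes)])
        u = puc_matrix(data, discretizer="uniform_width", n_bins=3)
        assert u.loc["G1", "G2"] == pytest.approx(2 * (n_genes - 2), rel=0.05)

    def test_bounds_and_symmetry(self, rng):
        data = pd.DataFrame(rng.normal(size=(6, 200)))
        u = puc_matrix(data, discretizer="uniform_width", n_bins=3).to_numpy()
        assert np.allclose(u, u.T)
        assert (u >= 0).all()
        assert (u <= 2 * (6 - 2) + 1e-6).all()

    def test_zero_mi_pair_contributes_nothing(self):
        # G1, G2 exactly independent (balanced design): MI = 0 -> 0/0 := 0
        x = np.repeat([0.0, 0.0, 1.0, 1.0], 25)
        y = np.tile([0.0, 1.0], 50)
        z = np.arange(100.0)
        data = pd.DataFrame([x, y, z], index=["G1", "G2", "G3"])
        u = puc_matrix(data, discretizer="uniform_width", n_bins=2)
        assert np.isfinite(u.to_numpy()).all()
        assert u.loc["G1", "G2"] == 0.0

    def test_requires_three_genes(self, rng):
        with pytest.raises(ValueError):
            puc_matrix(pd.DataFrame(rng.normal(size=(2, 50))))


class TestGeneScoreDistribution:
    def test_equal_scores_fall_back_to_step_cdf(self):
        dist = fit_gene_distribution(np.full(5, 2.0), family="gamma")
        assert dist.family == "gaussian"
        assert dist.cdf(1.9) == 0.0 and dist.cdf(2.0) == 1.0

    def test_gaussian_median_is_half(self):
        dist = fit_gene_distribution(np.array([1.0, 2, 3, 4]), family="gaussian")
        assert dist.cdf(2.5) == pytest.approx(0.5)

    def test_gamma_moment_fit_recovers_shape(self):
        draws = stats.gamma.rvs(a=3, scale=2, size=500,
                                random_state=np.random.default_rng(0))
        dist = fit_gene_distribution(draws, family="gamma")
        assert dist.family == "gamma"
        assert dist.params["shape"] == pytest.approx(3, rel=0.25)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            fit_gene_distribution(np.array([1.0]))


class TestPIDC:
    def test_copy_pair_tops_ranking(self, copy_pair_data):
        ranked = pidc_network(copy_pair_data, discretizer="uniform_width", n_bins=4)
        top = ranked.edges[0]
        assert (top.gene_a, top.gene_b) == ("G1", "G2")

    def test_confidence_in_zero_two_range(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 150)))
        ranked = pidc_network(data, discretizer="uniform_width", n_bins=3)
        for e in ranked:
            assert 0.0 <= e.score <= 2.0

    def test_cell_permutation_invariance(self, rng, copy_pair_data):
        perm = rng.permutation(copy_pair_data.shape[1])
        r1 = pidc_network(copy_pair_data, discretizer="uniform_width", n_bins=4)
        r2 = pidc_network(copy_pair_data.iloc[:, perm],
                          discretizer="uniform_width", n_bins=4)
        assert r1.edges == r2.edges

    def test_pair_maximal_for_both_genes_attains_top_confidence(self, rng):
        """If one pair's PUC is the largest score in both its genes'
        distributions, monotone CDFs force it to the top of the ranking."""
        n_cells = 500
        g = rng.normal(size=n_cells)
        data = pd.DataFrame([g, g + rng.normal(0, 0.1, n_cells),
                             rng.normal(size=n_cells), rng.normal(size=n_cells)],
                            index=["A", "B", "C", "D"])
        u = puc_matrix(data, discretizer="uniform_width", n_bins=3)
        assert u.loc["A", "B"] == u.loc["A"].drop("A").max()
        assert u.loc["A", "B"] == u.loc["B"].drop("B").max()
        ranked = pidc_network(data, discretizer="uniform_width", n_bins=3)
        assert {ranked.edges[0].gene_a, ranked.edges[0].gene_b} == {"A", "B"}


class TestThresholdTopPercent:
    def test_full_percent_is_identity(self, rng):
        ranked = _random_ranking(rng, 6)
        assert threshold_top_percent(ranked, 100).edges == ranked.edges

    def test_ceil_of_possible_edges(self, rng):
        ranked = _random_ranking(rng, 50)
        assert len(threshold_top_percent(ranked, 2.5)) == 31  # ceil(.025 * 1225)
        assert len(threshold_top_percent(_random_ranking(rng, 10), 1e-4)) == 1

    def test_percent_bounds(self, rng):
        ranked = _random_ranking(rng, 4)
        for bad in (0, -1, 101):
            with pytest.raises(ValueError):
                threshold_top_percent(ranked, bad)


def _random_ranking(rng, n):
    m = np.abs(rng.normal(size=(n, n)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return RankedEdgeList.from_score_matrix([f"G{i:02d}" for i in range(n)], m)


class TestSklearnAPI:
    @pytest.mark.parametrize("cls", [RelevanceNetwork, AracneNetwork,
                                     PUCNetwork, PIDCNetwork])
    def test_clone_and_fitted_attributes(self, cls, rng):
        est = cls(discretizer="uniform_width", n_bins=3)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        X = rng.normal(size=(120, 4))
        est.fit(X)
        assert est.mi_matrix_.shape == (4, 4)
        assert est.scores_.shape == (4, 4)
        assert len(est.ranked_edges_) == 6

    def test_set_params_roundtrip(self):
        est = PIDCNetwork()
        est.set_params(edge_distribution="gaussian", estimator="dirichlet")
        assert est.get_params()["edge_distribution"] == "gaussian"

    def test_determinism_across_runs(self, rng):
        X = rng.normal(size=(100, 5))
        r1 = PIDCNetwork(discretizer="uniform_width").fit(X).ranked_edges_
        r2 = PIDCNetwork(discretizer="uniform_width").fit(X.copy()).ranked_edges_
        assert r1 == r2

    def test_pidc_networks_better_connected_than_mi(self):
        """At a fixed top-percent threshold, per-gene context spreads edges
        across nodes, so PIDC connects at least as many nodes as raw MI
        (averaged over simulated circuits)."""
        from pidc.evaluation import GoldStandardNetwork
        from pidc.simulate import (MassActionParams, random_dag, sample_cells,
                                   simulate_mass_action)
        fractions = {"pidc": [], "mi": []}
        for seed in range(3):
            topo = random_dag(10, mean_degree=2.0, seed=seed)
            ens = simulate_mass_action(topo, MassActionParams.benchmark(),
                                       repeats=100, seed=seed,
                                       rotate_stimulus=True)
            data = sample_cells(ens, "medium", seed=seed)
            for algo in fractions:
                top = threshold_top_percent(
                    infer_network(data, algorithm=algo), 20)
                touched = {g for e in top for g in (e.gene_a, e.gene_b)}
                fractions[algo].append(len(touched) / 10)
        assert np.mean(fractions["pidc"]) >= np.mean(fractions["mi"])

    def test_infer_network_dispatch(self, copy_pair_data):
        for algo in ("mi", "clr", "aracne", "puc", "pidc"):
            ranked = infer_network(copy_pair_data, algorithm=algo,
                                   discretizer="uniform_width", n_bins=4)
            assert len(ranked) == 3
        with pytest.raises(ValueError):
            infer_network(copy_pair_data, algorithm="mrnet")
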