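import itertools

import networkx as nx
import numpy as np
import pytest

from topnet.ggin import (
    GGINConfig,
    StateNetwork,
    aggregate_gene_stats,
    build_network,
    clustering_coefficient,
    degree_cc_profile,
    mean_degree,
    pearson_p,
    power_law_exponent,
    subsample_ensemble,
    summarize_network,
)
from topnet.io_formats import ExpressionStudy, PPIGraph


def _net(edges, state="S", sub=0):
    net = StateNetwork(state=state, subsample_id=sub)
    for a, b in edges:
        net.add_edge(a, b, 0.9, 0.001)
    return net


class TestPearsonP:
    def test_identical_vectors(self):
        a = np.arange(8, dtype=float)
        edge = pearson_p(a, a)
        assert edge.r == pytest.approx(1.0)
        assert edge.p == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_vectors_give_p_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(8)
        b = rng.standard_normal(8)
        a0 = a - a.mean()
        b_perp = (b - b.mean()) - np.dot(b - b.mean(), a0) / np.dot(a0, a0) * a0
        edge = pearson_p(a, b_perp + 5.0)
        assert edge.r == pytest.approx(0.0, abs=1e-12)
        assert edge.p == pytest.approx(1.0, abs=1e-10)

    def test_t_based_p_matches_permutation_oracle(self):
        # oracle: 10,000-permutation null of the same statistic at n=8
        rng = np.random.default_rng(42)
        a = rng.standard_normal(8)
        b = 0.8 * a + 0.6 * rng.standard_normal(8)
        t_edge = pearson_p(a, b, method="t")
        perm_edge = pearson_p(a, b, method="permutation", n_permutations=10000, seed=1)
        assert abs(t_edge.p - perm_edge.p) <= 0.01

    def test_short_vectors_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_p(np.ones(2), np.ones(2))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_p(np.ones(8), np.arange(8.0))

    def test_scipy_agreement(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        edge = pearson_p(a, b)
        r_ref, p_ref = stats.pearsonr(a, b)
        assert edge.r == pytest.approx(r_ref)
        assert edge.p == pytest.approx(p_ref)


def _study_from_values(values, state="X"):
    genes = [chr(ord("A") + i) for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionStudy(
        genes=genes,
        samples=samples,
        values=values,
        design={s: state for s in samples},
    )


class TestBuildNetwork:
    def test_identical_profiles_with_ppi_edge_kept(self):
        v = np.tile(np.arange(8.0), (2, 1))
        v[1] += 0.001 * np.arange(8)  # perfectly monotone pair, r ~ 1
        study = _study_from_values(v)
        net = build_network(study, PPIGraph(edges={("A", "B")}), GGINConfig())
        assert ("A", "B") in net.edges

    def test_no_ppi_edge_means_no_network_edge(self):
        v = np.tile(np.arange(8.0), (2, 1))
        study = _study_from_values(v + 0.001 * np.random.default_rng(0).random((2, 8)))
        net = build_network(study, PPIGraph(edges=set()), GGINConfig())
        assert net.n_edges == 0

    def test_matches_exhaustive_pair_scan(self):
        # oracle: brute-force all-pairs Pearson filter restricted to PPI edges
        rng = np.random.default_rng(11)
        values = rng.standard_normal((5, 8))
        values[1] = values[0] + 0.1 * rng.standard_normal(8)
        values[3] = -values[2] + 0.1 * rng.standard_normal(8)
        study = _study_from_values(values)
        ppi = PPIGraph(
            edges={("A", "B"), ("C", "D"), ("A", "E"), ("B", "C"), ("D", "E")}
        )
        cfg = GGINConfig(p0=0.05)
        net = build_network(study, ppi, cfg)
        expected = set()
        for ga, gb in itertools.combinations(study.genes, 2):
            edge = pearson_p(study.gene_row(ga), study.gene_row(gb))
            key = (ga, gb) if ga < gb else (gb, ga)
            if edge.p <= cfg.p0 and key in ppi.edges:
                expected.add(key)
        assert set(net.edges) == expected

    def test_too_few_arrays_errors(self):
        study = _study_from_values(np.random.default_rng(0).random((3, 2)))
        with pytest.raises(ValueError, match="3 arrays"):
            build_network(study, PPIGraph(edges={("A", "B")}), GGINConfig())

    def test_every_edge_is_ppi_edge(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        sub = study.subset_samples(study.state_samples("CRC")[:8])
        net = build_network(sub, ppi, GGINConfig())
        assert set(net.edges) <= ppi.edges

    def test_edge_monotone_in_p0(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        sub = study.subset_samples(study.state_samples("CRC")[:8])
        nets = {
            p0: set(build_network(sub, ppi, GGINConfig(p0=p0)).edges)
            for p0 in (0.001, 0.01, 0.05)
        }
        assert nets[0.001] <= nets[0.01] <= nets[0.05]

    def test_edges_grow_along_state_sequence(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        cfg = GGINConfig(n_subsamples=20, seed=1)
        means = []
        for st in ["Nor", "Ade", "CRC"]:
            ens = subsample_ensemble(study, st, ppi, cfg)
            means.append(np.mean([n.n_edges for n in ens]))
        assert means[0] <= means[1] <= means[2]


class TestSubsampleEnsemble:
    def test_exact_size_state_gives_single_network(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        ens = subsample_ensemble(study, "Nor", ppi, GGINConfig())
        assert len(ens) == 1

    def test_larger_state_gives_n_subsamples(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        ens = subsample_ensemble(study, "Ade", ppi, GGINConfig(n_subsamples=10))
        assert len(ens) == 10

    def test_seeded_reproducibility(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        cfg = GGINConfig(n_subsamples=5, seed=9)
        e1 = subsample_ensemble(study, "Ade", ppi, cfg)
        e2 = subsample_ensemble(study, "Ade", ppi, cfg)
        for a, b in zip(e1, e2):
            assert a.edges == b.edges

    def test_absent_state_errors(self, paper_shaped_fixture):
        study, ppi, _ = paper_shaped_fixture
        with pytest.raises(KeyError):
            subsample_ensemble(study, "XXX", ppi, GGINConfig())


class TestClusteringCoefficient:
    def test_triangle_vertex(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "C")])
        assert clustering_coefficient(net, "A") == 1.0

    def test_star_center(self):
        net = _net([("Z", x) for x in "ABCD"])
        assert clustering_coefficient(net, "Z") == 0.0

    def test_degree_one_convention(self):
        net = _net([("A", "B")])
        assert clustering_coefficient(net, "A") == 0.0

    def test_absent_gene_errors(self):
        net = _net([("A", "B")])
        with pytest.raises(KeyError):
            clustering_coefficient(net, "Q")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_graphs(self, seed):
        # oracle: triple loop over neighbor pairs
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        net = _net([(f"N{u}", f"N{v}") for u, v in g.edges()])
        for gene in net.nodes:
            nbrs = sorted(net.neighbors(gene))
            k = len(nbrs)
            e = sum(
                1
                for i in range(k)
                for j in range(i + 1, k)
                if nbrs[j] in net.neighbors(nbrs[i])
            )
            expected = 0.0 if k < 2 else 2 * e / (k * (k - 1))
            assert clustering_coefficient(net, gene) == pytest.approx(expected)

    def test_matches_networkx(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        net = _net([(f"N{u}", f"N{v}") for u, v in g.edges()])
        ref = nx.clustering(g)
        for u in g.nodes():
            if f"N{u}" in net:
                assert clustering_coefficient(net, f"N{u}") == pytest.approx(ref[u])


class TestSummarizeNetwork:
    @pytest.mark.parametrize(
        "n_nodes,n_edges,expected",
        [(1436, 1215, 1.69), (1801, 2281, 2.53), (2478, 3457, 2.79), (2318, 4988, 4.30)],
    )
    def test_mean_degree_identity(self, n_nodes, n_edges, expected):
        assert round(mean_degree(n_nodes, n_edges), 2) == expected

    def test_power_law_exact_line(self):
        # counts 1000*k^-2 at k in {1,2,5,10} are exact integers on the line
        degrees = []
        for k, c in [(1, 1000), (2, 250), (5, 40), (10, 10)]:
            degrees += [k] * c
        assert power_law_exponent(degrees) == pytest.approx(-2.0, abs=1e-10)

    def test_summary_fields(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")])
        s = summarize_network(net)
        assert s.n_nodes == 5
        assert s.n_edges == 4
        assert s.mean_degree == pytest.approx(2 * 4 / 5)
        assert s.mean_clustering == pytest.approx(3 / 5)
        assert s.giant_component_size == 3

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            summarize_network(StateNetwork(state="S"))


class TestAggregateGeneStats:
    def test_single_network_passthrough(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "C")])
        stats = {s.gene: s for s in aggregate_gene_stats([net], ["A", "B", "C", "D"])}
        assert stats["A"].D == 2.0
        assert stats["A"].C == 1.0
        assert stats["A"].presence_fraction == 1.0

    def test_absent_gene_zero(self):
        net = _net([("A", "B")])
        stats = {s.gene: s for s in aggregate_gene_stats([net], ["A", "B", "Z"])}
        assert stats["Z"].D == 0.0
        assert stats["Z"].C == 0.0
        assert stats["Z"].presence_fraction == 0.0

    def test_mean_over_three_networks(self):
        nets = [
            _net([("A", "B"), ("A", "C")], sub=0),  # degree 2
            _net([("A", "B"), ("A", "C"), ("A", "D"), ("A", "E")], sub=1),  # degree 4
            _net([("B", "C")], sub=2),  # absent -> 0
        ]
        stats = {s.gene: s for s in aggregate_gene_stats(nets, ["A"])}
        assert stats["A"].D == pytest.approx(2.0)
        assert stats["A"].presence_fraction == pytest.approx(2 / 3)

    def test_median_and_single_modes(self):
        nets = [
            _net([("A", "B"), ("A", "C")], sub=0),
            _net([("A", "B"), ("A", "C"), ("A", "D"), ("A", "E")], sub=1),
            _net([("B", "C")], sub=2),
        ]
        med = {s.gene: s for s in aggregate_gene_stats(nets, ["A"], aggregate="median")}
        assert med["A"].D == 2.0
        one = {
            s.gene: s
            for s in aggregate_gene_stats(nets, ["A"], aggregate="single_network")
        }
        assert one["A"].D == 2.0

    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError):
            aggregate_gene_stats([], ["A"])


class TestDegreeCCProfile:
    def test_triangle_all_at_k2_c1(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "C")])
        df = degree_cc_profile([net])
        assert len(df) == 1
        row = df.iloc[0]
        assert row["degree"] == 2
        assert row["c_low"] < 1.0 <= row["c_high"]
        assert row["percent"] == pytest.approx(100.0)

    def test_degree_two_c_zero_or_one(self):
        # path A-B-C: B has k=2, C=0; triangle gives C=1
        net = _net([("A", "B"), ("B", "C")])
        assert clustering_coefficient(net, "B") in (0.0, 1.0)

    def test_percentages_sum_to_100(self):
        g = nx.gnp_random_graph(25, 0.2, seed=1)
        net = _net([(f"N{u}", f"N{v}") for u, v in g.edges()])
        df = degree_cc_profile([net])
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_degree_one_excluded(self):
        net = _net([("A", "B"), ("B", "C")])  # A and C have degree 1
        df = degree_cc_profile([net])
        assert (df["degree"] >= 2).all()
        assert df["percent"].sum() == pytest.approx(100.0)
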