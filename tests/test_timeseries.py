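import numpy as np
import pytest

from microstm.io_prep import build_design_matrix
from microstm.stm_core import StmConfig, fit_stm
from microstm.synthetic import generate_regime_timeseries, generate_stm_dataset
from microstm.timeseries import (
    CorrelationGraph, EventTimeline, cluster_day_frequencies, detect_events,
    hierarchical_cluster, taxa_by_cluster, topic_correlation_graph,
)
from conftest import match_topics


def _manual_graph(fit, clusters, singletons):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(fit.K))
    for c in clusters:
        for a, b in zip(c[:-1], c[1:]):
            g.add_edge(a, b, weight=0.5)
    return CorrelationGraph(graph=g, cutoff=0.05, clusters=[sorted(c) for c in clusters],
                            singletons=sorted(singletons))


class TestCorrelationGraph:
    def test_independent_topics_yield_no_edges(self):
        ds = generate_stm_dataset(120, 60, 3, sigma=0.5 * np.eye(2), seed=0,
                                  library_sizes=np.full(120, 2000))
        fit = fit_stm(ds.table, None, StmConfig(K=3, seed=0))
        g = topic_correlation_graph(fit, cutoff=0.05, n_draws=200, seed=0)
        assert g.graph.number_of_edges() == 0
        assert g.singletons == [0, 1, 2]

    def test_planted_blocks_recovered(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = S[2, 3] = S[3, 2] = 0.85
        S *= 1.5
        ds = generate_stm_dataset(250, 100, 5, sigma=S, seed=101,
                                  library_sizes=np.full(250, 3000))
        fit = fit_stm(ds.table, None, StmConfig(K=5, seed=1))
        true_to_fit, _ = match_topics(fit.beta, ds.beta)
        fit_to_true = {v: k for k, v in true_to_fit.items()}
        g = topic_correlation_graph(fit, cutoff=0.05, n_draws=200, seed=1)
        parts = sorted(sorted(fit_to_true[t] for t in c) for c in g.clusters)
        assert parts == [[0, 1], [2, 3]]
        assert [fit_to_true[t] for t in g.singletons] == [4]

    def test_symmetric_and_no_self_loops(self, planted_dataset):
        _, _, fit = planted_dataset
        g = topic_correlation_graph(fit, n_draws=100, seed=2)
        assert not any(u == v for u, v in g.graph.edges())
        for u, v, w in g.edge_list():
            assert 0.05 < w <= 1

    def test_invalid_cutoff_errors(self, planted_dataset):
        _, _, fit = planted_dataset
        with pytest.raises(ValueError):
            topic_correlation_graph(fit, cutoff=1.0)


class TestClusterTimeline:
    def test_single_cluster_has_frequency_one(self, tiny_fit):
        g = _manual_graph(tiny_fit, clusters=[[0, 1]], singletons=[])
        tl = cluster_day_frequencies(tiny_fit, g, np.array([1.0, 2.0]),
                                     n_draws=50, seed=0)
        np.testing.assert_allclose(tl.mean, 1.0, atol=1e-12)
        np.testing.assert_allclose(tl.upper - tl.lower, 0.0, atol=1e-12)

    def test_per_day_means_sum_to_one(self, planted_dataset):
        _, _, fit = planted_dataset
        g = _manual_graph(fit, clusters=[[0, 1]], singletons=[2])
        day = np.arange(fit.M, dtype=float) % 10
        tl = cluster_day_frequencies(fit, g, day, n_draws=50, seed=1)
        np.testing.assert_allclose(tl.mean.sum(axis=1), 1.0, atol=1e-6)

    def test_cluster_frequency_is_linear_image_of_theta(self, tiny_fit):
        # degenerate posterior: the per-day mean equals the exact sum of
        # member-topic frequencies
        g = _manual_graph(tiny_fit, clusters=[], singletons=[0, 1])
        tl = cluster_day_frequencies(tiny_fit, g, np.array([1.0, 2.0]),
                                     n_draws=20, seed=2)
        np.testing.assert_allclose(tl.mean[:, 0], tiny_fit.theta.sum(axis=1),
                                   atol=1e-12)

    def test_missing_day_errors(self, tiny_fit):
        g = _manual_graph(tiny_fit, clusters=[[0, 1]], singletons=[])
        with pytest.raises(ValueError, match="day"):
            cluster_day_frequencies(tiny_fit, g, np.array([1.0, np.nan]))


class TestEventDetection:
    def _timeline(self, means, labels=None):
        means = np.asarray(means, dtype=float)
        labels = labels or [f"cluster{j+1}" for j in range(means.shape[1])]
        return EventTimeline(days=np.arange(1.0, means.shape[0] + 1),
                             labels=labels, mean=means, lower=means,
                             upper=means, level=0.8, n_draws=1)

    def test_constant_dominant_no_events(self):
        tl = self._timeline([[0.8, 0.2]] * 5)
        assert detect_events(tl) == []

    def test_single_switch_detected_exactly(self):
        tl = self._timeline([[0.8, 0.2]] * 4 + [[0.2, 0.8]] * 4)
        assert detect_events(tl) == [5.0]

    def test_low_dominance_days_inherit(self):
        tl = self._timeline([[0.8, 0.2], [0.45, 0.4], [0.8, 0.2], [0.1, 0.9]])
        assert detect_events(tl) == [4.0]

    def test_relabeling_invariance(self):
        means = np.array([[0.8, 0.2]] * 3 + [[0.2, 0.8]] * 3)
        tl = self._timeline(means)
        tl_swapped = self._timeline(means[:, ::-1], labels=["cluster2", "cluster1"])
        assert detect_events(tl) == detect_events(tl_swapped)

    def test_empty_timeline_errors(self):
        tl = EventTimeline(days=np.array([]), labels=[], mean=np.empty((0, 0)),
                           lower=np.empty((0, 0)), upper=np.empty((0, 0)),
                           level=0.8, n_draws=1)
        with pytest.raises(ValueError):
            detect_events(tl)

    def test_planted_two_switch_recovered(self):
        ds = generate_regime_timeseries(
            120, [50, 90], seed=3,
            cluster_topic_map={"a": [0, 1], "b": [2, 3], "c": [4, 5]})
        X = build_design_matrix(ds.table.metadata, [("day", ("bspline", 10))])
        fit = fit_stm(ds.table, X, StmConfig(K=ds.params["K"], seed=3))
        g = topic_correlation_graph(fit, n_draws=200, seed=3)
        day = ds.table.metadata["day"].to_numpy(float)
        tl = cluster_day_frequencies(fit, g, day, n_draws=100, seed=4)
        ev = detect_events(tl)
        for d in (50, 90):
            assert any(abs(e - d) <= 2 for e in ev)


class TestTaxaByCluster:
    def test_single_topic_cluster_matches_collapsed_beta(self, tiny_fit):
        taxonomy = {"A": ("B", "p", "c", "o", "F1", "g", "s"),
                    "B": ("B", "p", "c", "o", "F2", "g", "s"),
                    "C": ("B", "p", "c", "o", "F2", "g", "s")}
        # point-mass theta on topic 0: cluster {0} receives all tokens
        tiny_fit.eta_mean[:] = 30.0
        tiny_fit.theta[:] = [1.0, 0.0]
        g = _manual_graph(tiny_fit, clusters=[[0], [1]], singletons=[])
        freq = taxa_by_cluster(tiny_fit, g, taxonomy, rank="family",
                               n_draws=20, tokens_per_draw=2500, seed=0)
        expected_f1 = tiny_fit.beta[0, 0]          # OTU A is the only F1 member
        assert abs(freq.loc["cluster1", "F1"] - expected_f1) < 0.01
        np.testing.assert_allclose(freq.loc["cluster1"].sum(), 1.0, atol=1e-6)

    def test_zero_token_cluster_is_nan(self, tiny_fit):
        taxonomy = {o: ("B", "p", "c", "o", "f", "g", "s") for o in "ABC"}
        tiny_fit.eta_mean[:] = 30.0
        tiny_fit.theta[:] = [1.0, 0.0]
        g = _manual_graph(tiny_fit, clusters=[[0], [1]], singletons=[])
        freq = taxa_by_cluster(tiny_fit, g, taxonomy, rank="family",
                               n_draws=5, tokens_per_draw=100, seed=1)
        assert freq.loc["cluster2"].isna().all()

    def test_unknown_rank_errors(self, tiny_fit):
        g = _manual_graph(tiny_fit, clusters=[[0, 1]], singletons=[])
        with pytest.raises(ValueError, match="rank"):
            taxa_by_cluster(tiny_fit, g, {}, rank="strain")


class TestHierarchicalClustering:
    def test_identical_rows_share_label(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]])
        lab = hierarchical_cluster(m, 2)
        assert lab[0] == lab[1] != lab[2]

    def test_bray_curtis_extremes(self):
        lab = hierarchical_cluster(np.array([[1.0, 0.0], [0.0, 1.0]]), 2)
        assert lab[0] != lab[1]

    def test_two_block_recovery(self):
        rng = np.random.default_rng(5)
        m = rng.poisson(5, (20, 30)).astype(float)
        m[:10, :15] += 50
        m[10:, 15:] += 50
        lab = hierarchical_cluster(m, 2)
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
        assert lab[0] != lab[-1]

    def test_normalized_variant_runs(self):
        rng = np.random.default_rng(6)
        m = rng.poisson(20, (12, 8)).astype(float)
        lab = hierarchical_cluster(m, 3, normalize=True)
        assert len(np.unique(lab)) == 3

    def test_negative_entries_error(self):
        with pytest.raises(ValueError, match="negative"):
            hierarchical_cluster(np.array([[1.0, -1.0], [0.0, 1.0]]), 2)

    def test_too_many_clusters_error(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.ones((2, 2)), 3)
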