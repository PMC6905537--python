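import numpy as np
import pandas as pd
import pytest

from microstm.synthetic import generate_gene_content
from microstm.topic_functions import (
    GeneContentTable, collapse_pathways, metagenome_topic_table,
    predict_functions, read_gene_content, topics_to_pseudocounts,
    write_gene_content,
)


class TestPseudocounts:
    def test_forced_arithmetic(self):
        out = topics_to_pseudocounts(np.array([[0.5, 0.3, 0.2]]), constant=10000)
        np.testing.assert_array_equal(out, [[5000, 3000, 2000]])

    def test_below_half_unit_rounds_to_zero(self):
        beta = np.array([[4e-5, 1 - 4e-5]])
        out = topics_to_pseudocounts(beta, constant=10000)
        assert out[0, 0] == 0

    def test_row_sums_within_rounding_slack(self):
        rng = np.random.default_rng(0)
        beta = rng.dirichlet(np.full(40, 0.3), size=6)
        out = topics_to_pseudocounts(beta)
        assert np.all(np.abs(out.sum(axis=1) - 10000) <= 40 / 2)

    def test_invalid_constant_errors(self):
        with pytest.raises(ValueError):
            topics_to_pseudocounts(np.array([[1.0]]), constant=0)

    def test_unnormalized_beta_errors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            topics_to_pseudocounts(np.array([[0.5, 0.4]]))


class TestPredictFunctions:
    def test_single_term_product(self):
        gc = GeneContentTable(content=np.array([[2.0]]), otu_ids=["O1"],
                              gene_ids=["K1"])
        out = predict_functions(np.array([[100]]), gc, ["O1"])
        assert out[0, 0] == 200

    def test_matches_naive_accumulation(self):
        rng = np.random.default_rng(1)
        K, V, G = 5, 8, 6
        pseudo = rng.integers(0, 500, (K, V))
        content = rng.integers(0, 4, (V, G)).astype(float)
        otus = [f"O{v}" for v in range(V)]
        gc = GeneContentTable(content=content, otu_ids=otus,
                              gene_ids=[f"K{g}" for g in range(G)])
        out = predict_functions(pseudo, gc, otus)
        naive = np.zeros((K, G))
        for k in range(K):
            for g in range(G):
                for v in range(V):
                    naive[k, g] += pseudo[k, v] * content[v, g]
        np.testing.assert_array_equal(out, naive)

    def test_zero_content_column_gives_zero(self):
        gc = GeneContentTable(content=np.array([[1.0, 0.0]]), otu_ids=["O1"],
                              gene_ids=["K1", "K2"])
        out = predict_functions(np.array([[50]]), gc, ["O1"])
        assert out[0, 1] == 0

    def test_linearity(self):
        rng = np.random.default_rng(2)
        pseudo = rng.integers(0, 100, (3, 5))
        gc = GeneContentTable(content=rng.integers(0, 3, (5, 4)).astype(float),
                              otu_ids=[f"O{v}" for v in range(5)],
                              gene_ids=[f"K{g}" for g in range(4)])
        otus = gc.otu_ids
        np.testing.assert_array_equal(predict_functions(2 * pseudo, gc, otus),
                                      2 * predict_functions(pseudo, gc, otus))

    def test_no_overlap_errors(self):
        gc = GeneContentTable(content=np.ones((1, 1)), otu_ids=["O1"], gene_ids=["K1"])
        with pytest.raises(ValueError, match="overlap"):
            predict_functions(np.array([[10]]), gc, ["OTHER"])


class TestCollapsePathways:
    def _gc(self, hierarchy):
        genes = sorted(hierarchy)
        return GeneContentTable(content=np.ones((1, len(genes))),
                                otu_ids=["O1"], gene_ids=genes,
                                hierarchy=hierarchy)

    def test_multimapped_gene_duplicates_full_count(self):
        gc = self._gc({"K1": {("M", "L2a", "L3a"), ("M", "L2a", "L3b")}})
        counts, labels, _ = collapse_pathways(np.array([[10.0]]), gc, level=3)
        assert sorted(labels) == ["L3a", "L3b"]
        np.testing.assert_array_equal(np.sort(counts[0]), [10, 10])

    def test_single_mapped_conserves_totals(self):
        rng = np.random.default_rng(3)
        gc = generate_gene_content(6, 10, multimap_prob=0.0, seed=3)
        gene_counts = rng.integers(0, 200, (4, 10)).astype(float)
        counts, labels, _ = collapse_pathways(gene_counts, gc, level=3)
        np.testing.assert_allclose(counts.sum(axis=1), gene_counts.sum(axis=1),
                                   atol=len(labels) / 2)

    def test_level2_filter_excludes_gene(self):
        gc = self._gc({"K1": {("M", "L2a", "L3a")}, "K2": {("M", "L2b", "L3b")}})
        counts, labels, _ = collapse_pathways(np.array([[5.0, 7.0]]), gc,
                                              level=3, allowed_level2={"L2a"})
        assert labels == ["L3a"]
        assert counts[0, 0] == 5

    def test_disjoint_filter_errors(self):
        gc = self._gc({"K1": {("M", "L2a", "L3a")}})
        with pytest.raises(ValueError, match="overlap"):
            collapse_pathways(np.array([[1.0]]), gc, allowed_level2={"NOPE"})

    def test_level2_collapse(self):
        gc = self._gc({"K1": {("M", "L2a", "L3a")}, "K2": {("M", "L2a", "L3b")}})
        counts, labels, _ = collapse_pathways(np.array([[5.0, 7.0]]), gc, level=2)
        assert labels == ["L2a"]
        assert counts[0, 0] == 12


class TestMetagenomeTable:
    def _fit(self, beta, otus):
        from microstm.stm_core import StmConfig, StmFit
        K = beta.shape[0]
        return StmFit(theta=np.full((2, K), 1 / K), beta=beta,
                      gamma=np.zeros((1, K - 1)), sigma=np.eye(K - 1),
                      eta_mean=np.zeros((2, K - 1)),
                      eta_cov=np.zeros((2, K - 1, K - 1)), elbo_trace=[0.0],
                      config=StmConfig(K=K), vocabulary=otus,
                      sample_ids=["s1", "s2"])

    def test_single_genus_single_ko(self):
        beta = np.array([[0.9, 0.1], [0.1, 0.9]])
        otus = ["O1", "O2"]
        tax = {"O1": ("B", "p", "c", "o", "f", "GenA", "s"),
               "O2": ("B", "p", "c", "o", "f", "GenB", "s")}
        ko = pd.DataFrame({"K1|GenA": [100.0, 50.0], "K1|GenB": [30.0, 20.0]},
                          index=["s1", "s2"])
        rec = {"K1|GenA": ("K1", "GenA"), "K1|GenB": ("K1", "GenB")}
        hier = {"K1": {("M", "L2", "L3x")}}
        fit = self._fit(beta, otus)
        y, labels, Z = metagenome_topic_table(ko, fit, tax, rec, hier, threshold=0.5)
        assert labels == ["L3x"]
        assert y[0, 0] == 150       # topic 0 keeps only GenA records
        assert y[1, 0] == 50        # topic 1 keeps only GenB records
        np.testing.assert_allclose(Z, [130.0, 70.0])

    def test_matches_naive_filter_then_sum(self):
        rng = np.random.default_rng(4)
        K, n_gen, n_ko = 3, 4, 6
        genera = [f"G{i}" for i in range(n_gen)]
        otus = [f"O{i}" for i in range(8)]
        tax = {o: ("B", "p", "c", "o", "f", genera[i % n_gen], "s")
               for i, o in enumerate(otus)}
        beta = rng.dirichlet(np.ones(8), size=K)
        recs, rec_map, hier = [], {}, {}
        for j in range(n_ko):
            ko_id = f"K{j}"
            hier[ko_id] = {("M", "L2", f"L3_{j % 3}")}
            for g in genera[: 1 + j % n_gen]:
                r = f"{ko_id}|{g}"
                recs.append(r)
                rec_map[r] = (ko_id, g)
        ko = pd.DataFrame(rng.integers(0, 300, (2, len(recs))).astype(float),
                          index=["s1", "s2"], columns=recs)
        fit = self._fit(beta, otus)
        thr = 0.1
        y, labels, Z = metagenome_topic_table(ko, fit, tax, rec_map, hier, threshold=thr)
        # naive oracle
        for k in range(K):
            hot_genera = {tax[otus[v]][5] for v in range(8) if beta[k, v] > thr}
            for c, lab in enumerate(labels):
                tot = 0.0
                for r in recs:
                    ko_id, g = rec_map[r]
                    if g in hot_genera and ("M", "L2", lab) in hier[ko_id]:
                        tot += ko[r].sum()
                assert y[k, c] == int(np.floor(tot + 0.5))

    def test_threshold_one_rejected(self):
        beta = np.array([[0.9, 0.1], [0.1, 0.9]])
        fit = self._fit(beta, ["O1", "O2"])
        with pytest.raises(ValueError):
            metagenome_topic_table(pd.DataFrame(), fit, {}, {}, {}, threshold=1.0)


class TestFileFormats:
    def test_gene_content_round_trip(self, tmp_path):
        gc = generate_gene_content(5, 7, multimap_prob=0.3, seed=5)
        write_gene_content(gc, tmp_path / "gc.tsv", hierarchy_path=tmp_path / "h.tsv")
        back = read_gene_content(tmp_path / "gc.tsv", hierarchy_path=tmp_path / "h.tsv")
        np.testing.assert_allclose(back.content, gc.content)
        assert back.gene_ids == gc.gene_ids
        assert back.hierarchy == gc.hierarchy
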