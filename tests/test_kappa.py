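"""Cohen's kappa, association edges and member-sharing clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import silscreen as ss
from silscreen.kappa import KappaEdge, cluster_ids

binary_rows = st.lists(st.integers(0, 1), min_size=2, max_size=60)


def brute_force_kappa(a, b):
    """Independent oracle: explicit 2x2 contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n11 = int(((a == 1) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    pr_a = (n11 + n00) / n
    p_a = (n11 + n10) / n
    p_b = (n11 + n01) / n
    pr_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if pr_e == 1.0:
        return 0.0
    return (pr_a - pr_e) / (1 - pr_e)


class TestCohenKappa:
    def test_worked_example(self):
        """n=10, rows 1110000000 / 1100000000: Pr(a)=0.9, Pr(e)=0.62, kappa=14/19."""
        e = ss.cohen_kappa([1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                           [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert e.pr_a == pytest.approx(0.9)
        assert e.pr_e == pytest.approx(0.62)
        assert e.kappa == pytest.approx(14 / 19)  # ~0.7368
        assert e.kappa == pytest.approx(0.7368, abs=5e-5)

    def test_identical_nonconstant_rows(self):
        assert ss.cohen_kappa([1, 0, 1], [1, 0, 1]).kappa == 1.0

    def test_fully_discordant_constant_rows(self):
        e = ss.cohen_kappa([1, 1, 1], [0, 0, 0])
        assert e.pr_a == 0.0 and e.pr_e == 0.0 and e.kappa == 0.0

    def test_identical_constant_rows_warn_and_zero(self):
        with pytest.warns(RuntimeWarning, match="Pr\\(e\\) = 1"):
            e = ss.cohen_kappa([0, 0, 0], [0, 0, 0])
        assert e.kappa == 0.0

    @given(binary_rows, st.randoms(use_true_random=False))
    def test_symmetry(self, row, rnd):
        other = [rnd.randint(0, 1) for _ in row]
        assert ss.cohen_kappa(row, other).kappa == ss.cohen_kappa(other, row).kappa

    @given(binary_rows)
    def test_self_kappa_one_for_nonconstant(self, row):
        if 0 < sum(row) < len(row):
            assert ss.cohen_kappa(row, row).kappa == 1.0

    def test_matches_sklearn_implementation(self):
        """Cross-check against sklearn's independent Cohen's kappa."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 2, 40)
            b = (a ^ (rng.random(40) < 0.3)).astype(int)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert ss.cohen_kappa(a, b).kappa == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.cohen_kappa([1, 0], [1, 0, 1])


class TestPairwiseKappa:
    @pytest.mark.parametrize("density", [0.05, 0.2, 0.5])
    def test_matches_contingency_oracle(self, density):
        rng = np.random.default_rng(int(density * 100))
        bits = (rng.random((50, 200)) < density).astype(np.uint8)
        M = ss.AnnotationMatrix([f"g{i}" for i in range(50)],
                                [f"t{j}" for j in range(200)], bits)
        K = ss.pairwise_kappa(M)
        for i, j in itertools.combinations(range(0, 50, 7), 2):
            assert K[i, j] == pytest.approx(brute_force_kappa(bits[i], bits[j]),
                                            abs=1e-12)
        assert np.allclose(K, K.T, atol=0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        bits = (rng.random((12, 30)) < 0.3).astype(np.uint8)
        M1 = ss.AnnotationMatrix([f"g{i}" for i in range(12)],
                                 [f"t{j}" for j in range(30)], bits)
        perm = rng.permutation(30)
        M2 = ss.AnnotationMatrix(M1.gene_ids, [M1.term_ids[j] for j in perm],
                                 bits[:, perm])
        assert np.array_equal(ss.pairwise_kappa(M1), ss.pairwise_kappa(M2))


class TestAssociationEdges:
    def test_planted_cluster_yields_exact_clique(self):
        M = ss.simulate_annotation_matrix(10, 50, [(range(4), range(12))], 0.0, seed=0)
        es = ss.build_association_edges(M, 0.35)
        expected = {tuple(sorted((M.gene_ids[i], M.gene_ids[j])))
                    for i, j in itertools.combinations(range(4), 2)}
        assert {(e.gene_a, e.gene_b) for e in es.edges} == expected
        assert len(es.edges) == 6

    def test_impossible_threshold_yields_no_edges(self):
        M = ss.simulate_annotation_matrix(8, 30, [(range(4), range(10))], 0.0, seed=1)
        assert ss.build_association_edges(M, 1.01).edges == []

    def test_pair_count_at_screen_scale(self):
        M = ss.simulate_annotation_matrix(266, 40, [], 0.1, seed=2)
        es = ss.build_association_edges(M)
        assert es.n_pairs == 266 * 265 // 2 == 35245

    def test_threshold_quantile_reported(self):
        M = ss.simulate_annotation_matrix(30, 100, [(range(5), range(20))], 0.05, seed=3)
        es = ss.build_association_edges(M, 0.35)
        assert 0.9 < es.threshold_quantile <= 1.0  # few associated pairs -> high quantile


def edge(a, b, k=1.0):
    return KappaEdge(a, b, 1.0, 0.0, k)


class TestIterativeCluster:
    def test_single_edge_single_cluster(self):
        cs = ss.iterative_cluster([edge("A", "B")])
        assert cs.clusters == [frozenset("AB")]

    def test_path_does_not_merge_but_triangle_does(self):
        cs = ss.iterative_cluster([edge("A", "B"), edge("B", "C")])
        assert sorted(map(sorted, cs.clusters)) == [["A", "B"], ["B", "C"]]
        cs = ss.iterative_cluster([edge("A", "B"), edge("B", "C"), edge("A", "C")])
        assert cs.clusters == [frozenset("ABC")]

    def test_invariant_under_edge_order(self):
        edges = [edge(a, b) for a, b in
                 [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E"),
                  ("C", "E"), ("F", "G")]]
        ref = ss.iterative_cluster(edges).clusters
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(edges)
            rng.shuffle(shuffled)
            assert ss.iterative_cluster(shuffled).clusters == ref

    def test_fixpoint_within_gene_count_iterations(self):
        M = ss.simulate_annotation_matrix(
            24, 120, [(range(0, 8), range(0, 30)), (range(8, 16), range(30, 60)),
                      (range(16, 24), range(60, 90))], 0.05, seed=5)
        es = ss.build_association_edges(M)
        cs = ss.iterative_cluster(es.edges)
        assert cs.n_iterations <= 24
        # merge log replays to the final state: every logged merge happened
        assert all(ev.shared_fraction > 0.5 for ev in cs.merge_log)

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            M = ss.simulate_annotation_matrix(
                40, 200, [(range(0, 8), range(0, 30)), (range(8, 16), range(30, 60)),
                          (range(16, 24), range(60, 90))], 0.05, seed=seed)
            cs = ss.iterative_cluster(ss.build_association_edges(M).edges)
            ids = cluster_ids(cs)
            label = {}
            for c, i in ids.items():
                for g in c:
                    label.setdefault(g, i)
            pred = [label.get(g, 1000 + k) for k, g in enumerate(M.gene_ids)]
            true = [i // 8 if i < 24 else 100 + i for i in range(40)]
            aris.append(adjusted_rand_score(true, pred))
        assert np.mean(aris) >= 0.9

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError):
            ss.iterative_cluster([])


class TestNetworkExport:
    def test_empty_network_writes_header(self, tmp_path):
        from silscreen.kappa import ClusterSet, export_network, read_network

        path = tmp_path / "net.tsv"
        export_network(ClusterSet([], 1, []), [], path)
        df = read_network(path)
        assert list(df.columns) == ["gene_a", "gene_b", "kappa", "cluster_id"]
        assert df.empty

    def test_round_trip_and_stable_ids(self, tmp_path):
        M = ss.simulate_annotation_matrix(
            20, 80, [(range(0, 5), range(0, 20)), (range(5, 9), range(20, 40))],
            0.02, seed=6)
        es = ss.build_association_edges(M)
        cs = ss.iterative_cluster(es.edges)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ss.export_network(cs, es.edges, p1)
        ss.export_network(cs, es.edges, p2)
        df1, df2 = pd.read_csv(p1, sep="\t"), pd.read_csv(p2, sep="\t")
        pd.testing.assert_frame_equal(df1, df2)
        graph = {(r.gene_a, r.gene_b): r.kappa for r in df1.itertuples()}
        assert graph == {(e.gene_a, e.gene_b): pytest.approx(e.kappa)
                         for e in es.edges}


class TestAnnotationMatrixIo:
    def test_dense_tsv_round_trip(self, tmp_path):
        M = ss.simulate_annotation_matrix(9, 15, [(range(3), range(5))], 0.2, seed=7)
        path = tmp_path / "annot.tsv"
        M.write_tsv(path)
        back = ss.AnnotationMatrix.read_tsv(path)
        assert back.gene_ids == M.gene_ids and back.term_ids == M.term_ids
        assert np.array_equal(back.bits, M.bits)

    def test_triplet_round_trip(self, tmp_path):
        M = ss.simulate_annotation_matrix(7, 11, [(range(3), range(4))], 0.3, seed=8)
        path = tmp_path / "annot.triplets.tsv"
        M.write_triplets(path)
        back = ss.AnnotationMatrix.read_triplets(path)
        dense = M.to_frame().loc[back.gene_ids, back.term_ids]
        assert np.array_equal(back.bits, dense.to_numpy(dtype=np.uint8))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            ss.AnnotationMatrix(["a"], ["t"], np.array([[2]]))
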