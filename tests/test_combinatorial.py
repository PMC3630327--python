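"""Binary co-occupancy matrix, correlation distance, and clustering."""

import dataclasses

import numpy as np
import pytest
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from gsca import (
    Compendium,
    DatasetInfo,
    GenomicRegion,
    PeakDataset,
    ValidationError,
    build_binary_matrix,
    build_compendium,
    build_peak_gene_map,
    hierarchical_cluster,
    map_gene_set_to_regions,
    pearson_distance,
    run_cgsca,
)
from gsca.combinatorial import BinaryOccupancyMatrix

R = GenomicRegion


def toy_compendium(occupancy: np.ndarray) -> Compendium:
    """Wrap a 0/1 matrix into a Compendium with placeholder regions."""
    occupancy = np.asarray(occupancy, dtype=np.uint8)
    n, d = occupancy.shape
    regions = [R("chr1", 10 * i, 10 * i + 5) for i in range(n)]
    infos = [DatasetInfo(f"d{j}", f"TF{j}", "ct", int(occupancy[:, j].sum())) for j in range(d)]
    return Compendium(regions, infos, occupancy)


class TestBuildBinaryMatrix:
    def test_fully_shared_regions_all_retained(self):
        comp = toy_compendium(np.ones((10, 2)))
        mat = build_binary_matrix(comp, ["d0", "d1"])
        assert mat.shape == (10, 2)
        assert (mat.values == 1).all()

    def test_single_factor_rows_excluded(self):
        occ = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]])
        comp = toy_compendium(occ)
        mat = build_binary_matrix(comp, ["d0", "d1", "d2"])
        assert mat.row_indices.tolist() == [0, 2]

    def test_restriction_to_region_subset(self):
        occ = np.array([[1, 1], [1, 1], [1, 1], [0, 1]])
        comp = toy_compendium(occ)
        mat = build_binary_matrix(comp, ["d0", "d1"], restrict_to={1, 3})
        assert mat.row_indices.tolist() == [1]

    def test_retained_rows_match_bruteforce_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n, d = int(rng.integers(2, 40)), int(rng.integers(2, 8))
            occ = (rng.random((n, d)) < 0.4).astype(np.uint8)
            occ[occ.sum(axis=1) == 0, rng.integers(0, d)] = 1  # keep rows occupied
            comp = toy_compendium(occ)
            enriched = [f"d{j}" for j in range(d)]
            expected = [i for i in range(n) if int(occ[i].sum()) >= 2]
            if not expected:
                with pytest.raises(ValidationError):
                    build_binary_matrix(comp, enriched)
                continue
            mat = build_binary_matrix(comp, enriched)
            assert mat.row_indices.tolist() == expected
            assert (mat.values.sum(axis=1) >= 2).all()

    def test_fewer_than_two_datasets_rejected(self):
        comp = toy_compendium(np.ones((3, 2)))
        with pytest.raises(ValidationError, match="need >= 2"):
            build_binary_matrix(comp, ["d0"])

    def test_no_surviving_rows_is_diagnosed(self):
        occ = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValidationError, match="single-factor"):
            build_binary_matrix(toy_compendium(occ), ["d0", "d1"])


class TestPearsonDistance:
    def test_identical_columns_at_distance_zero(self):
        X = np.array([[1, 1], [0, 0], [1, 1], [0, 0]])
        d = pearson_distance(X)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_complementary_columns_at_distance_two(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        assert pearson_distance(X)[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula_on_toy_matrix(self):
        rng = np.random.default_rng(2)
        X = (rng.random((5, 3)) < 0.5).astype(float)
        X[:, 0] = [1, 0, 1, 1, 0]  # ensure variance
        X[:, 1] = [1, 1, 0, 1, 0]
        X[:, 2] = [0, 0, 1, 0, 1]
        d = pearson_distance(X)
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i], X[:, j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                )
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_symmetric_zero_diagonal_in_range(self, demo):
        gene_set = set(demo.truth.gene_set)
        rows = sorted(map_gene_set_to_regions(gene_set, demo.pgmap))
        mat = build_binary_matrix(demo.comp, list(demo.truth.enriched), rows)
        d = pearson_distance(mat)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 2

    def test_zero_variance_column_convention(self, caplog):
        X = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]])
        with caplog.at_level("WARNING"):
            d = pearson_distance(X)
        assert "zero-variance" in caplog.text
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0 and d[0, 0] == 0.0


def naive_agglomerate(D, linkage):
    """From-scratch oracle: recompute cluster distances from member sets."""
    D = np.asarray(D, float)
    K = D.shape[0]
    clusters = {i: [i] for i in range(K)}
    next_id = K
    merges = []

    def cluster_dist(a, b):
        vals = [D[i, j] for i in clusters[a] for j in clusters[b]]
        if linkage == "average":
            return sum(vals) / len(vals)
        return max(vals) if linkage == "complete" else min(vals)

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = min(
            ((cluster_dist(a, b), a, b) for ai, a in enumerate(ids) for b in ids[ai + 1:]),
        )
        h, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, h))
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        dendro = hierarchical_cluster(D, labels=["a", "b"])
        assert dendro.merges.tolist() == [[0.0, 1.0, 0.7, 2.0]]

    def test_block_structure_merges_within_groups_first(self):
        D = np.full((4, 4), 1.5)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        dendro = hierarchical_cluster(D)
        first_two = {tuple(sorted(row[:2])) for row in dendro.merges[:2].astype(int).tolist()}
        assert first_two == {(0, 1), (2, 3)}
        assert dendro.cut_k(2) == {"0": 1, "1": 1, "2": 2, "3": 2}

    def test_ties_broken_by_lowest_index(self):
        D = np.array([
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.5],
            [0.5, 0.5, 0.0],
        ])
        dendro = hierarchical_cluster(D)
        assert dendro.merges[0, 0] == 0 and dendro.merges[0, 1] == 1

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_merge_sequence_matches_naive_oracle(self, linkage):
        rng = np.random.default_rng(31)
        for _ in range(25):
            K = int(rng.integers(2, 9))
            pts = rng.random((K, 3))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dendro = hierarchical_cluster(D, linkage=linkage)
            oracle = naive_agglomerate(D, linkage)
            got = [(int(a), int(b), h) for a, b, h, _ in dendro.merges.tolist()]
            for (ga, gb, gh), (oa, ob, oh) in zip(got, oracle):
                assert {ga, gb} == {oa, ob}
                assert gh == pytest.approx(oh, abs=1e-12)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_partitions_agree_with_scipy_on_tie_free_data(self, linkage):
        rng = np.random.default_rng(5)
        pts = rng.random((10, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dendro = hierarchical_cluster(D, linkage=linkage)
        Z = scipy_hierarchy.linkage(squareform(D, checks=False), method=linkage)
        assert np.allclose(np.sort(dendro.merges[:, 2]), np.sort(Z[:, 2]))
        for k in (2, 3, 5):
            ours = dendro.cut_k(k)
            theirs = scipy_hierarchy.fcluster(Z, t=k, criterion="maxclust")
            a = [ours[str(i)] for i in range(10)]
            assert adjusted_rand_score(a, theirs) == 1.0

    def test_merge_heights_nondecreasing(self, demo):
        gene_set = set(demo.truth.gene_set)
        rows = sorted(map_gene_set_to_regions(gene_set, demo.pgmap))
        mat = build_binary_matrix(demo.comp, list(demo.truth.enriched), rows)
        dendro = hierarchical_cluster(pearson_distance(mat), labels=mat.dataset_ids)
        h = dendro.merges[:, 2]
        assert (np.diff(h) >= -1e-12).all()

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        X = (rng.random((30, 5)) < 0.4).astype(np.uint8)
        X[:2] = 1  # avoid zero-variance edge and guarantee rows
        labels = [f"d{j}" for j in range(5)]
        base = hierarchical_cluster(pearson_distance(X), labels=labels).cut_k(2)
        perm = [3, 1, 4, 0, 2]
        Xp = X[:, perm]
        permuted = hierarchical_cluster(
            pearson_distance(Xp), labels=[labels[j] for j in perm]
        ).cut_k(2)
        grouping = lambda cl: {frozenset(d for d, c in cl.items() if c == v) for v in set(cl.values())}
        assert grouping(base) == grouping(permuted)

    def test_invalid_distance_matrices_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.array([[0.5, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.zeros((2, 2)), linkage="ward")


class TestDendrogramOutputs:
    def test_newick_contains_each_leaf_once(self, demo):
        result = run_cgsca(demo.comp, demo.pgmap, set(demo.truth.gene_set), cut_k=2)
        nwk = result.dendrogram.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
        for d in result.matrix.dataset_ids:
            assert nwk.count(d) == 1

    def test_cut_height_zero_keeps_zero_distance_merges_only(self):
        D = np.array([
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ])
        dendro = hierarchical_cluster(D, labels=["a", "b", "c"])
        assert dendro.cut_height(0.0) == {"a": 1, "b": 1, "c": 2}
        assert dendro.cut_height(1.5) == {"a": 1, "b": 1, "c": 1}

    def test_leaf_order_is_a_permutation(self, demo):
        result = run_cgsca(demo.comp, demo.pgmap, set(demo.truth.gene_set), cut_k=2)
        order = result.dendrogram.leaf_order()
        assert sorted(order) == list(range(len(result.matrix.dataset_ids)))


class TestRunCgsca:
    def test_recovers_planted_two_group_partition(self, demo):
        result = run_cgsca(demo.comp, demo.pgmap, set(demo.truth.gene_set), cut_k=2)
        truth = demo.truth.partition()
        labels = sorted(truth)
        ari = adjusted_rand_score(
            [truth[d] for d in labels], [result.clusters[d] for d in labels]
        )
        assert ari == 1.0

    def test_identical_binding_collapses_to_one_cluster_at_height_zero(self):
        shared = [R("chr1", 10_000 * i, 10_000 * i + 200) for i in range(30)]
        datasets = [PeakDataset(f"d{j}", f"TF{j}", "ct", list(shared)) for j in range(3)]
        comp = build_compendium(datasets)
        from gsca import GeneAnnotation

        genes = [GeneAnnotation("GeneA", "chr1", "+", 0, 300_000)]
        pgmap = build_peak_gene_map(comp.regions, genes)
        # all datasets bind the whole-gene locus identically: p = 1 for all,
        # so take everything into the combinatorial stage with alpha > 1
        result = run_cgsca(comp, pgmap, {"GeneA"}, alpha=1.1, cut_height=0.0)
        assert set(result.clusters.values()) == {1}
        assert np.allclose(result.dendrogram.merges[:, 2], 0.0)

    def test_too_few_significant_datasets_is_an_error(self, demo):
        with pytest.raises(ValidationError, match="combinatorial stage"):
            run_cgsca(demo.comp, demo.pgmap, set(demo.truth.gene_set), alpha=1e-30)

    def test_genome_wide_mode_runs_and_keeps_more_rows(self, demo):
        gene_set = set(demo.truth.gene_set)
        restricted = run_cgsca(demo.comp, demo.pgmap, gene_set, cut_k=2)
        genome_wide = run_cgsca(
            demo.comp, demo.pgmap, gene_set, cut_k=2, restrict_to_gene_set=False
        )
        assert genome_wide.matrix.shape[0] >= restricted.matrix.shape[0]

    def test_mixed_program_gene_set_separates_two_cell_type_patterns(self, demo):
        # The planted gene set is driven by two disjoint co-binding groups;
        # the combinatorial cut must separate them even though plain
        # enrichment flags all five datasets together.
        result = run_cgsca(demo.comp, demo.pgmap, set(demo.truth.gene_set), cut_k=2)
        groups = {
            frozenset(d for d, c in result.clusters.items() if c == v)
            for v in set(result.clusters.values())
        }
        expected = {frozenset(m) for m, _ in demo.truth.groups}
        assert groups == expected
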