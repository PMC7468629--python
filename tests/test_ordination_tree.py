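import itertools

import numpy as np
import pandas as pd
import pytest

from aimpanel import ordination_tree as ot
from aimpanel.io_formats import MISSING, GenotypeTable, read_newick, write_newick


# ---------------------------------------------------------------------------
# oracle helpers: random additive trees and their path-length metrics
# ---------------------------------------------------------------------------

def random_binary_tree(rng, n_leaves):
    """Random unrooted binary tree as an edge list with positive lengths."""
    # grow by attaching each new leaf to a random existing edge
    next_node = n_leaves  # internal ids from n_leaves upward
    edges = {}  # (u, v) -> length

    def add_edge(u, v):
        edges[(u, v)] = float(rng.uniform(0.1, 1.0))

    add_edge(0, 1)
    for leaf in range(2, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        split = float(rng.uniform(0.2, 0.8))
        mid = next_node
        next_node += 1
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        add_edge(mid, leaf)
    return edges


def path_metric(edges, n_leaves):
    """All-pairs path lengths between leaves of an edge list (Dijkstra-free:
    the graph is a tree, BFS with accumulated distance suffices)."""
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    stack.append(nxt)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    return D


class TestGenotypePca:
    def test_two_blocks_separate_on_pc1(self):
        dosage = np.vstack([np.full((10, 8), 2), np.zeros((10, 8), dtype=int)])
        t = GenotypeTable([f"s{i}" for i in range(20)], ["X"] * 10 + ["Y"] * 10,
                          [f"L{j}" for j in range(8)], dosage)
        res = ot.genotype_pca(t)
        pc1 = res.scores[:, 0]
        assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()  # opposite sides
        assert res.explained[0] == pytest.approx(1.0)

    def test_duplicated_individual_identical_scores(self, world):
        t = world.table
        dup = GenotypeTable(t.sample_ids + ["dup"], t.population_labels + ["X"],
                            t.locus_ids, np.vstack([t.dosage, t.dosage[:1]]))
        res = ot.genotype_pca(dup)
        assert res.scores[0] == pytest.approx(res.scores[-1], abs=1e-8)

    def test_matches_svd_oracle(self, world):
        res = ot.genotype_pca(world.table)
        X = ot.impute_dosage(world.table)
        X = X - X.mean(axis=0)
        s = np.linalg.svd(X, compute_uv=False)
        recomputed = np.sqrt((res.scores ** 2).sum(axis=0))
        assert recomputed == pytest.approx(s[:len(recomputed)], abs=1e-8)
        # scores are column-centered
        assert res.scores.mean(axis=0) == pytest.approx(
            np.zeros(res.scores.shape[1]), abs=1e-8)

    def test_explained_fractions_decreasing(self, world):
        res = ot.genotype_pca(world.table)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert res.explained.sum() <= 1 + 1e-9

    def test_locus_reordering_invariance(self, world):
        t = world.table
        perm = list(reversed(range(t.n_loci)))
        shuffled = GenotypeTable(t.sample_ids, t.population_labels,
                                 [t.locus_ids[j] for j in perm], t.dosage[:, perm])
        a = ot.genotype_pca(t).scores[:, 0]
        b = ot.genotype_pca(shuffled).scores[:, 0]
        assert np.abs(a) == pytest.approx(np.abs(b), abs=1e-8)

    def test_mean_imputation(self):
        dosage = np.array([[2, MISSING], [0, 2], [1, 0]])
        t = GenotypeTable(["a", "b", "c"], ["P"] * 3, ["L1", "L2"], dosage)
        X = ot.impute_dosage(t)
        assert X[0, 1] == pytest.approx(1.0)  # mean of 2 and 0

    def test_single_sample_raises(self):
        t = GenotypeTable(["a"], ["P"], ["L1"], np.array([[1]]))
        with pytest.raises(ValueError):
            ot.genotype_pca(t)

    def test_patterson_mode_runs(self, world):
        res = ot.genotype_pca(world.table, mode="patterson")
        assert res.mode == "patterson"
        assert res.scores.shape[0] == world.table.n_samples


class TestClassicalMds:
    def test_planar_points_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = ot.classical_mds(D, dims=2)
        got = res.coordinates.to_numpy()
        D2 = np.linalg.norm(got[:, None] - got[None, :], axis=2)
        assert D2 == pytest.approx(D, abs=1e-8)
        assert res.stress == pytest.approx(0.0, abs=1e-9)

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        got = ot.classical_mds(D, dims=2).coordinates.to_numpy()
        dists = sorted(np.linalg.norm(got[i] - got[j])
                       for i, j in itertools.combinations(range(3), 2))
        assert dists == pytest.approx([1.0, 1.0, 1.0], abs=1e-9)

    def test_random_euclidean_reconstruction(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        got = ot.classical_mds(pd.DataFrame(D), dims=2).coordinates.to_numpy()
        D2 = np.linalg.norm(got[:, None] - got[None, :], axis=2)
        assert D2 == pytest.approx(D, abs=1e-8)

    def test_centroid_at_origin(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        got = ot.classical_mds(D).coordinates.to_numpy()
        assert got.mean(axis=0) == pytest.approx([0, 0], abs=1e-10)

    def test_population_reordering_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        perm = [3, 1, 4, 0, 2]
        got = ot.classical_mds(D).coordinates.to_numpy()
        got_perm = ot.classical_mds(D[np.ix_(perm, perm)]).coordinates.to_numpy()
        d_a = np.linalg.norm(got[:, None] - got[None, :], axis=2)
        d_b = np.linalg.norm(got_perm[:, None] - got_perm[None, :], axis=2)
        assert d_a[np.ix_(perm, perm)] == pytest.approx(d_b, abs=1e-8)

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError):
            ot.classical_mds(np.array([[0, 1.0], [2.0, 0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = ot.neighbor_joining(D)
        lengths = {c.name: c.branch_length for c in tree.get_terminals()}
        assert lengths["A"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert lengths["B"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert lengths["C"] == pytest.approx(0.5 * (4 + 5 - 3))

    def test_four_taxon_additive_recovery(self):
        # ((A:1,B:2):0.5,(C:1.5,D:0.7)) as an additive metric
        edges = {(0, 4): 1.0, (1, 4): 2.0, (4, 5): 0.5, (2, 5): 1.5, (3, 5): 0.7}
        D = path_metric(edges, 4)
        labels = list("ABCD")
        tree = ot.neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
        D2 = ot.tree_distance_matrix(tree)
        assert D2.loc[labels, labels].to_numpy() == pytest.approx(D, abs=1e-10)

    def test_root_trifurcates(self):
        rng = np.random.default_rng(0)
        edges = random_binary_tree(rng, 6)
        D = path_metric(edges, 6)
        tree = ot.neighbor_joining(D, labels=[str(i) for i in range(6)])
        assert len(tree.root.clades) == 3

    def test_two_leaves_single_edge(self):
        tree = ot.neighbor_joining(np.array([[0, 1.5], [1.5, 0]]), labels=["a", "b"])
        assert {c.name for c in tree.get_terminals()} == {"a", "b"}
        total = sum(c.branch_length for c in tree.get_terminals())
        assert total == pytest.approx(1.5)

    def test_nj_inverts_additive_expansion(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            edges = random_binary_tree(rng, n)
            D = path_metric(edges, n)
            labels = [f"t{i}" for i in range(n)]
            tree = ot.neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
            D2 = ot.tree_distance_matrix(tree).loc[labels, labels].to_numpy()
            assert D2 == pytest.approx(D, abs=1e-9)

    def test_newick_round_trip_stable(self, tmp_path, world):
        from aimpanel.differentiation import da_distance_matrix

        tree = ot.neighbor_joining(da_distance_matrix(world.table))
        p1 = tmp_path / "a.nwk"
        write_newick(tree, p1)
        back = read_newick(p1)
        p2 = tmp_path / "b.nwk"
        write_newick(back, p2)
        assert p1.read_text() == p2.read_text()

    def test_target_group_inside_source_hull(self, world):
        # individuals of the admixed target group project within the convex
        # hull of their source-group centroids in PC1-PC2
        res = ot.genotype_pca(world.table)
        labels = np.asarray(world.table.population_labels)
        pts = res.scores[:, :2]
        centroids = {p: pts[labels == p].mean(axis=0)
                     for p in world.table.populations if p != "TARGET"}
        hull = np.array(list(centroids.values()))
        target_centroid = pts[labels == "TARGET"].mean(axis=0)
        # centroid inside bounding region of sources (loose hull surrogate)
        assert (target_centroid >= hull.min(axis=0) - 1e-9).all()
        assert (target_centroid <= hull.max(axis=0) + 1e-9).all()
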