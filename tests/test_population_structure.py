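import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from aisnp import genotype_io as gio
from aisnp import population_structure as ps
from aisnp import synthetic_data as sd
from aisnp.divergence_metrics import fst_nei


def make_aft(freq_rows, labels=None):
    arr = np.array(freq_rows, dtype=float)
    loci = [
        gio.Locus(f"rs{j}", "1", j + 1, "A", "G") for j in range(arr.shape[1])
    ]
    labels = labels or [f"G{i}" for i in range(arr.shape[0])]
    return gio.AlleleFrequencyTable(
        labels, loci, arr, np.full(arr.shape, 100, dtype=int)
    )


# ---------------------------------------------------------------------------
# random additive trees (independent of the package's tree code)
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary topology + branch lengths; returns (edges, leaf names)."""
    nodes = list(range(n_taxa))
    next_id = n_taxa
    edges = []
    active = nodes[:]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]  # pop higher index first
        u = next_id
        next_id += 1
        edges.append((u, a, rng.uniform(0.1, 2.0)))
        edges.append((u, b, rng.uniform(0.1, 2.0)))
        active = [x for x in active if x not in (a, b)] + [u]
    edges.append((active[0], active[1], rng.uniform(0.1, 2.0)))
    return edges, next_id


def path_distances(edges, n_nodes, n_leaves):
    adj = {i: [] for i in range(n_nodes)}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    out = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            out[src, dst] = dist[dst]
    return out


def tree_splits(tree: ps.PhyloTree) -> set[frozenset]:
    """Non-trivial leaf bipartitions induced by internal edges."""
    adj = tree.adjacency()
    n_leaves = len(tree.leaf_labels)
    splits = set()
    for u, v, _ in tree.edges:
        # leaves on v's side when edge (u, v) removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(x)
            for y, _w in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n_leaves - 1:
            splits.add(frozenset(side))
    return splits


# ---------------------------------------------------------------------------
# Nei DA
# ---------------------------------------------------------------------------

class TestNeiDA:
    def test_identical_zero(self):
        aft = make_aft([[0.3, 0.7], [0.3, 0.7]])
        assert ps.nei_da(aft).values[0, 1] == pytest.approx(0.0)

    def test_fixed_opposite_maximal(self):
        aft = make_aft([[0.0, 1.0], [1.0, 0.0]])
        assert ps.nei_da(aft).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # 1 - (1/2) [ (sqrt(.25)+sqrt(.25)) + (sqrt(.5)+0) ]
        aft = make_aft([[0.5, 0.5], [0.5, 1.0]])
        expected = 1 - 0.5 * ((0.5 + 0.5) + math.sqrt(0.5))
        assert ps.nei_da(aft).values[0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1464, abs=5e-5)

    def test_undefined_cell_drops_locus(self):
        aft = make_aft([[0.5, 0.5], [0.5, 1.0]])
        aft.alt_freq[1, 1] = np.nan
        d = ps.nei_da(aft)
        assert d.values[0, 1] == pytest.approx(0.0)  # only locus 0 remains

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(1)
        aft = make_aft(rng.uniform(0, 1, size=(4, 20)))
        d = ps.nei_da(aft)
        assert np.allclose(d.values, d.values.T)
        assert (np.diag(d.values) == 0).all()
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestPairwiseFst:
    def test_identical_zero(self):
        aft = make_aft([[0.3, 0.7], [0.3, 0.7]])
        assert ps.pairwise_fst_matrix(aft).values[0, 1] == 0.0

    def test_fixed_difference_one(self):
        aft = make_aft([[0.0, 1.0], [1.0, 0.0]])
        assert ps.pairwise_fst_matrix(aft).values[0, 1] == pytest.approx(1.0)

    def test_single_locus_consistent_with_fst_nei(self):
        aft = make_aft([[0.9], [0.1]])
        assert ps.pairwise_fst_matrix(aft).values[0, 1] == pytest.approx(
            fst_nei([0.9, 0.1])
        )
        assert ps.pairwise_fst_matrix(aft).values[0, 1] == pytest.approx(0.64)

    def test_all_monomorphic_pair_zero(self):
        aft = make_aft([[0.0, 1.0], [0.0, 1.0]])
        assert ps.pairwise_fst_matrix(aft).values[0, 1] == 0.0


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 3.0, 4.0, 5.0
        dm = ps.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]),
        )
        tree = ps.neighbor_joining(dm)
        lengths = {min(u, v) if min(u, v) < 3 else None: w
                   for u, v, w in tree.edges}
        adj = {leaf: w for u, leaf, w in tree.edges if leaf < 3}
        assert adj[0] == pytest.approx((d12 + d13 - d23) / 2)
        assert adj[1] == pytest.approx((d12 + d23 - d13) / 2)
        assert adj[2] == pytest.approx((d13 + d23 - d12) / 2)

    def test_four_taxon_additive_recovery(self):
        # known tree: (A,B)-internal(5)-(C,D); leaf branches 1,2,3,4
        labels = ["A", "B", "C", "D"]
        d = {
            ("A", "B"): 3.0,
            ("A", "C"): 1 + 5 + 3.0,
            ("A", "D"): 1 + 5 + 4.0,
            ("B", "C"): 2 + 5 + 3.0,
            ("B", "D"): 2 + 5 + 4.0,
            ("C", "D"): 7.0,
        }
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = ps.neighbor_joining(ps.DistanceMatrix(labels, mat))
        recovered = tree.leaf_distance_matrix()
        np.testing.assert_allclose(recovered.values, mat, atol=1e-12)
        assert tree_splits(tree) == {frozenset({0, 1}), frozenset({2, 3})} or \
            tree_splits(tree) == {frozenset({0, 1})}

    def test_random_additive_recovery(self):
        """100 random additive trees (<= 8 taxa) recovered exactly."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_taxa = int(rng.integers(4, 9))
            edges, n_nodes = random_additive_tree(rng, n_taxa)
            dmat = path_distances(edges, n_nodes, n_taxa)
            labels = [f"T{i}" for i in range(n_taxa)]
            tree = ps.neighbor_joining(ps.DistanceMatrix(labels, dmat))
            recovered = tree.leaf_distance_matrix()
            np.testing.assert_allclose(recovered.values, dmat, atol=1e-9)

    def test_ultrametric_matches_single_linkage(self):
        # balanced ultrametric on 6 taxa with three clear pairs
        labels = list("ABCDEF")
        heights = {
            ("A", "B"): 1.0, ("C", "D"): 1.2, ("E", "F"): 1.4,
        }
        mat = np.full((6, 6), 8.0)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 2 * heights[("A", "B")]
        mat[2, 3] = mat[3, 2] = 2 * heights[("C", "D")]
        mat[4, 5] = mat[5, 4] = 2 * heights[("E", "F")]
        for i, j in ((0, 2), (0, 3), (1, 2), (1, 3)):
            mat[i, j] = mat[j, i] = 6.0  # AB closer to CD than to EF
        tree = ps.neighbor_joining(ps.DistanceMatrix(labels, mat))
        splits = tree_splits(tree)
        assert frozenset({0, 1}) in splits or frozenset({2, 3, 4, 5}) in splits
        assert frozenset({4, 5}) in splits or frozenset({0, 1, 2, 3}) in splits
        # oracle: single-linkage merges the same three pairs first
        link = hierarchy.linkage(squareform(mat), method="single")
        first_merges = {frozenset(map(int, row[:2])) for row in link[:3]}
        assert first_merges == {
            frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})
        }

    def test_too_few_taxa(self):
        dm = ps.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            ps.neighbor_joining(dm)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            ps.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            ps.DistanceMatrix(["A", "B"], np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(6, 3))
        mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = ps.neighbor_joining(
            ps.DistanceMatrix([f"T{i}" for i in range(6)], mat)
        )
        assert all(w >= 0 for _, _, w in tree.edges)


class TestNewick:
    def test_three_leaf_shape(self):
        dm = ps.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]]),
        )
        nwk = ps.to_newick(ps.neighbor_joining(dm))
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 1
        for leaf in "ABC":
            assert leaf in nwk

    def test_round_trip_path_lengths(self):
        rng = np.random.default_rng(23)
        edges, n_nodes = random_additive_tree(rng, 7)
        dmat = path_distances(edges, n_nodes, 7)
        labels = [f"T{i}" for i in range(7)]
        tree = ps.neighbor_joining(ps.DistanceMatrix(labels, dmat))
        nwk = ps.to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for a, b in itertools.combinations(range(7), 2):
            got = pdm.patristic_distance(taxa[f"T{a}"], taxa[f"T{b}"])
            assert got == pytest.approx(dmat[a, b], abs=1e-6)

    def test_labels_with_spaces_quoted(self):
        dm = ps.DistanceMatrix(
            ["pop one", "pop two", "C"],
            np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]]),
        )
        nwk = ps.to_newick(ps.neighbor_joining(dm))
        assert "'pop one'" in nwk
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {t.label for t in parsed.taxon_namespace}
        assert labels == {"pop one", "pop two", "C"}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_identical_populations_coincide(self):
        aft = make_aft([[0.2, 0.8, 0.5], [0.2, 0.8, 0.5], [0.9, 0.1, 0.3]])
        res = ps.pca_populations(aft)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-12)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(3)
        aft = make_aft(rng.uniform(0, 1, size=(5, 12)))
        res = ps.pca_populations(aft)
        r = res.explained_variance_ratio
        assert np.all(r[:-1] >= r[1:] - 1e-12)
        assert r.sum() <= 1.0 + 1e-9
        assert np.all((r >= 0) & (r <= 1))

    def test_within_super_tighter_than_between(self, study_dataset):
        aft = gio.allele_frequencies(
            study_dataset["full"], study_dataset["manifest"], level="population"
        )
        res = ps.pca_populations(aft)
        # with one population per super-group here, check group separation
        # on PC1-2: distinct groups are farther apart than numerical zero
        pts = res.scores[:, :2]
        dists = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        assert dists[np.triu_indices(len(pts), 1)].min() > 0.01

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, size=(6, 10)).astype(np.int16)
        codes[5] = codes[0]
        loci = [gio.Locus(f"rs{j}", "1", j + 1, "A", "G") for j in range(10)]
        gm = gio.GenotypeMatrix([f"s{i}" for i in range(6)], loci, codes)
        res = ps.pca_individuals(gm)
        np.testing.assert_allclose(res.scores[0], res.scores[5], atol=1e-10)

    def test_two_separated_populations_pc1(self, study_dataset):
        gm = study_dataset["sources"]
        man = study_dataset["manifest"]
        keep = [s for s in gm.samples
                if man.super_of(s) in ("AFR", "EAS")]
        sub = gm.subset_samples(keep)
        res = ps.pca_individuals(sub)
        pc1 = res.scores[:, 0]
        afr = np.array([man.super_of(s) == "AFR" for s in sub.samples])
        lo, hi = sorted([pc1[afr].mean(), pc1[~afr].mean()])
        assert max(pc1[afr].min(), pc1[~afr].min()) > lo  # groups separate
        assert abs(pc1[afr].mean() - pc1[~afr].mean()) > pc1.std()

    def test_constant_locus_contributes_nothing(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(8, 5)).astype(np.int16)
        codes_const = np.hstack([codes, np.full((8, 1), 1, dtype=np.int16)])
        loci5 = [gio.Locus(f"rs{j}", "1", j + 1, "A", "G") for j in range(5)]
        loci6 = loci5 + [gio.Locus("rs5", "1", 6, "A", "G")]
        a = ps.pca_individuals(
            gio.GenotypeMatrix([f"s{i}" for i in range(8)], loci5, codes)
        )
        b = ps.pca_individuals(
            gio.GenotypeMatrix([f"s{i}" for i in range(8)], loci6, codes_const)
        )
        k = min(a.scores.shape[1], b.scores.shape[1])
        np.testing.assert_allclose(
            np.abs(a.scores[:, :k]), np.abs(b.scores[:, :k]), atol=1e-10
        )

    def test_score_row_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, size=(10, 8)).astype(np.int16)
        loci = [gio.Locus(f"rs{j}", "1", j + 1, "A", "G") for j in range(8)]
        gm1 = gio.GenotypeMatrix([f"s{i}" for i in range(10)], loci, codes)
        perm = rng.permutation(10)
        gm2 = gio.GenotypeMatrix(
            [f"s{i}" for i in perm], loci, codes[perm]
        )
        r1 = ps.pca_individuals(gm1)
        r2 = ps.pca_individuals(gm2)
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            np.abs(r1.scores), np.abs(r2.scores[inv]), atol=1e-9
        )

    def test_all_missing_locus_dropped(self):
        loci = [gio.Locus(f"rs{j}", "1", j + 1, "A", "G") for j in range(3)]
        codes = np.array(
            [[0, gio.MISSING, 2], [1, gio.MISSING, 0], [2, gio.MISSING, 1]],
            dtype=np.int16,
        )
        gm = gio.GenotypeMatrix(["a", "b", "c"], loci, codes)
        res = ps.pca_individuals(gm)
        assert res.loadings.shape[0] == 2
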