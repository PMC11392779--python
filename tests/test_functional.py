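"""Weighted Gower similarity and UPGMA dendrogram construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

import divgrid as dg
from divgrid.errors import IncomparablePairError
from divgrid.trees import BranchTable


def traits_of(frame, types, weights=None):
    return dg.TraitMatrix(
        values=frame, types=types,
        weights=weights or {c: 1.0 for c in frame.columns},
    )


class TestGower:
    def test_identical_vectors_fully_similar(self):
        tm = traits_of(
            pd.DataFrame({"t1": [1.0, 1.0], "t2": [0, 0]}, index=["a", "b"]),
            {"t1": "continuous", "t2": "binary"},
        )
        assert dg.weighted_gower_similarity(tm).loc["a", "b"] == 1.0

    def test_all_binary_mismatch_gives_zero(self):
        tm = traits_of(
            pd.DataFrame({"t1": [0, 1], "t2": [1, 0]}, index=["a", "b"]),
            {"t1": "binary", "t2": "binary"},
        )
        assert dg.weighted_gower_similarity(tm).loc["a", "b"] == 0.0

    def test_weighted_mixture_hand_value(self):
        # weights (1.0, 0.5); trait 1 matches, trait 2 mismatches
        tm = traits_of(
            pd.DataFrame({"t1": [1, 1], "t2": [0, 1]}, index=["a", "b"]),
            {"t1": "binary", "t2": "binary"},
            weights={"t1": 1.0, "t2": 0.5},
        )
        assert dg.weighted_gower_similarity(tm).loc["a", "b"] == \
            pytest.approx(1.0 / 1.5)

    def test_zero_weight_trait_is_ignored(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {"t1": rng.normal(size=6), "t2": rng.normal(size=6),
             "junk": rng.normal(size=6)},
            index=[f"s{i}" for i in range(6)],
        )
        types = {c: "continuous" for c in frame.columns}
        with_junk = dg.weighted_gower_similarity(
            traits_of(frame, types, {"t1": 1, "t2": 0.7, "junk": 0.0}))
        without = dg.weighted_gower_similarity(
            traits_of(frame[["t1", "t2"]],
                      {"t1": "continuous", "t2": "continuous"},
                      {"t1": 1, "t2": 0.7}))
        np.testing.assert_allclose(with_junk, without)

    def test_missing_values_renormalize(self):
        tm = traits_of(
            pd.DataFrame({"t1": [1, 1], "t2": [0, np.nan]},
                         index=["a", "b"]),
            {"t1": "binary", "t2": "binary"},
        )
        assert dg.weighted_gower_similarity(tm).loc["a", "b"] == 1.0

    def test_incomparable_pair_is_an_error(self):
        tm = traits_of(
            pd.DataFrame({"t1": [1, np.nan], "t2": [np.nan, 1.0]},
                         index=["a", "b"]),
            {"t1": "continuous", "t2": "continuous"},
        )
        with pytest.raises(IncomparablePairError, match="'a'.*'b'"):
            dg.weighted_gower_similarity(tm)

    def test_dissimilarity_bounded_and_symmetric(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({
            "c1": rng.normal(size=12),
            "o1": rng.integers(0, 4, 12).astype(float),
            "b1": rng.integers(0, 2, 12).astype(float),
        }, index=[f"s{i}" for i in range(12)])
        D = dg.gower_dissimilarity(traits_of(
            frame, {"c1": "continuous", "o1": "ordinal", "b1": "binary"}))
        assert (D.values >= -1e-12).all() and (D.values <= 1 + 1e-12).all()
        np.testing.assert_allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


def brute_force_upgma_heights(D: np.ndarray) -> np.ndarray:
    """Independent O(n^3) agglomeration oracle: cophenetic matrix of UPGMA."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dmin
        merged = clusters[i] + clusters[j]
        del clusters[j]
        clusters[i] = merged
        dist = {}
        keys = sorted(clusters)
        for p_idx, p in enumerate(keys):
            for q in keys[p_idx + 1:]:
                vals = [D[a, b] for a in clusters[p] for b in clusters[q]]
                dist[(p, q)] = float(np.mean(vals))
    return coph


def cophenetic_of_tree(tree: dg.RootedTree, labels) -> np.ndarray:
    depths = tree.leaf_depths()
    height = max(depths.values())
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                mrca = tree.mrca({a, b})
                d = 2 * (height - tree.node_depths()[id(mrca)])
                out[i, j] = out[j, i] = d
    return out


class TestUPGMA:
    def test_worked_three_species_heights(self, worked_dissimilarity):
        tree = dg.upgma(worked_dissimilarity)
        depths = tree.leaf_depths()
        assert all(d == pytest.approx(0.3) for d in depths.values())
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.3)

    def test_duplicate_species_merge_at_zero(self):
        D = pd.DataFrame([[0, 0, .4], [0, 0, .4], [.4, .4, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = dg.upgma(D)
        assert tree.is_ultrametric()
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        M = rng.uniform(0.05, 1.0, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        labels = [f"s{i:02d}" for i in range(n)]
        D = pd.DataFrame(M, index=labels, columns=labels)
        tree = dg.upgma(D)
        assert tree.is_ultrametric(rel_tol=1e-9)
        np.testing.assert_allclose(
            cophenetic_of_tree(tree, labels), brute_force_upgma_heights(M),
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_average_linkage(self, seed):
        """Independent library cross-check on matrices with distinct merges."""
        rng = np.random.default_rng(100 + seed)
        n = 10
        M = rng.uniform(0.05, 1.0, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        labels = [f"s{i:02d}" for i in range(n)]
        tree = dg.upgma(pd.DataFrame(M, index=labels, columns=labels))
        Z = average(squareform(M))
        np.testing.assert_allclose(
            cophenetic_of_tree(tree, labels),
            squareform(cophenet(Z)), atol=1e-10,
        )

    def test_exactly_ultrametric_input_is_reproduced(self, worked_tree):
        labels = sorted(worked_tree.leaf_labels)
        D_in = cophenetic_of_tree(worked_tree, labels)
        tree = dg.upgma(pd.DataFrame(D_in, index=labels, columns=labels))
        np.testing.assert_allclose(
            cophenetic_of_tree(tree, labels), D_in, atol=1e-12
        )

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, .2], [.3, 0]], index=list("AB"),
                         columns=list("AB"))
        with pytest.raises(ValueError, match="symmetric"):
            dg.upgma(D)


class TestFDSurfaces:
    def test_worked_dendrogram_fd(self, worked_dissimilarity):
        tree = dg.upgma(worked_dissimilarity)
        presence = np.array([[True, True, False]])
        fd, fe = dg.functional.fd_fe_surfaces(
            tree, presence, ["A", "B", "C"], mode="mrca")
        assert fd[0] == pytest.approx(0.2)

    def test_dendrogram_equal_phylogeny_gives_fd_equal_pd(self):
        from conftest import random_world

        tree, presence, species = random_world(7, n_species=20)
        fd, fe = dg.functional.fd_fe_surfaces(tree, presence, species)
        table = BranchTable(tree, presence, species)
        np.testing.assert_allclose(fd, table.pd_per_cell("root"),
                                   equal_nan=True)
        np.testing.assert_allclose(fe, table.endemism_per_cell("root"),
                                   equal_nan=True)

    def test_fe_conserved_and_bounded(self, worked_dissimilarity):
        tree = dg.upgma(worked_dissimilarity)
        rng = np.random.default_rng(4)
        presence = rng.random((5, 3)) < 0.6
        presence[0] = True
        fd, fe = dg.functional.fd_fe_surfaces(tree, presence,
                                              ["A", "B", "C"])
        occ = presence.any(axis=1)
        assert np.all(fe[occ] <= fd[occ] + 1e-12)
        assert np.nansum(fe) == pytest.approx(tree.total_length)
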