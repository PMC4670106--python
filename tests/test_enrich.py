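"""Nested-subset enrichment sweep: hypergeometric tail, GO propagation,
profile construction, top-k selection, and Ward clustergram."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from hdbrain import enrich
from hdbrain.enrich import (EnrichmentProfile, GeneSetCollection,
                            enrichment_profile, go_enrich, hypergeom_enrich,
                            integrate_and_cluster, nested_subsets,
                            rank_genesets)
from hdbrain.errors import ConfigurationError, InputError


def enumerate_tail(N, K, n, k):
    """Exhaustive oracle: fraction of n-subsets of N with >= k of K marked."""
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for x in combo if x < K) >= k
    return hits / total


class TestNestedSubsets:
    def test_full_scale_grid(self):
        ranked = [str(i) for i in range(5480)]
        sizes = nested_subsets(ranked, step=25)
        assert sizes[0] == 25 and sizes[1] == 50
        assert sizes[-2:] == [5475, 5480]
        assert len(sizes) == 5480 // 25 + 1

    def test_exact_multiple(self):
        assert nested_subsets([str(i) for i in range(100)]) == [25, 50, 75, 100]

    def test_remainder_appended(self):
        assert nested_subsets([str(i) for i in range(30)]) == [25, 30]

    def test_errors(self):
        with pytest.raises(InputError):
            nested_subsets([])
        with pytest.raises(ConfigurationError):
            nested_subsets(["a"], step=0)


class TestHypergeomEnrich:
    def test_zero_overlap_full_tail(self):
        universe = set(range(20))
        # P(X >= 0) is the full tail: p = 1 whenever the overlap is zero
        assert hypergeom_enrich({0, 1}, {2, 3}, universe) == 1.0
        # any positive overlap leaves a proper sub-tail
        assert hypergeom_enrich({0, 1}, {0, 3}, universe) < 1.0

    def test_subset_equal_universe_forces_full_overlap(self):
        universe = set(range(10))
        geneset = {1, 2, 3}
        assert hypergeom_enrich(universe, geneset, universe) == 1.0

    def test_hand_enumerated_example(self):
        # N=10, K=4, n=5, overlap 3: 66 of the 252 5-subsets have >= 3 marked
        universe = set(range(10))
        geneset = set(range(4))
        subset = {0, 1, 2, 4, 5}
        p = hypergeom_enrich(subset, geneset, universe)
        assert p == pytest.approx(66 / 252)

    def test_matches_enumeration_small_grid(self):
        # spot-check a few (N, K, n) against the exhaustive oracle; the full
        # universe <= 12 sweep runs in the acceptance suite
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 6, 3)]:
            universe = set(range(N))
            geneset = set(range(K))
            for overlap in range(0, min(K, n) + 1):
                subset = set(range(overlap)) | set(range(K, K + n - overlap))
                p = hypergeom_enrich(subset, geneset, universe)
                assert p == pytest.approx(enumerate_tail(N, K, n, overlap))

    def test_empty_geneset_returns_one(self):
        assert hypergeom_enrich({0}, {99}, set(range(10))) == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            hypergeom_enrich(set(), set(), set())


class TestGoEnrich:
    def test_flat_hierarchy_reduces_to_per_set_test(self):
        universe = set(f"g{i}" for i in range(50))
        coll = GeneSetCollection("go", {
            "t1": [f"g{i}" for i in range(5)],
            "t2": [f"g{i}" for i in range(10, 20)]})
        subset = set(f"g{i}" for i in range(8))
        result = go_enrich(subset, coll, universe)
        for term in coll.sets:
            assert result[term] == pytest.approx(
                hypergeom_enrich(subset, set(coll.sets[term]), universe))

    def test_parent_inherits_leaf_members(self):
        coll = GeneSetCollection("go", {"leaf": ["a", "b"], "parent": []},
                                 hierarchy=[("leaf", "parent")])
        members = coll.propagated()
        assert members["parent"] == {"a", "b"}

    def test_three_level_dag_transitive_closure(self):
        # grandparent gets leaf + mid members; diamond edges merge
        coll = GeneSetCollection("go", {
            "leaf": ["a"], "mid1": ["b"], "mid2": ["c"], "root": ["d"]},
            hierarchy=[("leaf", "mid1"), ("leaf", "mid2"),
                       ("mid1", "root"), ("mid2", "root")])
        members = coll.propagated()
        assert members["mid1"] == {"a", "b"}
        assert members["mid2"] == {"a", "c"}
        assert members["root"] == {"a", "b", "c", "d"}

    def test_cyclic_hierarchy_rejected(self):
        coll = GeneSetCollection("go", {"a": ["x"], "b": ["y"]},
                                 hierarchy=[("a", "b"), ("b", "a")])
        with pytest.raises(InputError):
            coll.propagated()


class TestEnrichmentProfile:
    def test_prefix_set_peaks_at_its_own_size(self):
        ranked = [f"g{i}" for i in range(1000)]
        universe = set(ranked)
        coll = GeneSetCollection("c", {"top25": ranked[:25]})
        prof = enrichment_profile(coll, ranked, universe, step=25)
        neglog = prof.neglog10p.loc["top25"]
        assert prof.best_size["top25"] == 25
        assert (np.diff(neglog.to_numpy()) <= 1e-9).all()

    def test_cells_match_per_subset_hypergeometric_calls(self):
        # vectorized sweep vs the scalar tail function, independent routes
        rng = np.random.default_rng(5)
        ranked = [f"g{i}" for i in range(120)]
        universe = set(ranked) | {f"x{i}" for i in range(30)}
        members = list(rng.choice(ranked, 25, replace=False)) + ["x0", "x1"]
        coll = GeneSetCollection("c", {"s": members})
        prof = enrichment_profile(coll, ranked, universe, step=25)
        for size in prof.pvalues.columns:
            expected = hypergeom_enrich(set(ranked[:size]), set(members),
                                        universe)
            assert prof.pvalues.loc["s", size] == pytest.approx(expected)

    def test_overlap_monotone_under_nesting(self):
        rng = np.random.default_rng(6)
        ranked = [f"g{i}" for i in range(200)]
        members = set(rng.choice(ranked, 30, replace=False))
        overlaps = [len(set(ranked[:n]) & members)
                    for n in nested_subsets(ranked, 25)]
        assert (np.diff(overlaps) >= 0).all()

    def test_empty_collection_gives_empty_profile(self):
        prof = enrichment_profile(GeneSetCollection("c", {}),
                                  ["a", "b"], {"a", "b"}, step=1)
        assert prof.pvalues.empty

    def test_duplicate_ranked_genes_rejected(self):
        with pytest.raises(InputError):
            enrichment_profile(GeneSetCollection("c", {"s": ["a"]}),
                               ["a", "a"], {"a"}, step=1)


class TestRankGenesets:
    def test_single_set(self):
        prof = EnrichmentProfile("c", pd.DataFrame({25: [0.01]},
                                                   index=["only"]))
        assert rank_genesets(prof, top_k=15) == ["only"]

    def test_dominating_set_ranked_first(self):
        prof = EnrichmentProfile("c", pd.DataFrame(
            {25: [0.001, 0.01], 50: [0.002, 0.02]}, index=["A", "B"]))
        assert rank_genesets(prof, 2) == ["A", "B"]

    def test_matches_bruteforce_min_sort(self):
        rng = np.random.default_rng(7)
        pvals = pd.DataFrame(rng.random((50, 8)),
                             index=[f"s{i:02d}" for i in range(50)])
        prof = EnrichmentProfile("c", pvals)
        expected = sorted(pvals.index,
                          key=lambda s: (pvals.loc[s].min(), s))[:15]
        assert rank_genesets(prof, 15) == expected


def ward_bruteforce(X):
    """Naive Ward agglomeration via the Lance-Williams update.

    Returns merge heights (ascending) and the partition into k clusters for
    every k, as sets of frozensets of row indices.
    """
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = np.linalg.norm(X[i] - X[j])
    heights = []
    partitions = {n: set(clusters.values())}
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        na, nb = sizes[a], sizes[b]
        merged = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        new_d = {}
        for key in list(d):
            if a in key or b in key:
                other = key[0] if key[1] in (a, b) else key[1]
                if other in (a, b):
                    del d[key]
                    continue
                dao = d.pop((min(a, other), max(a, other)), None)
                dbo = d.pop((min(b, other), max(b, other)), None)
                if dao is None or dbo is None:
                    continue
                nk = sizes[other]
                new = np.sqrt(((na + nk) * dao**2 + (nb + nk) * dbo**2
                               - nk * h**2) / (na + nb + nk))
                new_d[(other, next_id)] = new
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        d.update(new_d)
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        partitions[len(clusters)] = set(clusters.values())
        next_id += 1
    return heights, partitions


class TestIntegrateAndCluster:
    @staticmethod
    def _profile_from_matrix(mat, names, sizes=(25, 50, 75)):
        # build a profile whose masked -log10 p equals `mat` row-normalized
        pvals = pd.DataFrame(10.0 ** -np.asarray(mat), index=names,
                             columns=list(sizes)[: np.asarray(mat).shape[1]])
        return EnrichmentProfile("c", pvals, mask_alpha=1.0)

    def test_identical_rows_merge_first_and_share_group(self):
        mat = np.array([[5.0, 2.0, 9.0], [5.0, 2.0, 9.0], [1.0, 8.0, 3.0]])
        prof = self._profile_from_matrix(mat, ["r1", "r2", "r3"])
        gram = integrate_and_cluster([prof], top_k=3, n_groups=2)
        assert gram.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert gram.groups["c:r1"] == gram.groups["c:r2"]
        assert gram.groups["c:r3"] != gram.groups["c:r1"]

    def test_two_separated_blocks_recovered(self):
        rng = np.random.default_rng(8)
        block_a = np.abs(rng.normal(10, 0.5, (3, 4))) * [[1, 1, 0.01, 0.01]]
        block_b = np.abs(rng.normal(10, 0.5, (3, 4))) * [[0.01, 0.01, 1, 1]]
        mat = np.vstack([block_a, block_b])
        prof = self._profile_from_matrix(mat, [f"r{i}" for i in range(6)],
                                         sizes=(25, 50, 75, 100))
        gram = integrate_and_cluster([prof], top_k=6, n_groups=2)
        labels = gram.groups
        assert len({labels[f"c:r{i}"] for i in range(3)}) == 1
        assert len({labels[f"c:r{i}"] for i in range(3, 6)}) == 1
        assert labels["c:r0"] != labels["c:r5"]

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(9)
        mat = np.abs(rng.normal(5, 2, (5, 3))) + 0.5
        prof_a = self._profile_from_matrix(mat, [f"r{i}" for i in range(5)])
        # near-unit scales keep the best-p selection order; the row-sum
        # normalization must then cancel the scaling entirely
        scaled = mat * np.array([1.0, 1.01, 0.99, 1.02, 0.98])[:, None]
        prof_b = self._profile_from_matrix(scaled, [f"r{i}" for i in range(5)])
        ga = integrate_and_cluster([prof_a], top_k=5, n_groups=2)
        gb = integrate_and_cluster([prof_b], top_k=5, n_groups=2)
        pd.testing.assert_frame_equal(ga.matrix, gb.matrix)
        np.testing.assert_allclose(ga.linkage_matrix, gb.linkage_matrix)
        pd.testing.assert_series_equal(ga.groups, gb.groups)

    def test_matches_bruteforce_ward_agglomeration(self):
        rng = np.random.default_rng(10)
        mat = np.abs(rng.normal(4, 2, (7, 5))) + 0.1
        prof = self._profile_from_matrix(mat, [f"r{i}" for i in range(7)],
                                         sizes=(25, 50, 75, 100, 125))
        gram = integrate_and_cluster([prof], top_k=7, n_groups=3)
        X = gram.matrix.to_numpy()
        heights, partitions = ward_bruteforce(X)
        np.testing.assert_allclose(np.sort(gram.linkage_matrix[:, 2]),
                                   np.sort(heights), rtol=1e-10)
        for k in (2, 3, 4):
            scipy_labels = fcluster(gram.linkage_matrix, t=k,
                                    criterion="maxclust")
            scipy_partition = {
                frozenset(np.flatnonzero(scipy_labels == lab))
                for lab in set(scipy_labels)}
            assert scipy_partition == partitions[k]

    def test_mismatched_columns_rejected(self):
        p1 = self._profile_from_matrix([[1.0, 2.0]], ["a"], sizes=(25, 50))
        p2 = self._profile_from_matrix([[1.0, 2.0]], ["b"], sizes=(25, 75))
        with pytest.raises(InputError):
            integrate_and_cluster([p1, p2], top_k=1, n_groups=1)
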