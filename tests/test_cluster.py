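"""Clustering: binary distance, UPGMA with deterministic tie-breaks, and
multiscale bootstrap support."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

import palmitome as pt
from palmitome.cluster import DEFAULT_SCALES, Dendrogram
from palmitome.errors import ValidationError


def matrix_from_sets(sets: dict, universe) -> pd.DataFrame:
    return pd.DataFrame(
        {s: [1 if g in genes else 0 for g in universe] for s, genes in sets.items()},
        index=list(universe),
    )


class TestBinaryDistance:
    def test_set_formula_example(self):
        m = matrix_from_sets({"A": {1, 2, 3}, "B": {2, 3, 4}}, [1, 2, 3, 4, 5])
        d = pt.binary_distance(m)
        assert d.loc["A", "B"] == pytest.approx(2 / 4)

    def test_identical_and_disjoint_columns(self):
        m = matrix_from_sets({"A": {1, 2}, "B": {1, 2}, "C": {3}}, [1, 2, 3])
        d = pt.binary_distance(m)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == 1.0
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_matches_set_oracle_on_random_sparse_columns(self):
        rng = np.random.default_rng(42)
        X = (rng.random((60, 6)) < 0.2).astype(int)
        m = pd.DataFrame(X, columns=list("ABCDEF"))
        d = pt.binary_distance(m)
        for i, a in enumerate(m.columns):
            for b in m.columns[i + 1 :]:
                sa = {g for g in range(60) if X[g, m.columns.get_loc(a)]}
                sb = {g for g in range(60) if X[g, m.columns.get_loc(b)]}
                expected = len(sa ^ sb) / len(sa | sb) if sa | sb else 0.0
                assert d.loc[a, b] == pytest.approx(expected)

    def test_agrees_with_scipy_jaccard(self):
        rng = np.random.default_rng(7)
        X = (rng.random((100, 5)) < 0.3)
        m = pd.DataFrame(X.astype(int), columns=list("ABCDE"))
        ours = pt.binary_distance(m).to_numpy()
        theirs = squareform(pdist(X.T, metric="jaccard"))
        assert np.allclose(ours, theirs)


def naive_average_linkage(dist: pd.DataFrame):
    """Independent re-scan oracle: average distance recomputed from the
    original matrix at every step."""
    clusters = [frozenset([c]) for c in dist.columns]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                d = np.mean([dist.loc[x, y] for x in a for y in b])
                key = (d, tuple(sorted([min(a), min(b)])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        merged = a | b
        merges.append((merged, d))
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
    return merges


class TestAverageLinkage:
    def test_three_study_hand_example(self):
        d = pd.DataFrame(
            [[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = pt.average_linkage(d)
        assert tree.merges[0].members == frozenset("AB")
        assert tree.merges[0].height == pytest.approx(0.2)
        assert tree.merges[1].height == pytest.approx(0.8)

    def test_equal_distances_merge_lexicographically(self):
        d = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("CBA"), columns=list("CBA"))
        tree = pt.average_linkage(d)
        assert tree.merges[0].members == frozenset("AB")

    def test_two_study_base_case(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=list("XY"), columns=list("XY"))
        tree = pt.average_linkage(d)
        assert tree.root.members == frozenset("XY")
        assert tree.root.height == pytest.approx(0.3)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 0.3], [0.1, 0.0]], index=list("XY"), columns=list("XY"))
        with pytest.raises(ValidationError):
            pt.average_linkage(d)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_naive_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        D = squareform(rng.random(n * (n - 1) // 2))
        d = pd.DataFrame(D, index=list("ABCDEF"), columns=list("ABCDEF"))
        tree = pt.average_linkage(d)
        oracle = naive_average_linkage(d)
        assert [m.members for m in tree.merges] == [m for m, _ in oracle]
        for node, (_, h) in zip(tree.merges, oracle):
            assert node.height == pytest.approx(h)

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_scipy_upgma(self, seed):
        rng = np.random.default_rng(100 + seed)
        condensed = rng.random(15)  # 6 leaves, generically distinct distances
        d = pd.DataFrame(squareform(condensed), index=list("ABCDEF"), columns=list("ABCDEF"))
        ours = sorted(m.height for m in pt.average_linkage(d).merges)
        theirs = sorted(linkage(condensed, method="average")[:, 2])
        assert np.allclose(ours, theirs)

    def test_heights_non_decreasing(self, sim):
        entries = pt.build_compendium(sim.study_gene_sets, sim.manifest)
        matrix = pt.to_binary_matrix(entries)
        tree = pt.average_linkage(pt.binary_distance(matrix))
        heights = [m.height for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestBinaryMatrix:
    def test_column_sums_equal_study_set_sizes(self, sim):
        entries = pt.build_compendium(sim.study_gene_sets, sim.manifest)
        matrix = pt.to_binary_matrix(entries, [m.study_id for m in sim.manifest])
        for study, genes in sim.study_gene_sets.items():
            assert matrix[study].sum() == len(genes)
        assert (matrix.sum(axis=1) >= 1).all()  # no all-zero gene rows


class TestBootstrap:
    def _toy_matrix(self, seed=0, n_genes=120):
        rng = np.random.default_rng(seed)
        base = (rng.random(n_genes) < 0.4).astype(int)
        cols = {
            "dup1": base,
            "dup2": base,  # exact duplicate pair
            "other1": (rng.random(n_genes) < 0.4).astype(int),
            "other2": (rng.random(n_genes) < 0.4).astype(int),
            "other3": (rng.random(n_genes) < 0.4).astype(int),
        }
        return pd.DataFrame(cols)

    def test_duplicated_studies_get_bp_one(self):
        m = self._toy_matrix()
        tree = pt.average_linkage(pt.binary_distance(m))
        support = pt.bootstrap_support(m, tree, n_samplings=200, seed=1)
        assert support.bp[frozenset({"dup1", "dup2"})] == 1.0

    def test_fixed_seed_reproduces_support_exactly(self):
        m = self._toy_matrix(3)
        tree = pt.average_linkage(pt.binary_distance(m))
        s1 = pt.bootstrap_support(m, tree, n_samplings=150, seed=9)
        s2 = pt.bootstrap_support(m, tree, n_samplings=150, seed=9)
        assert s1.bp == s2.bp
        assert s1.au == s2.au

    def test_au_values_lie_in_unit_interval_or_undefined(self):
        m = self._toy_matrix(5)
        tree = pt.average_linkage(pt.binary_distance(m))
        support = pt.bootstrap_support(m, tree, n_samplings=200, seed=2)
        for members in support.node_members:
            au = support.au[members]
            assert au is None or 0.0 <= au <= 1.0
        # the duplicate clade is recovered at every scale -> strong AU or undefined
        assert support.bp[frozenset({"dup1", "dup2"})] == 1.0

    def test_scales_must_include_one(self):
        m = self._toy_matrix()
        tree = pt.average_linkage(pt.binary_distance(m))
        with pytest.raises(ValidationError):
            pt.bootstrap_support(m, tree, n_samplings=100, scales=(0.5, 0.8), seed=0)


def test_newick_export_parses_with_biopython(tmp_path, sim):
    from io import StringIO

    from Bio import Phylo

    entries = pt.build_compendium(sim.study_gene_sets, sim.manifest)
    matrix = pt.to_binary_matrix(entries)
    tree = pt.average_linkage(pt.binary_distance(matrix))
    newick = tree.to_newick()
    parsed = Phylo.read(StringIO(newick), "newick")
    assert {t.name for t in parsed.get_terminals()} == set(matrix.columns)
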