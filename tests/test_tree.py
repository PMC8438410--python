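"""Distances, UPGMA and Newick serialisation."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ssrcore import (
    DistanceMatrix,
    GenotypeMatrix,
    allele_freqs,
    allele_sharing_distance,
    cophenetic,
    nei_1972_distance,
    to_newick,
    upgma,
)
from ssrcore.errors import InfiniteDistanceError, NoSharedLociError

from conftest import genotype_matrices, naive_upgma_heights


class TestAlleleSharingDistance:
    def test_identical_accessions_have_zero_distance(self):
        m = GenotypeMatrix.from_cells(
            ["a", "b"], ["s1", "s2"], [["AB", "CC"], ["AB", "CC"]]
        )
        assert allele_sharing_distance(m).value("a", "b") == 0.0

    def test_disjoint_homozygotes_have_distance_one(self):
        m = GenotypeMatrix.from_cells(
            ["a", "b"], ["s1", "s2"], [["AA", "AA"], ["BB", "BB"]]
        )
        assert allele_sharing_distance(m).value("a", "b") == 1.0

    def test_one_shared_allele_of_two(self):
        m = GenotypeMatrix.from_cells(["a", "b"], ["s1"], [["AB"], ["AC"]])
        assert allele_sharing_distance(m).value("a", "b") == 0.5

    def test_pairwise_deletion_of_missing_loci(self):
        m = GenotypeMatrix.from_cells(
            ["a", "b"], ["s1", "s2"], [["AA", None], ["AA", "BB"]]
        )
        assert allele_sharing_distance(m).value("a", "b") == 0.0

    def test_no_commonly_typed_locus_is_an_error_naming_the_pair(self):
        m = GenotypeMatrix.from_cells(
            ["a", "b"], ["s1", "s2"], [["AA", None], [None, "BB"]]
        )
        with pytest.raises(NoSharedLociError, match="'a'.*'b'"):
            allele_sharing_distance(m)

    @given(genotype_matrices(max_n=6, max_loci=3, missing_rate=0.0))
    def test_invariant_to_accession_order(self, m):
        rev = m.subset(m.accession_ids[::-1])
        d1 = allele_sharing_distance(m)
        d2 = allele_sharing_distance(rev)
        for i, a in enumerate(m.accession_ids):
            for b in m.accession_ids[i + 1 :]:
                assert d1.value(a, b) == pytest.approx(d2.value(a, b), abs=1e-12)


class TestNei1972:
    def _freqs(self, cells, n_acc):
        m = GenotypeMatrix.from_cells(
            [f"a{i}" for i in range(n_acc)], ["s1"], cells
        )
        return [allele_freqs(m, "s1")]

    def test_identical_frequencies_give_zero(self):
        fx = self._freqs([["AB"], ["AB"]], 2)
        assert nei_1972_distance(fx, fx) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_flagged_infinite(self):
        fx = self._freqs([["AA"]], 1)
        fy = self._freqs([["BB"], ["BB"]], 2)
        # second collection observes only allele B; alignment is on the union
        assert math.isinf(nei_1972_distance(fx, fy))

    def test_hand_evaluated_example(self):
        # fx = (1, 0), fy = (0.5, 0.5): D = -ln(0.5 / sqrt(0.5)) = ln(sqrt(2))
        fx = self._freqs([["AA"]], 1)
        fy = self._freqs([["AB"]], 1)
        assert nei_1972_distance(fx, fy) == pytest.approx(-math.log(0.5 / math.sqrt(0.5)))
        assert nei_1972_distance(fx, fy) == pytest.approx(0.3466, abs=5e-5)


def _dm(ids, rows):
    return DistanceMatrix(ids, np.array(rows, dtype=float))


class TestUpgma:
    def test_three_leaf_hand_example(self):
        dm = _dm(["A", "B", "C"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = upgma(dm)
        assert to_newick(tree) == "((A:1.0,B:1.0):1.0,C:2.0);"
        assert tree.root.height == 2.0

    def test_two_leaves_single_cherry(self):
        tree = upgma(_dm(["A", "B"], [[0, 3], [3, 0]]))
        assert to_newick(tree) == "(A:1.5,B:1.5);"
        assert len(tree.cherries()) == 1

    def test_all_equal_distances_tie_break_lowest_pair(self):
        dm = _dm(["A", "B", "C"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        tree = upgma(dm)
        # first merge must be (A, B); all heights equal d/2
        assert to_newick(tree) == "((A:0.5,B:0.5):0.0,C:0.5);"

    def test_infinite_entry_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, np.inf], [np.inf, 0.0]]))
        with pytest.raises(InfiniteDistanceError):
            upgma(dm)

    def test_ultrametric_input_is_reproduced_exactly(self):
        dm = _dm(
            ["A", "B", "C", "D"],
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
        )
        coph = cophenetic(upgma(dm))
        for a in dm.ids:
            for b in dm.ids:
                assert coph.value(a, b) == pytest.approx(dm.value(a, b), abs=1e-9)

    @given(st.integers(0, 200), st.integers(4, 7))
    def test_agrees_with_naive_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        coph = cophenetic(upgma(DistanceMatrix(ids, d)))
        oracle = naive_upgma_heights(ids, d.tolist())
        for (a, b), h in oracle.items():
            assert coph.value(a, b) == pytest.approx(2 * h, abs=1e-9)

    @given(st.integers(0, 100), st.integers(4, 12))
    def test_cophenetic_agrees_with_scipy_average_linkage(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        coph = cophenetic(upgma(DistanceMatrix(ids, d)))
        order = [coph.ids.index(x) for x in ids]  # cophenetic ids follow leaf order
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        ref = squareform(hierarchy.cophenet(z))
        np.testing.assert_allclose(coph.d[np.ix_(order, order)], ref, atol=1e-9)

    @given(st.integers(0, 100), st.integers(4, 8))
    def test_topology_invariant_to_input_order(self, seed, n):
        # tie-free (generic) distances: reordering rows permutes labels only
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        perm = rng.permutation(n)
        t1 = cophenetic(upgma(DistanceMatrix(ids, d)))
        t2 = cophenetic(
            upgma(DistanceMatrix([ids[k] for k in perm], d[np.ix_(perm, perm)]))
        )
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert t1.value(a, b) == pytest.approx(t2.value(a, b), abs=1e-9)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(5)
        n = 9
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))

        def check(node):
            for child in node.children:
                assert child.height <= node.height + 1e-9
                check(child)

        check(tree.root)


class TestNewick:
    def test_round_trip_parse_equality(self):
        rng = np.random.default_rng(11)
        n = 6
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(ids, d))
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        coph = cophenetic(tree)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    coph.value(a, b), abs=1e-9
                )
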