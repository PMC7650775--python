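"""K2P distances, the species-demarcation rule, neighbor joining and
alignment concatenation."""

import itertools
import math

import numpy as np
import pytest

from baculokit import (AlignedPair, DistanceMatrix, concat_alignments,
                       demarcate, diverge, k2p_distance, k2p_from_pq, nj_tree,
                       pairwise_distances)
from baculokit.phylo import SaturationError, nj_splits

from conftest import random_dna


class TestK2P:
    def test_identical_sequences_are_zero(self):
        pair = AlignedPair.from_strings("ACGTACGT", "ACGTACGT")
        assert k2p_distance(pair) == 0.0

    def test_closed_form_hand_value(self):
        # 100 sites, 10 transitions, 5 transversions:
        # d = -1/2 ln(0.75 * sqrt(0.90)) = 0.1701812...
        assert k2p_from_pq(0.10, 0.05) == pytest.approx(
            -0.5 * math.log(0.75 * math.sqrt(0.90)), abs=1e-12)

    def test_counts_from_strings(self):
        # transitions A<->G, C<->T; transversions otherwise; gaps and
        # ambiguity codes excluded pairwise.  Comparable pairs here:
        # AA, AG(ts), GG, GA(ts), CA(tv), CC, TT, TC(ts); '-', N and R
        # columns drop out.
        a = "AAGGCCTT-NA"
        b = "AGGAACTC-CR"
        pair = AlignedPair.from_strings(a, b)
        assert pair.n_compared == 8
        assert pair.P == pytest.approx(3 / 8)
        assert pair.Q == pytest.approx(1 / 8)

    def test_saturation_yields_nan_not_exception(self):
        assert math.isnan(k2p_from_pq(0.5, 0.1))
        assert math.isnan(k2p_from_pq(0.1, 0.5))

    def test_monotone_in_transitions(self):
        q = 0.05
        ds = [k2p_from_pq(p, q) for p in np.linspace(0.0, 0.40, 30)]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_matches_formula_on_random_draws(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 0.5)
            q = rng.uniform(0, 0.5)
            if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                continue
            assert k2p_from_pq(p, q) == pytest.approx(
                -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q)))

    def test_parameter_recovery_small(self, rng):
        for d_true in (0.05, 0.2):
            est = []
            for rep in range(5):
                s = random_dna(rng, 10_000)
                s2 = diverge(s, d_true, 2.0, int(rng.integers(1, 2**31)))
                est.append(k2p_distance(AlignedPair.from_strings(s, s2)))
            assert abs(np.mean(est) - d_true) < 0.01


class TestDemarcation:
    def test_all_low_is_same_species(self):
        v = demarcate({"granulin": 0.0, "lef8": 0.0, "lef9": 0.0})
        assert v.verdict == "same_species"

    def test_all_high_is_distinct(self):
        v = demarcate({"granulin": 0.21, "lef8": 0.18, "lef9": 0.19})
        assert v.verdict == "distinct_species"

    def test_mixed_is_inconclusive(self):
        assert demarcate({"granulin": 0.06,
                          "lef8": 0.04}).verdict == "inconclusive"

    def test_boundary_is_not_distinct(self):
        # the rule is strictly "more than 0.05"
        assert demarcate({"granulin": 0.05}).verdict == "same_species"

    def test_undefined_distance_forces_inconclusive(self):
        assert demarcate({"granulin": float("nan"),
                          "lef8": 0.2}).verdict == "inconclusive"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            demarcate({})


class TestPairwiseDistances:
    def test_identical_rows_zero_matrix(self):
        rows = {f"t{k}": "ACGTACGTAC" for k in range(3)}
        m = pairwise_distances(rows)
        assert np.allclose(m.d, 0.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        root = random_dna(rng, 300)
        rows = {f"t{k}": diverge(root, 0.1 + 0.05 * k, 2.0, 50 + k)
                for k in range(5)}
        m = pairwise_distances(rows)
        assert np.allclose(m.d, m.d.T)
        assert np.allclose(np.diag(m.d), 0.0)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_distances({"a": "ACGT", "b": "ACG"})

    def test_tsv_round_trip(self, rng, tmp_path):
        root = random_dna(rng, 200)
        rows = {f"t{k}": diverge(root, 0.05 * (k + 1), 2.0, 60 + k)
                for k in range(4)}
        m = pairwise_distances(rows)
        p = tmp_path / "d.tsv"
        m.to_tsv(p)
        back = DistanceMatrix.from_tsv(p)
        assert back.labels == m.labels
        assert np.allclose(back.d, m.d, atol=1e-6)


def _additive_matrix():
    """Distances from the 5-taxon tree ((A:1,B:2):1,(C:3,D:1):2,E:4)."""
    to_root = {"A": 2, "B": 3, "C": 5, "D": 3, "E": 4}
    cherry = {"A": "X", "B": "X", "C": "Y", "D": "Y", "E": "R"}
    leaf = {"A": 1, "B": 2, "C": 3, "D": 1, "E": 4}
    labels = list("ABCDE")
    d = np.zeros((5, 5))
    for i, j in itertools.combinations(range(5), 2):
        u, v = labels[i], labels[j]
        if cherry[u] == cherry[v] and cherry[u] != "R":
            dist = leaf[u] + leaf[v]
        else:
            dist = to_root[u] + to_root[v]
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.2, 0.3],
                                     [0.2, 0, 0.4],
                                     [0.3, 0.4, 0]]))
        tree = nj_tree(m)
        assert tree == "(A:0.050000,B:0.150000,C:0.250000);"

    def test_additive_five_taxon_exact(self):
        m = _additive_matrix()
        tree = nj_tree(m)
        assert nj_splits(m) == {frozenset("AB"), frozenset("CD")}
        # branch lengths recovered exactly on an additive matrix
        assert "A:1.000000" in tree and "B:2.000000" in tree
        assert "C:3.000000" in tree and "D:1.000000" in tree
        assert "E:4.000000" in tree

    def test_rejects_small_or_saturated_input(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
        bad = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        bad.d[0, 1] = bad.d[1, 0] = float("nan")
        with pytest.raises(SaturationError, match="saturated"):
            nj_tree(bad)

    def test_topology_agrees_with_dendropy_nj(self, rng):
        """Cross-check against an independent NJ implementation on a chain
        of serially diverged taxa."""
        import io

        import dendropy

        root = random_dna(rng, 1500)
        rows, cur = {}, root
        for k in range(6):
            cur = diverge(cur, 0.05, 2.0, 10 + k)
            rows[f"t{k}"] = cur
        m = pairwise_distances(rows)
        csv = "," + ",".join(m.labels) + "\n" + "".join(
            lab + "," + ",".join(f"{v:.6f}" for v in row) + "\n"
            for lab, row in zip(m.labels, m.d))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        taxa = frozenset(m.labels)

        def canon(s):
            o = taxa - s
            return min(s, o, key=lambda x: (len(x), tuple(sorted(x))))

        theirs = set()
        for node in pdm.nj_tree().preorder_node_iter():
            if node.parent_node and not node.is_leaf():
                leaves = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(leaves) < len(taxa) - 1:
                    theirs.add(canon(leaves))
        assert {canon(s) for s in nj_splits(m)} == theirs

    def test_topology_recovery_under_divergence(self, rng):
        # balanced 8-taxon tree evolved with the K2P generator
        full = frozenset("ABCDEFGH")

        def canon(s):
            o = full - s
            return min(s, o, key=lambda x: (len(x), tuple(sorted(x))))

        want = {canon(frozenset(x)) for x in
                ("AB", "CD", "EF", "GH", "ABCD", "EFGH")}
        ok = 0
        for rep in range(20):
            root = random_dna(rng, 2000)
            seeds = iter(range(rep * 100, rep * 100 + 50))
            n1 = diverge(root, 0.03, 2.0, next(seeds))
            n2 = diverge(root, 0.03, 2.0, next(seeds))
            parents = [diverge(n, 0.03, 2.0, next(seeds))
                       for n in (n1, n1, n2, n2)]
            leaves = {}
            for name, par in zip("ABCDEFGH",
                                 [p for p in parents for _ in (0, 1)]):
                leaves[name] = diverge(par, 0.03, 2.0, next(seeds))
            got = {canon(s) for s in nj_splits(pairwise_distances(leaves))}
            ok += got == want
        assert ok >= 19


class TestConcat:
    def test_two_blocks_concatenate(self):
        a = ("g1", {"x": "ACGTACGTAC", "y": "ACGTACGTAC"})
        b = ("g2", {"x": "TTTTTTTTTT", "y": "TTTTTTTTTT"})
        rows, offsets = concat_alignments([a, b])
        assert len(rows["x"]) == 20
        assert offsets == {"g1": (0, 10), "g2": (10, 20)}

    def test_offsets_partition_columns(self, rng):
        blocks = [(f"g{k}", {"x": random_dna(rng, 30 + 10 * k),
                             "y": random_dna(rng, 30 + 10 * k)})
                  for k in range(4)]
        rows, offsets = concat_alignments(blocks)
        spans = sorted(offsets.values())
        assert spans[0][0] == 0 and spans[-1][1] == len(rows["x"])
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_block_order_change_preserves_distances(self, rng):
        blocks = []
        for k in range(3):
            x = random_dna(rng, 200)
            blocks.append((f"g{k}", {"x": x,
                                     "y": diverge(x, 0.1, 2.0, 70 + k)}))
        r1, _ = concat_alignments(blocks)
        r2, _ = concat_alignments(blocks[::-1])
        d1 = k2p_distance(AlignedPair.from_strings(r1["x"], r1["y"]))
        d2 = k2p_distance(AlignedPair.from_strings(r2["x"], r2["y"]))
        assert d1 == pytest.approx(d2)

    def test_missing_taxon_listed(self):
        a = ("g1", {"x": "ACGT", "y": "ACGT"})
        b = ("g2", {"x": "ACGT"})
        with pytest.raises(ValueError, match="y"):
            concat_alignments([a, b])
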