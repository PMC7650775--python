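"""Protein alignment, gene-content classification, homolog mapping, parity
plots and the k-mer identity surrogate."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from baculokit import (CircularGenome, align_proteins, classify_orfs,
                       diverge, generate_genome, kmer_identity,
                       load_reference_panel, map_homologs, maphgv_like_spec,
                       parity_plot)
from baculokit.homology import PanelEntry, ReferencePanel
from baculokit.orfs import OrfRecord
from baculokit.simulate import diverge_genome_pair

from _oracles import collinearity_oracle, gotoh_score
from conftest import random_dna

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_protein(rng, n):
    return "".join(rng.choice(AA, n))


def _orf(orf_id, idx, translation):
    start = idx * 400
    return OrfRecord(orf_id, start, start + 3 * (len(translation) + 1), "+",
                     len(translation), translation)


class TestAlignProteins:
    def test_identical_sequences(self):
        score, ident, spans = align_proteins("MKV", "MKV", "global")
        assert ident == 1.0 and spans == ((0, 3), (0, 3))

    def test_ten_substitutions_in_hundred(self, rng):
        a = _random_protein(rng, 100)
        b = list(a)
        for pos in rng.choice(100, size=10, replace=False):
            choices = [x for x in AA if x != b[pos]]
            b[pos] = choices[int(rng.integers(0, len(choices)))]
        _, ident, _ = align_proteins(a, "".join(b), "global")
        assert ident == pytest.approx(0.90, abs=0.02)

    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_score_equals_bruteforce_dp(self, mode, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(15):
            a = _random_protein(rng, int(rng.integers(3, 12)))
            b = _random_protein(rng, int(rng.integers(3, 12)))
            score, _, _ = align_proteins(a, b, mode)
            assert score == pytest.approx(
                gotoh_score(a, b, blosum, local=(mode == "local")))

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            align_proteins("MKZ", "MKV")
        with pytest.raises(ValueError, match="empty"):
            align_proteins("", "MKV")


def _panel_with_seqs(rng):
    entries = [PanelEntry("granulin", "lepidopteran_conserved", "structure",
                          "orf1", "", [_random_protein(rng, 120)]),
               PanelEntry("lef-8", "core", "transcription", "orf117", "",
                          [_random_protein(rng, 150)]),
               PanelEntry("sod", "other", "auxiliary", "orf52", "",
                          [_random_protein(rng, 100)])]
    return ReferencePanel(entries)


class TestClassification:
    def test_packaged_panel_counts(self):
        panel = load_reference_panel()
        assert panel.counts() == {"core": 38, "lepidopteran_conserved": 16,
                                  "other": 20, "unique": 5}

    def test_iap_naming_conflict_surfaced_as_alias(self):
        panel = load_reference_panel()
        byname = {e.gene_name: e for e in panel.entries}
        assert byname["iap-1"].alias == "iap-6"
        assert byname["iap-2"].alias == "iap-5"

    def test_exact_match_assigns_gene_and_class(self, rng):
        panel = _panel_with_seqs(rng)
        orfs = [_orf("orf1", 0, panel.entries[0].sequences[0])]
        res = classify_orfs(orfs, panel)
        assert res.rows[0].gene_name == "granulin"
        assert res.rows[0].gene_class == "lepidopteran_conserved"
        assert res.rows[0].best_identity == 1.0

    def test_shuffled_decoy_is_unique(self, rng):
        panel = _panel_with_seqs(rng)
        decoy = list(panel.entries[1].sequences[0])
        rng.shuffle(decoy)
        res = classify_orfs([_orf("orfX", 0, "".join(decoy))], panel)
        assert res.rows[0].gene_class == "unique"
        assert res.rows[0].gene_name is None

    def test_counts_stable_under_renumbering(self, rng):
        panel = _panel_with_seqs(rng)
        orfs = [_orf(f"orf{k}", k, e.sequences[0])
                for k, e in enumerate(panel.entries)]
        c1 = classify_orfs(orfs, panel).counts()
        rotated = orfs[1:] + orfs[:1]
        c2 = classify_orfs(rotated, panel).counts()
        assert c1 == c2


class TestHomologMapping:
    def test_self_mapping_is_perfect(self, synthetic_genome):
        _, truth = synthetic_genome
        pairs = map_homologs(truth.orfs, truth.orfs)
        assert pairs == [(o.orf_id, o.orf_id) for o in truth.orfs]

    def test_recovery_after_divergence(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=21))
        # ~20% protein divergence arises near d=0.25 nucleotide divergence
        pair = diverge_genome_pair(genome, truth, 0.25, 2.0, seed=22)
        got = set(map_homologs(truth.orfs, pair.orfs))
        true_pairs = set(pair.homolog_pairs)
        assert len(got & true_pairs) >= 0.95 * len(true_pairs)

    def test_reciprocity(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=23))
        pair = diverge_genome_pair(genome, truth, 0.2, 2.0, seed=24)
        ab = set(map_homologs(truth.orfs, pair.orfs))
        ba = {(y, x) for x, y in map_homologs(pair.orfs, truth.orfs)}
        assert ab == ba

    def test_unrelated_orf_sets_share_nothing(self, rng):
        a = [_orf(f"a{k}", k, _random_protein(rng, 80)) for k in range(8)]
        b = [_orf(f"b{k}", k, _random_protein(rng, 80)) for k in range(8)]
        assert map_homologs(a, b) == []


class TestParity:
    def _genes(self, n, prefix):
        return [_orf(f"{prefix}{k}", k, "M" * 50) for k in range(n)]

    def test_identical_order_is_diagonal(self):
        a = self._genes(12, "a")
        b = self._genes(12, "b")
        pairs = [(f"a{k}", f"b{k}") for k in range(12)]
        data = parity_plot(a, b, pairs)
        assert data.collinearity == 1.0
        assert data.pairs == [(k, k) for k in range(12)]

    def test_reversal_needs_reflection(self):
        a = self._genes(10, "a")
        b = self._genes(10, "b")
        pairs = [(f"a{k}", f"b{9 - k}") for k in range(10)]
        assert parity_plot(a, b, pairs).collinearity == 1.0
        low = parity_plot(a, b, pairs, allow_reflection=False).collinearity
        # without reflection only short wrapping chains survive
        assert low <= 0.3

    def test_translocated_block_matches_chain_oracle(self):
        n = 50
        a = self._genes(n, "a")
        b_order = list(range(10)) + list(range(20, 50)) + list(range(10, 20))
        b = self._genes(n, "b")
        pairs = [(f"a{ia}", f"b{b_order.index(ia)}") for ia in range(n)]
        data = parity_plot(a, b, pairs)
        idx_pairs = [(ia, b_order.index(ia)) for ia in range(n)]
        assert data.collinearity == pytest.approx(
            collinearity_oracle(idx_pairs, n, n))
        assert data.collinearity == pytest.approx(0.8)

    def test_equals_oracle_on_random_permutations(self, rng):
        n = 9
        a = self._genes(n, "a")
        b = self._genes(n, "b")
        for _ in range(6):
            perm = list(rng.permutation(n))
            pairs = [(f"a{ia}", f"b{perm[ia]}") for ia in range(n)]
            got = parity_plot(a, b, pairs).collinearity
            want = collinearity_oracle([(ia, perm[ia]) for ia in range(n)],
                                       n, n)
            assert got == pytest.approx(want)

    def test_rotation_invariance(self, rng):
        n = 20
        a = self._genes(n, "a")
        b = self._genes(n, "b")
        perm = list(rng.permutation(n))
        pairs = [(f"a{ia}", f"b{perm[ia]}") for ia in range(n)]
        base = parity_plot(a, b, pairs).collinearity
        rot = a[7:] + a[:7]
        assert parity_plot(rot, b, pairs).collinearity == pytest.approx(base)

    def test_unknown_gene_rejected(self):
        a = self._genes(3, "a")
        b = self._genes(3, "b")
        with pytest.raises(ValueError, match="unknown genes"):
            parity_plot(a, b, [("a0", "nope")])


class TestKmerIdentity:
    def test_self_is_one(self, synthetic_genome):
        genome, _ = synthetic_genome
        assert kmer_identity(genome, genome) == 1.0

    def test_unrelated_is_near_zero(self):
        g1, _ = generate_genome(maphgv_like_spec(seed=41))
        g2, _ = generate_genome(maphgv_like_spec(seed=42))
        assert kmer_identity(g1, g2) < 0.01

    def test_five_percent_divergence_matches_expectation(self):
        g1, _ = generate_genome(maphgv_like_spec(seed=43))
        g2 = CircularGenome("d", diverge(g1.seq, 0.05, 2.0, 44))
        expected = (1 - 0.05) ** 17
        assert kmer_identity(g1, g2) == pytest.approx(expected, abs=0.05)

    def test_parameter_validation(self, synthetic_genome):
        genome, _ = synthetic_genome
        with pytest.raises(ValueError):
            kmer_identity(genome, genome, k=16)
        with pytest.raises(ValueError):
            kmer_identity(genome, genome, k=9)
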