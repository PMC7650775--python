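"""The synthetic-genome generator: determinism, composition targets,
feasibility checks, divergence statistics and implant recovery."""

import numpy as np
import pytest

from baculokit import (AlignedPair, CircularGenome, GenomeSpec, annotate,
                       diverge, find_hrs, generate_genome, k2p_distance,
                       maphgv_like_spec, parity_plot, scan_promoters)
from baculokit.simulate import (DrSpec, HrSpec, diverge_genome_pair,
                                k2p_event_probs)


class TestGeneration:
    def test_same_seed_is_byte_identical(self):
        g1, t1 = generate_genome(maphgv_like_spec(seed=77))
        g2, t2 = generate_genome(maphgv_like_spec(seed=77))
        assert g1.seq == g2.seq
        assert [(r.start, r.end, r.strand) for r in t1.orfs] == \
            [(r.start, r.end, r.strand) for r in t2.orfs]

    def test_background_only_hits_gc_target(self):
        spec = GenomeSpec(length_bp=30_000, n_orfs=0, seed=5,
                          gc_percent=37.18)
        genome, truth = generate_genome(spec)
        assert abs(genome.gc_percent() - 37.18) < 0.5
        assert truth.orfs == [] and truth.hrs == [] and truth.drs == []

    def test_infeasible_packing_raises_before_emitting(self):
        spec = GenomeSpec(length_bp=2_000, n_orfs=10, seed=5)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(spec)

    def test_unseeded_generation_refused(self):
        with pytest.raises(ValueError, match="seed"):
            GenomeSpec(length_bp=1000, n_orfs=0, seed=None)

    def test_core_must_be_palindrome(self):
        with pytest.raises(ValueError, match="palindrome"):
            HrSpec(core="GTAAACGTTTAA")

    def test_truth_orfs_translate_cleanly(self, synthetic_genome):
        genome, truth = synthetic_genome
        for rec in truth.orfs:
            nt = genome.subsequence(rec.start % len(genome), rec.end,
                                    rec.strand)
            assert nt[:3] == "ATG"
            assert nt[-3:] in ("TAA", "TAG", "TGA")
            assert rec.translation.startswith("M")
            assert "*" not in rec.translation


class TestImplantRecovery:
    """The generator's implants are recoverable by the analysis stages at
    their default thresholds (pooled over ORFs, promoters, hr units)."""

    def test_orf_and_promoter_implants_recovered(self):
        total = found = 0
        p_total = p_found = 0
        for seed in (101, 102, 103, 104, 105):
            genome, truth = generate_genome(maphgv_like_spec(seed=seed))
            pred = annotate(genome, 50, 30)
            pred_map = {(r.start, r.end, r.strand): r.orf_id for r in pred}
            total += len(truth.orfs)
            found += sum((r.start, r.end, r.strand) in pred_map
                         for r in truth.orfs)
            hits = {h.orf_id: h for h in scan_promoters(genome, pred)}
            for p in truth.promoters:
                tr = next(r for r in truth.orfs if r.orf_id == p.orf_id)
                pid = pred_map.get((tr.start, tr.end, tr.strand))
                p_total += 1
                p_found += bool(pid) and any(
                    h.promoter_class == p.promoter_class
                    and h.rel_start == p.rel_start
                    and h.matched_text == p.matched_text
                    for h in hits[pid].hits)
        assert found / total >= 0.95
        assert p_found / p_total >= 0.95

    def test_hr_implant_recovered_with_core(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=106))
        h = truth.hrs[0]
        match = [r for r in find_hrs(genome)
                 if min(r.span[1], h.span[1]) - max(r.span[0], h.span[0]) > 0]
        assert len(match) == 1
        assert len(match[0].units) == len(h.units)
        assert match[0].palindrome_core == h.core


class TestDiverge:
    def test_zero_distance_is_identity(self):
        s = "ACGT" * 100
        assert diverge(s, 0.0, 2.0, 1) == s

    def test_k2p_estimate_matches_d_true(self, rng):
        s = "".join(rng.choice(list("ACGT"), 10_000))
        ests = [k2p_distance(AlignedPair.from_strings(
            s, diverge(s, 0.1, 2.0, 300 + k))) for k in range(8)]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.1) <= max(2 * se, 0.005)

    def test_transition_transversion_ratio_matches_kappa(self, rng):
        s = "".join(rng.choice(list("ACGT"), 60_000))
        for kappa in (1.0, 2.0, 4.0):
            s2 = diverge(s, 0.1, kappa, 9)
            ts = tv = 0
            for x, y in zip(s, s2):
                if x == y:
                    continue
                if {x, y} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
            assert ts / tv == pytest.approx(kappa, rel=0.15)

    def test_event_probs_invert_through_k2p(self):
        # the generator's (P, Q) at d recover d through the estimator
        from baculokit import k2p_from_pq
        for d in (0.02, 0.1, 0.3, 0.6):
            P, Q = k2p_event_probs(d, 2.0)
            assert k2p_from_pq(P, Q) == pytest.approx(d, abs=1e-10)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            diverge("ACGT", 0.8, 2.0, 1)
        with pytest.raises(ValueError):
            diverge("ACGT", 0.1, -1.0, 1)

    def test_non_acgt_untouched(self):
        s = "ACGTN-ACGT"
        out = diverge(s, 0.5, 2.0, 3)
        assert out[4] == "N" and out[5] == "-"


class TestDivergePair:
    def test_orfs_stay_open_and_pairing_is_identity(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=110))
        pair = diverge_genome_pair(genome, truth, 0.3, 2.0, seed=111)
        assert pair.homolog_pairs == sorted(
            (r.orf_id, r.orf_id) for r in truth.orfs)
        for rec in pair.orfs:
            assert rec.translation.startswith("M")
            assert "*" not in rec.translation

    def test_no_permutation_gives_full_collinearity(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=112))
        pair = diverge_genome_pair(genome, truth, 0.1, 2.0, seed=113)
        data = parity_plot(sorted(truth.orfs, key=lambda r: r.start),
                           pair.orfs, pair.homolog_pairs)
        assert data.collinearity == 1.0

    def test_inverted_block_chain_fraction(self):
        # a 5-gene inversion in 15: an increasing chain keeps the 10
        # untouched genes plus one member of the inverted block
        genome, truth = generate_genome(maphgv_like_spec(seed=114))
        pair = diverge_genome_pair(genome, truth, 0.05, 2.0, seed=115,
                                   block_plan=[(0, 4, False), (5, 9, True),
                                               (10, 14, False)])
        data = parity_plot(sorted(truth.orfs, key=lambda r: r.start),
                           pair.orfs, pair.homolog_pairs,
                           allow_reflection=False)
        assert data.collinearity == pytest.approx(11 / 15)

    def test_deterministic_under_seed(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=116))
        a = diverge_genome_pair(genome, truth, 0.2, 2.0, seed=117)
        b = diverge_genome_pair(genome, truth, 0.2, 2.0, seed=117)
        assert a.genome.seq == b.genome.seq
        assert a.homolog_pairs == b.homolog_pairs

    def test_bad_block_plan_rejected(self):
        genome, truth = generate_genome(maphgv_like_spec(seed=118))
        with pytest.raises(ValueError, match="block plan"):
            diverge_genome_pair(genome, truth, 0.1, 2.0, seed=119,
                                block_plan=[(0, 3, False)])
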