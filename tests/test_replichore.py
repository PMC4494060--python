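"""GC skew, ori/ter detection, circular distances, growth and R value."""

import numpy as np
import pytest

from archflux.core_io import CircularGenome, GeneRecord
from archflux.replichore import (
    NoGrowthDetected,
    NoReplichoreSignal,
    SkewProfile,
    detect_ori_ter,
    distance_to_ori,
    estimate_doubling_time,
    find_dif_sites,
    gc_skew_profile,
    replication_ratio_R,
)
from archflux.synthetic import simulate_genome, simulate_growth_curve

REVCOMP = str.maketrans("ACGT", "TGCA")


def genome_from(seq, ori=0, ter=None):
    ter = ter if ter is not None else len(seq) // 2
    return CircularGenome("g", len(seq), ori, ter, seq)


class TestGcSkewProfile:
    def test_equal_g_and_c_gives_zero(self):
        prof = gc_skew_profile(genome_from("GGCC" * 5), window=4, step=4)
        assert np.allclose(prof.skew, 0.0)

    def test_all_g_hits_boundary_value(self):
        prof = gc_skew_profile(genome_from("GGGG" * 5), window=4, step=4)
        assert np.allclose(prof.skew, 1.0)

    def test_window_without_gc_flagged_zero(self):
        prof = gc_skew_profile(genome_from("ATAT" * 5), window=4, step=4)
        assert np.allclose(prof.skew, 0.0)
        assert prof.zero_gc.all()

    def test_reverse_complement_antisymmetry(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=1200))
        rc = seq.translate(REVCOMP)[::-1]
        w = 100
        fwd = gc_skew_profile(genome_from(seq), window=w, step=w).skew
        rev = gc_skew_profile(genome_from(rc), window=w, step=w).skew
        assert np.allclose(rev, -fwd[::-1])

    def test_cumulative_is_running_sum(self, small_genome):
        prof = gc_skew_profile(small_genome, window=500, step=100)
        assert np.allclose(prof.cumulative, np.cumsum(prof.skew))

    def test_window_larger_than_genome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="window"):
            gc_skew_profile(small_genome, window=20_000, step=100)


class TestDetectOriTer:
    @pytest.mark.parametrize("seed", range(5))
    def test_planted_signal_recovered_within_one_window(self, seed):
        L, window = 100_000, 5_000
        genome, _ = simulate_genome(L, ori=0, ter=50_000, skew_amp=0.1,
                                    seed=seed)
        prof = gc_skew_profile(genome, window=window, step=1_000)
        call = detect_ori_ter(prof)
        d_ori = min(abs(call.ori - 0), L - abs(call.ori - 0))
        d_ter = min(abs(call.ter - 50_000), L - abs(call.ter - 50_000))
        assert d_ori <= window and d_ter <= window

    @pytest.mark.parametrize("seed", range(5))
    def test_uniform_sequence_has_no_signal(self, seed):
        genome, _ = simulate_genome(60_000, ori=0, ter=30_000, skew_amp=0.0,
                                    seed=100 + seed)
        prof = gc_skew_profile(genome, window=5_000, step=1_000)
        with pytest.raises(NoReplichoreSignal):
            detect_ori_ter(prof)

    def test_invariant_to_additive_constant(self, small_genome):
        prof = gc_skew_profile(small_genome, window=500, step=100)
        prof.cumulative = prof.cumulative + 100.0
        genome2, _ = simulate_genome(50_000, 0, 25_000, 0.2, seed=3)
        p = gc_skew_profile(genome2, window=5_000, step=1_000)
        base = detect_ori_ter(p)
        shifted = SkewProfile(p.genome_id, p.window, p.step, p.centers,
                              p.skew, p.cumulative + 42.0, p.zero_gc,
                              p.gc_count, p.genome_length)
        moved = detect_ori_ter(shifted)
        assert (moved.ori, moved.ter) == (base.ori, base.ter)

    def test_polarity_flip_swaps_assignment(self):
        genome, _ = simulate_genome(50_000, 0, 25_000, 0.2, seed=4)
        p = gc_skew_profile(genome, window=5_000, step=1_000)
        a = detect_ori_ter(p, polarity="g_leading")
        b = detect_ori_ter(p, polarity="c_leading")
        assert (a.ori, a.ter) == (b.ter, b.ori)


class TestFindDifSites:
    def test_single_forward_hit(self):
        seq = "TTTTTACGTTTTTTTTTTTT"
        hits = find_dif_sites(genome_from(seq), "ACGT", 0)
        fwd = [h for h in hits if h[1] == "+"]
        assert fwd == [(5, "+", 0)]

    def test_reverse_strand_hit(self):
        # reverse complement of AACCG is CGGTT
        seq = "TTTTCGGTTTTTTATTTTAT"
        hits = find_dif_sites(genome_from(seq), "AACCG", 0)
        assert (4, "-", 0) in hits
        assert all(h[1] == "-" for h in hits)

    def test_iupac_wildcard(self):
        seq = "ACGTTTTTTTTTAAGTTTTT"
        hits = find_dif_sites(genome_from(seq), "ANGT", 0)
        plus = {h[0] for h in hits if h[1] == "+"}
        assert {0, 12} <= plus

    def test_mismatch_tolerance(self):
        seq = "TTTTTACTTTTTTTTTTTTG"
        assert not [h for h in find_dif_sites(genome_from(seq), "ACGT", 0)
                    if h[1] == "+"]
        hits = find_dif_sites(genome_from(seq), "ACGT", 1)
        assert (5, "+", 1) in hits

    def test_circular_match_across_origin(self):
        seq = "GTTTTTTTTTATTTTTTTAC"  # ACGT wraps: positions 18,19,0,1
        hits = find_dif_sites(genome_from(seq), "ACGT", 0)
        assert (18, "+", 0) in hits

    def test_invalid_iupac_rejected(self, small_genome):
        with pytest.raises(ValueError, match="IUPAC"):
            find_dif_sites(small_genome, "ACXT", 0)


class TestDistanceToOri:
    def test_gene_at_ori(self, small_genome):
        start = (small_genome.ori - 50) % small_genome.length
        g = GeneRecord("g", "g1", start, small_genome.ori + 50, "+")
        assert distance_to_ori(g, small_genome) == 0

    def test_forced_by_formula(self):
        genome = CircularGenome("g", 1_000_000, 0, 500_000)
        gene = GeneRecord("x", "g", 749_950, 750_050, "+")
        assert distance_to_ori(gene, genome) == 250_000

    def test_antipodal_maximum(self):
        genome = CircularGenome("g", 1_000_000, 0, 400_000)
        gene = GeneRecord("x", "g", 499_950, 500_050, "+")
        assert distance_to_ori(gene, genome) == 500_000

    @pytest.mark.parametrize("shift", [1, 123_456, 999_999])
    def test_rotation_invariance(self, shift):
        L = 1_000_000
        rng = np.random.default_rng(5)
        for _ in range(20):
            ori = int(rng.integers(0, L))
            start = int(rng.integers(0, L))
            end = (start + 900) % L
            g0 = CircularGenome("g", L, ori, (ori + L // 2) % L)
            gene0 = GeneRecord("x", "g", start, end, "+")
            g1 = CircularGenome("g", L, (ori + shift) % L,
                                (ori + shift + L // 2) % L)
            gene1 = GeneRecord("x", "g", (start + shift) % L,
                               (end + shift) % L, "+")
            assert distance_to_ori(gene0, g0) == distance_to_ori(gene1, g1)


class TestEstimateDoublingTime:
    def test_exact_exponential_recovers_55_minutes(self):
        t = np.arange(0, 601, 30.0)
        od = 0.1 * 2 ** (t / 55.0)
        fit = estimate_doubling_time(t, od)
        assert fit.doubling_time == pytest.approx(55.0, abs=1e-6)

    def test_constant_od_is_no_growth(self):
        t = np.arange(0, 301, 30.0)
        with pytest.raises(NoGrowthDetected):
            estimate_doubling_time(t, np.full_like(t, 0.3))

    def test_noisy_recovery_within_ten_percent(self):
        errors = []
        for seed in range(100):
            t, od, _ = simulate_growth_curve(55.0, 600.0, 30.0, 0.02,
                                             seed=seed)
            fit = estimate_doubling_time(t, od)
            errors.append(abs(fit.doubling_time - 55.0) / 55.0)
        assert max(errors) < 0.10

    def test_lag_and_plateau_are_skipped(self):
        t, od, _ = simulate_growth_curve(55.0, 900.0, 30.0, 0.0, seed=0,
                                         lag_min=120.0, plateau_od=1.0)
        fit = estimate_doubling_time(t, od)
        assert fit.doubling_time == pytest.approx(55.0, rel=1e-6)
        assert fit.window[0] >= 120.0

    def test_explicit_window(self):
        t = np.arange(0, 301, 30.0)
        od = 0.1 * 2 ** (t / 40.0)
        fit = estimate_doubling_time(t, od, window=(60.0, 240.0))
        assert fit.doubling_time == pytest.approx(40.0, rel=1e-9)
        assert fit.n_points == 7

    def test_nonpositive_od_in_window_rejected(self):
        t = np.arange(0, 151, 30.0)
        od = np.array([0.1, 0.2, 0.0, 0.4, 0.5, 0.6])
        with pytest.raises(ValueError, match="non-positive"):
            estimate_doubling_time(t, od, window=(0.0, 150.0))


class TestReplicationRatio:
    def test_worked_example(self):
        p = replication_ratio_R(1_500_000, 1_000.0, 55.0)
        assert p.R_rounded == 0.23

    def test_equal_times_give_unity(self):
        # replichore time = 750 s; doubling 12.5 min = 750 s
        p = replication_ratio_R(1_500_000, 1_000.0, 12.5)
        assert p.R == pytest.approx(1.0)

    def test_inverse_proportionality_in_doubling_time(self):
        p55 = replication_ratio_R(1_500_000, 1_000.0, 55.0)
        p27 = replication_ratio_R(1_500_000, 1_000.0, 27.5)
        assert p27.R == pytest.approx(2 * p55.R)

    def test_doubling_speed_halves_R(self):
        p1 = replication_ratio_R(1_500_000, 1_000.0, 55.0)
        p2 = replication_ratio_R(1_500_000, 2_000.0, 55.0)
        assert p2.R == pytest.approx(p1.R / 2)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            replication_ratio_R(0, 1000.0, 55.0)
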