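"""Generator contracts: exact noise-free means, determinism, HWE structure."""

import numpy as np
import pandas as pd
import pytest

from clonecnv import GenomeDef, TruthEvent
from clonecnv.simulate import (
    simulate_acgh,
    simulate_annotation_tracks,
    simulate_dye_swap,
    simulate_microsat_panel,
    simulate_qpcr,
    simulate_snp_array,
)


class TestAcgh:
    def test_noise_free_gain_hits_exact_segment_mean(self, small_genome):
        ev = [TruthEvent("chr1", 2_000_000, 4_000_000, "gain", 3)]
        probes = simulate_acgh(small_genome, ev, noise_sd=0.0, seed=1)
        inside = probes[
            (probes.chromosome == "chr1")
            & (probes.position >= 2_000_000)
            & (probes.position < 4_000_000)
        ]
        outside = probes.drop(inside.index)
        assert np.allclose(inside.log2_ratio, np.log2(1.5))
        assert np.allclose(outside.log2_ratio, 0.0)

    def test_noise_free_no_events_is_identically_zero(self, small_genome):
        probes = simulate_acgh(small_genome, [], noise_sd=0.0, seed=1)
        assert (probes.log2_ratio == 0.0).all()

    def test_in_event_sample_mean_within_clt_bound(self, small_genome):
        # 3-copy gain over >= 100 probes at noise 0.15: mean within 3 sd/sqrt(n)
        ev = [TruthEvent("chr1", 2_000_000, 2_400_000, "gain", 3)]
        probes = simulate_acgh(small_genome, ev, noise_sd=0.15, seed=7)
        inside = probes[
            (probes.chromosome == "chr1")
            & (probes.position >= 2_000_000)
            & (probes.position < 2_400_000)
        ]
        n = len(inside)
        assert n >= 100
        assert abs(inside.log2_ratio.mean() - np.log2(1.5)) < 3 * 0.15 / np.sqrt(n)

    def test_positions_strictly_increasing_and_deterministic(self, small_genome):
        a = simulate_acgh(small_genome, [], noise_sd=0.15, seed=3)
        b = simulate_acgh(small_genome, [], noise_sd=0.15, seed=3)
        c = simulate_acgh(small_genome, [], noise_sd=0.15, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a.log2_ratio, c.log2_ratio)
        for _, sub in a.groupby("chromosome"):
            assert (np.diff(sub.position) > 0).all()

    def test_event_outside_bounds_rejected(self, small_genome):
        ev = [TruthEvent("chr1", 7_000_000, 9_000_000, "gain", 3)]
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            simulate_acgh(small_genome, ev, seed=0)

    def test_haploid_baseline_scales_segment_mean(self, xy_genome):
        # gain to 2 copies on a 1-copy X is log2(2/1) = 1
        ev = [TruthEvent("chrX", 1_000_000, 3_000_000, "gain", 2)]
        probes = simulate_acgh(xy_genome, ev, noise_sd=0.0, seed=1)
        inside = probes[
            (probes.chromosome == "chrX")
            & (probes.position >= 1_000_000)
            & (probes.position < 3_000_000)
        ]
        assert np.allclose(inside.log2_ratio, 1.0)


class TestDyeSwap:
    def test_noise_free_swap_negates_event_signal(self, small_genome):
        ev = [TruthEvent("chr1", 2_000_000, 4_000_000, "gain", 3)]
        fwd = simulate_acgh(small_genome, ev, noise_sd=0.0, seed=1)
        swap = simulate_dye_swap(fwd, ev, noise_sd=0.0, seed=2)
        assert np.allclose(swap.log2_ratio, -fwd.log2_ratio)
        assert (swap.position == fwd.position).all()

    def test_no_events_noise_free_both_zero(self, small_genome):
        fwd = simulate_acgh(small_genome, [], noise_sd=0.0, seed=1)
        swap = simulate_dye_swap(fwd, [], noise_sd=0.0, seed=2)
        assert (fwd.log2_ratio == 0).all() and (swap.log2_ratio == 0).all()

    def test_noise_is_independent_between_channels(self):
        # corr(forward, swap) strongly negative over in-event probes, ~0 over neutral
        genome = GenomeDef([("chr1", 40_000_000)])
        ev = [TruthEvent("chr1", 0, 20_000_000, "gain", 3)]
        fwd = simulate_acgh(genome, ev, probe_spacing=3300, noise_sd=0.15, seed=5)
        swap = simulate_dye_swap(fwd, ev, noise_sd=0.15, seed=6)
        inside = fwd.position < 20_000_000
        r_all = np.corrcoef(fwd.log2_ratio, swap.log2_ratio)[0, 1]
        r_out = np.corrcoef(fwd.log2_ratio[~inside], swap.log2_ratio[~inside])[0, 1]
        # the flipped segment means induce anticorrelation across the mixture
        assert r_all < -0.5
        # but the noise itself is fresh: neutral probes are uncorrelated,
        # and in-event residuals around the segment means are too
        assert abs(r_out) < 0.1
        res_f = fwd.log2_ratio[inside] - np.log2(1.5)
        res_s = swap.log2_ratio[inside] + np.log2(1.5)
        assert abs(np.corrcoef(res_f, res_s)[0, 1]) < 0.1


class TestSnpArray:
    def test_three_copy_het_bands_exact_without_noise(self, small_genome):
        ev = [TruthEvent("chr1", 1_000_000, 6_000_000, "gain", 3)]
        snps = simulate_snp_array(small_genome, ev, baf_noise_sd=0.0, lrr_noise_sd=0.0, seed=2)
        inside = snps[
            (snps.chromosome == "chr1")
            & (snps.position >= 1_000_000)
            & (snps.position < 6_000_000)
        ]
        het = inside[(inside.baf > 0) & (inside.baf < 1)]
        assert len(het) > 20
        assert set(np.round(het.baf, 9)) <= {round(1 / 3, 9), round(2 / 3, 9)}
        assert np.allclose(inside.lrr, np.log2(1.5))

    def test_cn_loh_removes_het_band_and_keeps_lrr_neutral(self, small_genome):
        ev = [TruthEvent("chr2", 1_000_000, 7_000_000, "cn_loh", 2)]
        snps = simulate_snp_array(small_genome, ev, seed=3)
        inside = snps[
            (snps.chromosome == "chr2")
            & (snps.position >= 1_000_000)
            & (snps.position < 7_000_000)
        ]
        assert ((inside.baf <= 0.2) | (inside.baf >= 0.8)).all()
        assert abs(inside.lrr.mean()) < 0.05

    def test_zero_het_rate_handled(self, small_genome):
        snps = simulate_snp_array(small_genome, [], het_rate=0.0, seed=4)
        assert ((snps.baf <= 0.2) | (snps.baf >= 0.8)).all()

    def test_baf_stays_in_unit_interval(self, small_genome):
        snps = simulate_snp_array(small_genome, [], baf_noise_sd=0.2, seed=5)
        assert snps.baf.between(0, 1).all()

    def test_conflicting_overlapping_events_rejected(self, small_genome):
        evs = [
            TruthEvent("chr1", 1_000_000, 3_000_000, "gain", 3),
            TruthEvent("chr1", 2_000_000, 4_000_000, "cn_loh", 2),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            simulate_snp_array(small_genome, evs, seed=0)


class TestQpcr:
    @pytest.mark.parametrize("cn,fold", [(2, 1.0), (3, 1.5), (1, 0.5)])
    def test_noise_free_fold_recovery(self, cn, fold):
        from clonecnv.qpcr import ddct_fold_change

        assay = simulate_qpcr(cn, ct_noise_sd=0.0, seed=0)
        assert ddct_fold_change(assay) == pytest.approx(fold, abs=1e-12)

    def test_replicate_count_and_validation(self):
        assay = simulate_qpcr(2, replicates=3, seed=1)
        assert len(assay.sample_target) == 3
        with pytest.raises(ValueError):
            simulate_qpcr(0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_qpcr(2, replicates=0, seed=1)


class TestAnnotationTracks:
    def test_zero_intervals_gives_empty_tracks(self, small_genome):
        tracks = simulate_annotation_tracks(small_genome, n_intervals=0, seed=0)
        assert all(len(t) == 0 for t in tracks.values())

    def test_reproducible_and_within_bounds(self, small_genome):
        a = simulate_annotation_tracks(small_genome, n_intervals=20, seed=9)
        b = simulate_annotation_tracks(small_genome, n_intervals=20, seed=9)
        for track in a:
            assert [(i.chromosome, i.start, i.end) for i in a[track]] == [
                (i.chromosome, i.start, i.end) for i in b[track]
            ]
            for iv in a[track]:
                assert 0 <= iv.start < iv.end <= small_genome.length(iv.chromosome)
        assert all(iv.cls in ("LINE", "SINE", "LTR") for iv in a["repeat"])

    def test_density_cap_rejects_overfull_chromosome(self):
        tiny = GenomeDef([("chr1", 200_000)])
        with pytest.raises(ValueError, match="density cap"):
            simulate_annotation_tracks(tiny, n_intervals=50, size_range=(50_000, 60_000), seed=0)


class TestMicrosatPanel:
    def test_monomorphic_locus_everyone_homozygous(self):
        gt = simulate_microsat_panel({"L1": [1.0]}, 50, seed=0)
        assert (gt.allele1 == 0).all() and (gt.allele2 == 0).all()

    def test_het_fraction_approaches_hwe_expectation(self):
        gt = simulate_microsat_panel({"L1": [0.5, 0.5]}, 100_000, seed=1)
        het = (gt.allele1 != gt.allele2).mean()
        assert abs(het - 0.5) < 0.01

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            simulate_microsat_panel({"L1": [0.5, 0.4]}, 10, seed=0)
        with pytest.raises(ValueError, match="negative"):
            simulate_microsat_panel({"L1": [1.5, -0.5]}, 10, seed=0)
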