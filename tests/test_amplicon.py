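import numpy as np
import pytest

from hypertx import (
    RegionSet,
    SimConfig,
    detect_summits,
    loess_fit,
    make_genome,
    make_track,
    simulate_pair,
    smooth_curve,
    tile_counts,
    window_fold_change,
)
from hypertx.amplicon import TileCurve

from conftest import make_fs, tiling_fragments


def bg_only_cfg(**kw):
    """Single promoter element on a 2-Mb chromosome, background-dominated.

    The promoter still receives the whole region share (3% of emissions),
    giving a visible central peak for summit-anchoring tests.
    """
    defaults = dict(
        chrom_lengths=(2_000_000,), chrM_length=16_000,
        n_ccres=1, ccre_class_mix={"promoter": 1.0}, ccre_width=1000,
        histone_cluster=None,
        p_background=0.95, p_chrM_normal=0.02, chrM_depletion_factor=1.0,
        n_fragments=200_000,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def spike_free_cfg(**kw):
    """Like bg_only_cfg but the region pool share is negligible (0.01%)."""
    return bg_only_cfg(p_background=0.96, p_chrM_normal=0.0399, **kw)


class TestTileCounts:
    def test_uniform_track_bins(self, toy_genome):
        fs = make_fs(toy_genome, tiling_fragments(toy_genome, step=100))
        track = make_track(fs, toy_genome)
        tc = tile_counts(track, track, ("chr1", 0, 1000), bin_size=100)
        assert np.allclose(tc.tumor, 100.0)  # 1.0 per bp x 100 bp bins
        assert np.array_equal(tc.tumor, tc.normal)

    def test_single_fragment_bin_sum(self, flat_genome):
        fs = make_fs(flat_genome, [("chr1", 0, 10)])
        track = make_track(fs, flat_genome)
        tc = tile_counts(track, track, ("chr1", 0, 100), bin_size=50)
        assert tc.tumor[0] == pytest.approx(100.0)  # 10 bp x value 10
        assert tc.tumor[1] == 0.0

    def test_partial_last_bin(self, flat_genome):
        fs = make_fs(flat_genome, [("chr1", 0, 100)])
        track = make_track(fs, flat_genome)
        tc = tile_counts(track, track, ("chr1", 0, 100), bin_size=30)
        assert tc.n_bins == 4
        assert tc.tumor[-1] == pytest.approx(10.0)  # 10 bp remainder

    def test_bad_bin_size_rejected(self, flat_genome):
        fs = make_fs(flat_genome, [("chr1", 0, 10)])
        track = make_track(fs, flat_genome)
        with pytest.raises(ValueError, match="bin_size"):
            tile_counts(track, track, ("chr1", 0, 100), bin_size=0)

    def test_window_out_of_bounds_rejected(self, flat_genome):
        fs = make_fs(flat_genome, [("chr1", 0, 10)])
        track = make_track(fs, flat_genome)
        with pytest.raises(ValueError, match="outside genome"):
            tile_counts(track, track, ("chr1", 0, 500), bin_size=10)


class TestLoessFit:
    def test_constant_series_unchanged(self):
        y = np.full(50, 3.25)
        assert np.allclose(loess_fit(y, span=0.3), 3.25)

    def test_exact_on_noiseless_quadratic(self):
        x = np.arange(100, dtype=float)
        y = 2.0 + 0.5 * x + 0.01 * x**2
        fit = loess_fit(y, span=0.3)
        assert np.allclose(fit, y, rtol=1e-6)

    def test_variance_reduction_on_noisy_quadratic(self):
        x = np.arange(200, dtype=float)
        truth = 0.002 * (x - 100) ** 2
        sigma = 5.0
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = truth + rng.normal(0, sigma, x.size)
            rmse = np.sqrt(np.mean((loess_fit(y, span=0.2) - truth) ** 2))
            wins += rmse < sigma
        assert wins == 20

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            loess_fit(np.zeros(20), span=0.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            loess_fit(np.zeros(5), span=0.5)

    def test_tiny_window_falls_back_to_linear(self, caplog):
        import logging

        y = np.arange(20, dtype=float)
        with caplog.at_level(logging.INFO, logger="hypertx.amplicon"):
            fit = loess_fit(y, span=0.12)  # 3-point windows
        assert np.allclose(fit, y, atol=1e-8)  # linear fit is exact on a line
        assert any("degree 1" in rec.message for rec in caplog.records)


class TestDetectSummits:
    def test_flat_excess_no_summits(self):
        tc = TileCurve(chrom="chr1", start=0, end=100_000, bin_size=1000,
                       tumor=np.ones(100), normal=np.ones(100), span=0.2,
                       tumor_smooth=np.ones(100), normal_smooth=np.ones(100))
        assert detect_summits(tc) == []

    def test_unsmoothed_curve_rejected(self):
        tc = TileCurve(chrom="chr1", start=0, end=100_000, bin_size=1000,
                       tumor=np.ones(100), normal=np.ones(100))
        with pytest.raises(ValueError, match="smooth"):
            detect_summits(tc)

    def _summit_sim(self, seed, extra=3.0, sd=42_500.0):
        cfg0 = bg_only_cfg(seed=seed)
        genome, regions = make_genome(cfg0)
        prom = regions[0]
        c = int(prom.center)
        assert 350_000 < c < 1_650_000, "seed places the promoter too close to an edge"
        cfg = bg_only_cfg(seed=seed,
                          amplicon=("chr1", c - 150_000, c + 150_000, 2.0),
                          summits=((float(c), sd, extra),))
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        tt, nt = make_track(tumor, genome), make_track(normal, genome)
        tc = smooth_curve(
            tile_counts(tt, nt, ("chr1", c - 300_000, c + 300_000), 1000), span=0.2
        )
        return tc, prom, c

    def test_planted_summit_centered_on_promoter(self):
        tc, prom, c = self._summit_sim(seed=5)
        summits = detect_summits(tc, anchors=RegionSet([prom]))
        top = summits[0]
        assert abs(top.center - prom.center) <= 5_000
        assert top.anchor_offset <= 5_000
        # width within 2x of the planted FWHM (2.355 * 42.5 kb ~ 100 kb)
        fwhm = 2.355 * 42_500
        assert fwhm / 2 <= top.width_at_half_prominence <= 2 * fwhm * 2

    def test_two_summits_recovered(self):
        cfg = spike_free_cfg(
            seed=3,
            amplicon=("chr1", 500_000, 1_300_000, 2.0),
            summits=((750_000.0, 30_000.0, 3.0), (1_050_000.0, 30_000.0, 3.0)),
        )
        genome, regions = make_genome(cfg)
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        tc = smooth_curve(
            tile_counts(make_track(tumor, genome), make_track(normal, genome),
                        ("chr1", 400_000, 1_400_000), 1000), span=0.2
        )
        top2 = sorted(s.center for s in detect_summits(tc)[:2])
        assert abs(top2[0] - 750_000) <= 10_000
        assert abs(top2[1] - 1_050_000) <= 10_000

    def test_shift_equivariance(self):
        genome, regions = make_genome(spike_free_cfg(seed=6))
        centers = []
        for delta in (0, 120_000):
            c = 800_000 + delta
            cfg = spike_free_cfg(seed=6,
                                 amplicon=("chr1", c - 150_000, c + 150_000, 2.0),
                                 summits=((float(c), 40_000.0, 3.0),))
            tumor, normal, _ = simulate_pair(cfg, genome, regions)
            tc = smooth_curve(
                tile_counts(make_track(tumor, genome), make_track(normal, genome),
                            ("chr1", c - 300_000, c + 300_000), 1000), span=0.2
            )
            centers.append(detect_summits(tc)[0].center)
        assert abs((centers[1] - centers[0]) - 120_000) <= 1_000


class TestAmpliconRecovery:
    def _ratio(self, copy_number, seed):
        cfg = spike_free_cfg(seed=seed,
                             amplicon=("chr1", 1_400_000, 1_700_000, copy_number))
        genome, regions = make_genome(cfg)
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        tc = tile_counts(make_track(tumor, genome), make_track(normal, genome),
                         ("chr1", 0, 2_000_000), 1000)
        centers = tc.bin_centers()
        inside = (centers >= 1_400_000) & (centers < 1_700_000)
        ok = tc.normal > 0
        ratios = tc.tumor[ok] / tc.normal[ok]
        return ratios[inside[ok]].mean() / ratios[~inside[ok]].mean()

    @pytest.mark.parametrize("copy_number", [1.5, 2.0, 3.0])
    def test_copy_number_linearity(self, copy_number):
        assert self._ratio(copy_number, seed=4) == pytest.approx(copy_number, rel=0.1)

    def test_boundary_recovery_within_two_bins(self):
        cfg = spike_free_cfg(seed=5, amplicon=("chr1", 850_000, 1_150_000, 2.0))
        genome, regions = make_genome(cfg)
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        tt, nt = make_track(tumor, genome), make_track(normal, genome)
        for bound in (850_000, 1_150_000):
            tc = smooth_curve(
                tile_counts(tt, nt, ("chr1", bound - 150_000, bound + 150_000), 1000),
                span=0.2,
            )
            step = np.diff(tc.excess_smooth)
            k = int(np.argmax(np.abs(step)))
            detected = bound - 150_000 + (k + 1) * 1000
            assert abs(detected - bound) <= 2_000


class TestWindowFoldChange:
    def test_identical_tracks_unity(self, toy_genome):
        fs = make_fs(toy_genome, tiling_fragments(toy_genome, step=100))
        track = make_track(fs, toy_genome)
        assert window_fold_change(track, track, ("chr1", 0, 500)) == pytest.approx(1.0)

    def test_planted_multiplier_recovered(self):
        cfg = spike_free_cfg(seed=7, amplicon=("chr1", 995_000, 1_005_000, 5.4))
        genome, regions = make_genome(cfg)
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        fc = window_fold_change(make_track(tumor, genome), make_track(normal, genome),
                                ("chr1", 995_000, 1_005_000))
        assert fc == pytest.approx(5.4, rel=0.1)

    def test_null_window_near_unity(self):
        cfg = spike_free_cfg(seed=7, amplicon=("chr1", 995_000, 1_005_000, 5.4))
        genome, regions = make_genome(cfg)
        tumor, normal, _ = simulate_pair(cfg, genome, regions)
        fc = window_fold_change(make_track(tumor, genome), make_track(normal, genome),
                                ("chr1", 200_000, 400_000))
        assert fc == pytest.approx(1.0, abs=0.1)

    def test_zero_normal_flagged_nan(self, flat_genome):
        t = make_track(make_fs(flat_genome, [("chr1", 0, 10)]), flat_genome)
        n = make_track(make_fs(flat_genome, [("chr1", 50, 60)]), flat_genome)
        assert np.isnan(window_fold_change(t, n, ("chr1", 0, 10)))
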