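"""Release metric, Kruskal-Wallis statistics and gel densitometry."""

import numpy as np
import pytest
from scipy import stats

import presynquant as pq


class TestMeasureBoutons:
    def test_metric_algebra(self):
        f0 = pq.ImageStack([pq.PixelImage(np.full((4, 4), 100.0), 20)])
        fmax = pq.ImageStack([pq.PixelImage(np.full((4, 4), 200.0), 20)])
        rois = np.ones((4, 4), dtype=int)
        (b,) = pq.measure_boutons(f0, fmax, rois)
        assert b.release_metric == pytest.approx(0.5)

    def test_equal_frames_zero_metric(self):
        img = pq.ImageStack([pq.PixelImage(np.full((4, 4), 80.0), 20)])
        (b,) = pq.measure_boutons(img, img, np.ones((4, 4), dtype=int))
        assert b.release_metric == 0.0
        assert not b.negative_flag

    def test_simulated_noisefree_exact(self):
        config = pq.SimulationConfig(poisson_gain=0.0, gaussian_sd=0.0)
        f0, fmax, rois, truth = pq.generate_phluorin_pair(
            config, n_boutons=10, release_fractions=np.full(10, 0.3)
        )
        boutons = pq.measure_boutons(f0, fmax, rois)
        assert len(boutons) == 10
        for b in boutons:
            assert b.release_metric == pytest.approx(0.3, abs=1e-12)

    def test_gain_invariance(self):
        config = pq.SimulationConfig(seed=8, poisson_gain=0.0, gaussian_sd=0.0)
        f0, fmax, rois, _ = pq.generate_phluorin_pair(config, n_boutons=5)
        m1 = [b.release_metric for b in pq.measure_boutons(f0, fmax, rois)]
        scale = 11.0
        f0s = pq.ImageStack([pq.PixelImage(p.values * scale, p.pixel_size_nm) for p in f0.planes])
        fmaxs = pq.ImageStack(
            [pq.PixelImage(p.values * scale, p.pixel_size_nm) for p in fmax.planes]
        )
        m2 = [b.release_metric for b in pq.measure_boutons(f0s, fmaxs, rois)]
        np.testing.assert_allclose(m1, m2)

    def test_negative_metric_flagged_not_clamped(self):
        f0 = pq.ImageStack([pq.PixelImage(np.full((4, 4), 100.0), 20)])
        fmax = pq.ImageStack([pq.PixelImage(np.full((4, 4), 80.0), 20)])
        (b,) = pq.measure_boutons(f0, fmax, np.ones((4, 4), dtype=int))
        assert b.release_metric < 0
        assert b.negative_flag

    def test_grid_mismatch_rejected(self):
        f0 = pq.ImageStack([pq.PixelImage(np.zeros((4, 4)), 20)])
        with pytest.raises(ValueError):
            pq.measure_boutons(f0, f0, np.ones((5, 5), dtype=int))


class TestKruskalWallis:
    def test_equal_rank_sums_zero(self):
        assert pq.kruskal_wallis([[1, 4], [2, 3]]).h_statistic == pytest.approx(0.0)

    def test_hand_ranked_example(self):
        # ranks 1,2 vs 3,4: H = 12/(4*5) * (9/2 + 49/2) - 15 = 2.4
        result = pq.kruskal_wallis([[1, 2], [3, 4]])
        assert result.h_statistic == pytest.approx(2.4)

    def test_all_identical_defined(self):
        result = pq.kruskal_wallis([[5, 5], [5, 5, 5]])
        assert result.h_statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_scipy_with_ties(self, rng):
        """Independent cross-check incl. mid-rank tie correction."""
        for _ in range(20):
            groups = [
                rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
                for _ in range(rng.integers(2, 5))
            ]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            ours = pq.kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert ours.h_statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 1, 12), rng.normal(1, 1, 9)]
        h0 = pq.kruskal_wallis(groups).h_statistic
        transformed = [np.exp(g) for g in groups]  # strictly monotone
        assert pq.kruskal_wallis(transformed).h_statistic == pytest.approx(h0)

    def test_agrees_with_permutation_p(self, rng):
        """Chi-square p tracks a permutation reference on small datasets."""
        n_perm = 4000
        for _ in range(5):
            groups = [rng.normal(rng.uniform(0, 0.8), 1, 12) for _ in range(3)]
            result = pq.kruskal_wallis(groups)
            pooled = np.concatenate(groups)
            sizes = [len(g) for g in groups]
            h_null = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(pooled)
                parts = np.split(perm, np.cumsum(sizes)[:-1])
                h_null[b] = pq.kruskal_wallis(parts).h_statistic
            p_perm = (1 + (h_null >= result.h_statistic - 1e-12).sum()) / (1 + n_perm)
            mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
            # chi-square approximation error + Monte-Carlo error allowance
            assert abs(result.p_value - p_perm) <= 0.02 + 3 * mc_sd

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pq.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            pq.kruskal_wallis([[1.0], []])


class TestDunnPosthoc:
    def test_holm_never_below_raw(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 2.0)]
        comparison = pq.kruskal_wallis(groups)
        table = pq.dunn_posthoc(comparison)
        assert (table["p_holm"] >= table["p_raw"] - 1e-12).all()
        assert len(table) == 3

    def test_extreme_separation_detected(self, rng):
        groups = [rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)]
        table = pq.dunn_posthoc(pq.kruskal_wallis(groups))
        assert table["p_holm"].iloc[0] < 0.001


class TestDensitometry:
    def test_lane_profile_row_sums(self, rng):
        img = rng.random((30, 20))
        profile = pq.lane_profile(img, (5, 3, 10, 8))
        np.testing.assert_allclose(profile, img[5:15, 3:11].sum(axis=1))

    def test_flat_band_auc(self):
        profile = np.zeros(30)
        profile[10:18] = 7.0  # h=7 over w=8 rows
        assert pq.band_auc(profile) == pytest.approx(56.0)

    def test_chord_baseline_removes_linear_offset(self):
        rows = np.arange(40, dtype=float)
        baseline = 2.0 + 0.5 * rows
        band = np.zeros(40)
        band[15:25] = 9.0
        auc = pq.band_auc(baseline + band)
        assert auc == pytest.approx(90.0, rel=1e-6)

    def test_band_ratio(self):
        control, treated = pq.band_ratio(30.0, 5.0, control_pair=(10.0, 5.0))
        assert control == 1.0
        assert treated == pytest.approx(3.0)
        same, ratio = pq.band_ratio(10.0, 5.0, control_pair=(10.0, 5.0))
        assert ratio == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pq.band_ratio(10.0, 0.0, control_pair=(10.0, 5.0))

    def test_lane_rectangle_bounds_checked(self):
        with pytest.raises(ValueError):
            pq.lane_profile(np.zeros((10, 10)), (5, 5, 10, 3))
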