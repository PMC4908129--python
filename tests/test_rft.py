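"""RFT cluster correction: quantile/labeling oracles, smoothness recovery."""

from collections import deque

import numpy as np
import pytest
from scipy import integrate, optimize, special, stats
from scipy.ndimage import gaussian_filter

from voxelwise.rft import (
    apply_cluster_correction,
    cluster_forming_threshold,
    estimate_smoothness,
    fdr_threshold,
    label_clusters,
    rft_cluster_size_threshold,
)
from voxelwise.synth import smooth_volume
from voxelwise.volio import mask_from_array


def t_quantile_oracle(p, df):
    """Upper-tail T quantile by numerical integration of the density."""

    def density(x):
        c = special.gamma((df + 1) / 2) / (
            np.sqrt(df * np.pi) * special.gamma(df / 2)
        )
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    def tail(t):
        val, _ = integrate.quad(density, t, np.inf)
        return val - p

    return optimize.brentq(tail, 0.0, 200.0, xtol=1e-12)


def flood_fill_oracle(binary3d):
    """Breadth-first 6-connectivity labeling, pure Python."""
    labels = np.zeros(binary3d.shape, dtype=int)
    nxt = 0
    shape = binary3d.shape
    for start in zip(*np.nonzero(binary3d)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            i, j, k = q.popleft()
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = i + di, j + dj, k + dk
                if (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
                        and binary3d[ni, nj, nk] and not labels[ni, nj, nk]):
                    labels[ni, nj, nk] = nxt
                    q.append((ni, nj, nk))
    return labels, nxt


class TestClusterFormingThreshold:
    def test_median_is_zero(self):
        assert cluster_forming_threshold(0.5, 13) == 0.0

    @pytest.mark.parametrize("p,df", [(0.001, 269), (0.01, 30), (0.05, 5)])
    def test_matches_numeric_integration_oracle(self, p, df):
        assert np.isclose(
            cluster_forming_threshold(p, df), t_quantile_oracle(p, df), atol=1e-6
        )

    def test_gaussian_limit_at_large_df(self):
        t = cluster_forming_threshold(0.001, 1e7)
        assert np.isclose(t, 3.0902, atol=1e-3)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            cluster_forming_threshold(0.0, 10)
        with pytest.raises(ValueError):
            cluster_forming_threshold(1.5, 10)


class TestSmoothness:
    def test_white_noise_has_unit_scale_fwhm(self, rng):
        geom = mask_from_array(np.ones((30, 30, 30)))
        fwhms = []
        for _ in range(20):
            resid = rng.standard_normal((8, geom.tau))
            f, _ = estimate_smoothness(resid, geom)
            fwhms.append(f)
        mean_fwhm = np.mean(fwhms, axis=0)
        assert np.all(np.abs(mean_fwhm - 1.0) < 0.2)

    def test_recovers_applied_smoothing(self, rng):
        geom = mask_from_array(np.ones((32, 32, 32)))
        target = 4.0
        resid = np.stack(
            [
                smooth_volume(rng.standard_normal((32, 32, 32)), target, mode="wrap")
                .ravel(order="F")[geom.voxel_index]
                for _ in range(10)
            ]
        )
        fwhm, resel = estimate_smoothness(resid, geom)
        assert np.all(np.abs(np.array(fwhm) - target) / target < 0.15)

    def test_resel_count_proportional_to_tau(self, rng):
        geom1 = mask_from_array(np.ones((20, 20, 10)))
        geom2 = mask_from_array(np.ones((20, 20, 20)))
        resid1 = rng.standard_normal((6, geom1.tau))
        # identical smoothness (white noise), double tau
        resid2 = rng.standard_normal((6, geom2.tau))
        _, r1 = estimate_smoothness(resid1, geom1)
        _, r2 = estimate_smoothness(resid2, geom2)
        assert np.isclose(r2 / r1, 2.0, rtol=0.05)

    def test_constant_residuals_rejected(self):
        geom = mask_from_array(np.ones((10, 10, 10)))
        with pytest.raises(ValueError, match="constant"):
            estimate_smoothness(np.ones((5, geom.tau)), geom)


class TestLabeling:
    def test_face_adjacent_voxels_share_cluster(self):
        geom = mask_from_array(np.ones((4, 4, 4)))
        stat = np.zeros(geom.tau)
        stat[[0, 1]] = 5.0  # (0,0,0) and (1,0,0)
        labels, sizes = label_clusters(stat, geom, 2.0)
        assert sizes.tolist() == [2]

    def test_diagonal_voxels_do_not_connect_at_6(self):
        geom = mask_from_array(np.ones((4, 4, 4)))
        stat = np.zeros(geom.tau)
        stat[[0, 5]] = 5.0  # (0,0,0) and (1,1,0)
        labels, sizes = label_clusters(stat, geom, 2.0)
        assert len(sizes) == 2

    def test_matches_flood_fill_oracle_on_random_maps(self, rng):
        geom = mask_from_array(np.ones((16, 16, 16)))
        for _ in range(20):
            binary = rng.random((16, 16, 16)) < 0.3
            stat = np.where(binary.ravel(order="F")[geom.voxel_index], 5.0, 0.0)
            labels, sizes = label_clusters(stat, geom, 2.0)
            oracle_labels, n = flood_fill_oracle(binary)
            assert len(sizes) == n
            # same partition: label images agree up to renaming
            ours = labels
            theirs = oracle_labels.ravel(order="F")[geom.voxel_index]
            assert np.array_equal(ours > 0, theirs > 0)
            pairs = {(a, b) for a, b in zip(ours, theirs) if a}
            assert len({a for a, _ in pairs}) == len(pairs)
            assert len({b for _, b in pairs}) == len(pairs)

    def test_empty_suprathreshold_set(self):
        geom = mask_from_array(np.ones((4, 4, 4)))
        labels, sizes = label_clusters(np.zeros(geom.tau), geom, 2.0)
        assert sizes.size == 0
        assert np.all(labels == 0)


class TestClusterSizeThreshold:
    GEOM = mask_from_array(np.ones((40, 40, 40)))

    def test_loose_cluster_p_keeps_everything(self):
        k = rft_cluster_size_threshold(1.0 - 1e-9, 3.1, 50, (3, 3, 3), self.GEOM)
        assert k == 1

    def test_monotone_in_cluster_p(self):
        k05 = rft_cluster_size_threshold(0.05, 3.1, 50, (3, 3, 3), self.GEOM)
        k01 = rft_cluster_size_threshold(0.01, 3.1, 50, (3, 3, 3), self.GEOM)
        assert k01 >= k05 >= 1

    def test_monotone_in_smoothness(self):
        k_smooth = rft_cluster_size_threshold(0.05, 3.1, 50, (4, 4, 4), self.GEOM)
        k_rough = rft_cluster_size_threshold(0.05, 3.1, 50, (2, 2, 2), self.GEOM)
        assert k_smooth >= k_rough

    def test_degenerate_smoothness_rejected(self):
        with pytest.raises(ValueError, match="smoothness"):
            rft_cluster_size_threshold(0.05, 3.1, 50, (0, 3, 3), self.GEOM)

    def test_threshold_below_ec_validity_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            rft_cluster_size_threshold(0.05, 0.5, None, (3, 3, 3), self.GEOM)

    def test_null_field_fwe_within_band(self, rng):
        """Monte-Carlo check of the whole correction at nominal 0.05."""
        geom = self.GEOM
        u = stats.norm.isf(0.001)
        k = rft_cluster_size_threshold(0.05, u, None, (3.0, 3.0, 3.0), geom)
        sigma = 3.0 / (2 * np.sqrt(2 * np.log(2)))
        hits = 0
        n_fields = 200
        for _ in range(n_fields):
            f = gaussian_filter(rng.standard_normal((40, 40, 40)), sigma, mode="wrap")
            f /= f.std()
            _, sizes = label_clusters(f.ravel(order="F")[geom.voxel_index], geom, u)
            if sizes.size and sizes.max() >= k:
                hits += 1
        assert 0.01 <= hits / n_fields <= 0.12


class TestApplyCorrection:
    GEOM = mask_from_array(np.ones((10, 10, 10)))

    def _blob_stat(self, blobs):
        vol = np.zeros((10, 10, 10))
        for lo, hi, val in blobs:
            vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = val
        return vol.ravel(order="F")[self.GEOM.voxel_index]

    def test_nothing_above_threshold(self):
        out, report = apply_cluster_correction(
            np.zeros(self.GEOM.tau), self.GEOM, 3.0, 5
        )
        assert not report.clusters
        assert np.all(out == 0)

    def test_large_blob_survives_intact(self):
        stat = self._blob_stat([((0, 0, 0), (5, 2, 1), 4.0)])  # 10 voxels
        out, report = apply_cluster_correction(stat, self.GEOM, 3.0, 5)
        assert [c["size"] for c in report.clusters] == [10]
        assert np.count_nonzero(out) == 10

    def test_small_blob_removed_large_kept(self):
        stat = self._blob_stat(
            [((0, 0, 0), (3, 1, 1), 4.0), ((5, 5, 5), (9, 3 + 5, 1 + 5), 6.0)]
        )
        out, report = apply_cluster_correction(stat, self.GEOM, 3.0, 5)
        assert [c["size"] for c in report.clusters] == [12]
        assert report.clusters[0]["peak"] == 6.0
        assert np.count_nonzero(out) == 12

    def test_correction_monotone_in_thresholds(self, rng):
        stat = rng.standard_normal(self.GEOM.tau) * 2
        base, _ = apply_cluster_correction(stat, self.GEOM, 1.5, 3)
        higher_t, _ = apply_cluster_correction(stat, self.GEOM, 2.0, 3)
        higher_k, _ = apply_cluster_correction(stat, self.GEOM, 1.5, 6)
        assert set(np.flatnonzero(higher_t)) <= set(np.flatnonzero(base))
        assert set(np.flatnonzero(higher_k)) <= set(np.flatnonzero(base))


class TestFDR:
    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500) ** 2
        rejected, cutoff = fdr_threshold(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(rejected, ref)

    def test_no_rejections_when_uniform_high(self):
        p = np.linspace(0.5, 1.0, 100)
        rejected, cutoff = fdr_threshold(p, 0.05)
        assert not rejected.any() and cutoff == 0.0
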