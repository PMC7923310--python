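"""Metric correctness against independent brute-force oracles and
analytic limits."""

import numpy as np
import pytest
from scipy import stats

import rfmri_sexdiff as rsd
from rfmri_sexdiff.metrics import NEIGHBORHOOD_OFFSETS, R_CLIP


# ---------------------------------------------------------------------------
# brute-force oracles: direct loops over the definitions


def _pearson(a, b):
    return np.corrcoef(a, b)[0, 1]


def _fisher(r):
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def oracle_seed_ifc(bold, seed_mask):
    seed = bold.data[seed_mask].mean(axis=0)
    out = np.zeros(bold.mask.shape)
    for idx in np.argwhere(bold.mask):
        out[tuple(idx)] = _fisher(_pearson(bold.data[tuple(idx)], seed))
    return out


def oracle_vmhc(bold):
    nx = bold.mask.shape[0]
    out = np.zeros(bold.mask.shape)
    for i, j, k in np.argwhere(bold.mask):
        out[i, j, k] = _fisher(_pearson(bold.data[i, j, k], bold.data[nx - 1 - i, j, k]))
    return out


def oracle_kendall_w(series):
    K, n = series.shape
    ranks = np.array([stats.rankdata(s) for s in series])
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    ties = sum(
        (c**3 - c).sum() for c in
        (np.unique(s, return_counts=True)[1] for s in series)
    )
    return 12 * S / (K**2 * (n**3 - n) - K * ties)


def oracle_reho(bold, neighborhood=27):
    offs = NEIGHBORHOOD_OFFSETS[neighborhood]
    shape = bold.mask.shape
    out = np.zeros(shape)
    for i, j, k in np.argwhere(bold.mask):
        members = []
        for dx, dy, dz in offs:
            x, y, z = i + dx, j + dy, k + dz
            if 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
                if bold.mask[x, y, z]:
                    members.append(bold.data[x, y, z])
        if len(members) < 5:  # voxel + at least 4 neighbours
            continue
        out[i, j, k] = oracle_kendall_w(np.array(members))
    return out


def oracle_dc(bold, thr=0.25):
    vox = np.argwhere(bold.mask)
    series = np.array([bold.data[tuple(v)] for v in vox])
    out = np.zeros(bold.mask.shape)
    for a in range(len(vox)):
        deg = 0
        for b in range(len(vox)):
            if a != b:
                r = _pearson(series[a], series[b])
                if r > thr:
                    deg += 1
        out[tuple(vox[a])] = deg
    return out


def oracle_falff(bold, band=(0.01, 0.1)):
    out = np.zeros(bold.mask.shape)
    freqs = np.fft.rfftfreq(bold.n_timepoints, bold.tr)
    for idx in np.argwhere(bold.mask):
        x = bold.data[tuple(idx)]
        amp = np.abs(np.fft.rfft(x - x.mean()))
        pos = freqs > 0
        inb = pos & (freqs >= band[0]) & (freqs <= band[1])
        out[tuple(idx)] = amp[inb].sum() / amp[pos].sum()
    return out


class TestBruteForceOracles:
    def test_seed_ifc(self, tiny_bold):
        seed = np.zeros(tiny_bold.mask.shape, bool)
        seed[2:4, 2:4, 1:3] = True
        got = rsd.seed_ifc(tiny_bold, seed).data
        np.testing.assert_allclose(got, oracle_seed_ifc(tiny_bold, seed), atol=1e-10)

    def test_vmhc(self, tiny_bold):
        got = rsd.vmhc(tiny_bold).data
        np.testing.assert_allclose(got, oracle_vmhc(tiny_bold), atol=1e-10)

    def test_reho(self, tiny_bold):
        got = rsd.reho(tiny_bold).data
        np.testing.assert_allclose(got, oracle_reho(tiny_bold), atol=1e-10)

    def test_dc(self, tiny_bold):
        got = rsd.degree_centrality(tiny_bold).data
        np.testing.assert_allclose(got, oracle_dc(tiny_bold), atol=1e-10)

    def test_falff(self, tiny_bold):
        got = rsd.falff(tiny_bold).data
        np.testing.assert_allclose(got, oracle_falff(tiny_bold), atol=1e-10)


class TestKendallW:
    def test_identical_series_give_one(self, rng):
        w = rsd.kendall_w(np.tile(rng.standard_normal(12), (27, 1)))
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_two_reversed_rankings_give_zero(self):
        assert rsd.kendall_w(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])) == 0

    def test_hand_computed_three_by_three(self):
        # ranks (1,2,3), (1,2,3), (3,2,1): R = (5,6,7), S = 2
        series = np.array([[1.0, 2, 3], [10.0, 20, 30], [3.0, 2, 1]])
        assert rsd.kendall_w(series) == pytest.approx(12 * 2 / (9 * 24))

    def test_ties_use_midrank_correction(self):
        series = np.array([[1.0, 1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]])
        assert rsd.kendall_w(series) == pytest.approx(oracle_kendall_w(series))

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            rsd.kendall_w(np.ones((3, 5)))


class TestReho:
    def test_spatially_constant_signal_gives_one(self, rng):
        sig = rng.standard_normal(60)
        data = np.tile(sig, (8, 8, 6, 1))
        bold = rsd.BoldImage(data=data, mask=np.ones((8, 8, 6), bool),
                             voxel_size=3.0, tr=2.0)
        w = rsd.reho(bold).data
        assert np.allclose(w[1:-1, 1:-1, 1:-1], 1.0, atol=1e-10)

    def test_independent_noise_mean_near_one_over_k(self, rng):
        # E[W] = 1/K under independence; interior voxels have K = 27
        data = rng.standard_normal((11, 11, 7, 120))
        bold = rsd.BoldImage(data=data, mask=np.ones((11, 11, 7), bool),
                             voxel_size=3.0, tr=2.0)
        w = rsd.reho(bold).data[1:-1, 1:-1, 1:-1]
        assert w.mean() == pytest.approx(1 / 27, abs=0.005)

    def test_edge_voxel_uses_available_neighbors_and_flag(self, rng):
        data = rng.standard_normal((6, 6, 4, 30))
        mask = np.ones((6, 6, 4), bool)
        bold = rsd.BoldImage(data=data, mask=mask, voxel_size=3.0, tr=2.0)
        m = rsd.reho(bold)
        corner = m.data[0, 0, 0]  # 8 members at a corner
        members = np.array(
            [data[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        )
        assert corner == pytest.approx(oracle_kendall_w(members), abs=1e-12)

    def test_too_few_neighbors_flagged_zero(self, rng):
        mask = np.zeros((6, 6, 4), bool)
        mask[0, 0, 0] = True
        mask[5, 5, 3] = True
        data = rng.standard_normal((6, 6, 4, 30))
        bold = rsd.BoldImage(data=data, mask=mask, voxel_size=3.0, tr=2.0)
        m = rsd.reho(bold)
        assert m.data[0, 0, 0] == 0 and m.flags[0, 0, 0]

    def test_invalid_neighborhood(self, tiny_bold):
        with pytest.raises(ValueError):
            rsd.reho(tiny_bold, neighborhood=9)


class TestVmhc:
    def test_mirror_symmetric_data_clipped_z(self, rng):
        half = rng.standard_normal((3, 6, 4, 40))
        data = np.concatenate([half, half[::-1]], axis=0)
        bold = rsd.BoldImage(data=data, mask=np.ones((6, 6, 4), bool),
                             voxel_size=3.0, tr=2.0)
        z = rsd.vmhc(bold).data
        assert np.allclose(z, np.arctanh(R_CLIP), atol=1e-10)

    def test_independent_hemispheres_mean_near_zero(self, rng):
        data = rng.standard_normal((10, 10, 6, 150))
        bold = rsd.BoldImage(data=data, mask=np.ones((10, 10, 6), bool),
                             voxel_size=3.0, tr=2.0)
        z = rsd.vmhc(bold).data
        assert abs(z.mean()) < 3 / np.sqrt(150 * 300)  # ~3 SE of the pooled mean

    def test_map_exactly_mirror_symmetric(self, tiny_bold):
        z = rsd.vmhc(tiny_bold).data
        np.testing.assert_array_equal(z, z[::-1])

    def test_zero_variance_voxel_flagged(self, rng):
        data = rng.standard_normal((6, 6, 4, 30))
        data[0, 2, 2] = 5.0  # constant series
        bold = rsd.BoldImage(data=data, mask=np.ones((6, 6, 4), bool),
                             voxel_size=3.0, tr=2.0)
        m = rsd.vmhc(bold)
        assert m.data[0, 2, 2] == 0 and m.flags[0, 2, 2] and m.flags[5, 2, 2]


class TestDegreeCentrality:
    def test_shared_series_full_degree(self, rng):
        sig = rng.standard_normal(50)
        data = np.tile(sig, (4, 4, 2, 1)) + 1e-9 * rng.standard_normal((4, 4, 2, 50))
        bold = rsd.BoldImage(data=data, mask=np.ones((4, 4, 2), bool),
                             voxel_size=3.0, tr=2.0)
        deg = rsd.degree_centrality(bold).data
        assert np.all(deg == 31)

    def test_high_threshold_independent_noise(self, tiny_bold):
        deg = rsd.degree_centrality(tiny_bold, r_threshold=0.999).data
        assert deg.max() == 0

    def test_null_mean_degree_matches_t_transform(self, rng):
        # P(r > thr) under the null from the t distribution with T-2 df
        T, thr = 120, 0.25
        data = rng.standard_normal((12, 12, 6, T))
        bold = rsd.BoldImage(data=data, mask=np.ones((12, 12, 6), bool),
                             voxel_size=3.0, tr=2.0)
        deg = rsd.degree_centrality(bold, r_threshold=thr).data
        n_vox = 12 * 12 * 6
        t_thr = thr * np.sqrt((T - 2) / (1 - thr**2))
        p_null = stats.t.sf(t_thr, T - 2)
        expected = (n_vox - 1) * p_null
        sd = np.sqrt((n_vox - 1) * p_null * (1 - p_null) / n_vox)
        assert deg.mean() == pytest.approx(expected, abs=6 * sd)

    def test_weighted_variant_sums_correlations(self, tiny_bold):
        w = rsd.degree_centrality(tiny_bold, binarize=False).data
        b = rsd.degree_centrality(tiny_bold, binarize=True).data
        assert np.all(w <= b)  # each counted edge contributes r < 1


class TestFalff:
    def _sine_bold(self, freq, T=300, tr=2.0):
        t = np.arange(T) * tr
        data = np.tile(np.sin(2 * np.pi * freq * t), (2, 2, 1, 1))
        return rsd.BoldImage(data=data, mask=np.ones((2, 2, 1), bool),
                             voxel_size=3.0, tr=tr)

    def test_in_band_sinusoid_near_one(self):
        f = rsd.falff(self._sine_bold(0.05)).data
        assert np.all(f > 0.999)

    def test_out_of_band_sinusoid_near_zero(self):
        f = rsd.falff(self._sine_bold(0.2)).data
        assert np.all(f < 1e-6)

    def test_white_noise_matches_band_fraction(self, rng):
        T, tr = 300, 2.0
        data = rng.standard_normal((10, 10, 1, T))
        bold = rsd.BoldImage(data=data, mask=np.ones((10, 10, 1), bool),
                             voxel_size=3.0, tr=tr)
        f = rsd.falff(bold).data
        freqs = np.fft.rfftfreq(T, tr)
        frac = ((freqs >= 0.01) & (freqs <= 0.1)).sum() / (freqs > 0).sum()
        assert f.mean() == pytest.approx(frac, abs=0.02)

    def test_range_and_band_validation(self, tiny_bold):
        f = rsd.falff(tiny_bold).data
        assert f.min() >= 0 and f.max() <= 1
        with pytest.raises(ValueError):
            rsd.falff(tiny_bold, band=(0.0, 0.1))


class TestStandardize:
    def test_zscore_within_mask(self, tiny_bold):
        m = rsd.standardize_map(rsd.reho(tiny_bold))
        vals = m.data[m.mask]
        assert abs(vals.mean()) < 1e-10 and vals.std() == pytest.approx(1.0, abs=1e-10)
        assert m.standardization == "zscore"

    def test_constant_map_errors(self):
        m = rsd.MetricMap("reho", np.ones((4, 4, 2)), np.ones((4, 4, 2), bool))
        with pytest.raises(ValueError):
            rsd.standardize_map(m)

    def test_affine_invariance(self, tiny_bold):
        m = rsd.reho(tiny_bold)
        a = rsd.standardize_map(m)
        import dataclasses as dc
        m2 = dc.replace(m, data=3.0 * m.data + 5.0)
        b = rsd.standardize_map(m2)
        np.testing.assert_allclose(a.data[a.mask], b.data[b.mask], atol=1e-9)

    def test_fisher_z_maps_untouched(self, tiny_bold):
        m = rsd.vmhc(tiny_bold)
        assert rsd.standardize_map(m) is m


@pytest.mark.parametrize("metric", ["pcc_ifc", "vmhc", "reho", "dc", "falff"])
def test_scale_invariance(metric, tiny_bold, rng):
    """All five metrics are invariant to global positive rescaling."""
    import dataclasses as dc
    scaled = dc.replace(tiny_bold, data=3.7 * tiny_bold.data)
    seed = np.zeros(tiny_bold.mask.shape, bool)
    seed[2:4, 2:4, 1:3] = True
    kw = dict(seed_mask=seed, bold_unfiltered=tiny_bold, standardize=False)
    kw2 = dict(seed_mask=seed, bold_unfiltered=scaled, standardize=False)
    a = rsd.metrics.compute_metric(metric, tiny_bold, **kw)
    b = rsd.metrics.compute_metric(metric, scaled, **kw2)
    np.testing.assert_allclose(a.data, b.data, atol=1e-9)
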