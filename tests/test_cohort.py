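"""Generator tests: counts, determinism, moment recovery, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rfmri_sexdiff as rsd
from rfmri_sexdiff.cohort import simulate_cluster_means


def _noise_free_effects(grid_dims, **kw):
    """Effects spec with no broadband noise / motion / subject variation."""
    eff = rsd.default_effects(grid_dims)
    eff.base_inband = 1.0
    eff.subject_sd = 0.0
    eff.motion_amp = 0.0
    eff.seed_roi = None
    for k, v in kw.items():
        setattr(eff, k, v)
    return eff


class TestPhenotypes:
    def test_exact_cell_counts(self):
        spec = rsd.default_cohort_spec(n_sites=2, cell_sizes=((5, 5, 5, 5),) * 2)
        t = rsd.generate_phenotypes(spec, rsd.default_sites(2))
        assert len(t) == 40
        counts = t.groupby(["dx", "sex"]).size()
        assert (counts == 10).all()
        per_site = t.groupby(["site", "dx", "sex"]).size()
        assert (per_site == 5).all()

    def test_deterministic_under_seed(self):
        spec = rsd.default_cohort_spec()
        a = rsd.generate_phenotypes(spec)
        b = rsd.generate_phenotypes(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_fiq_group_means_recovered(self):
        spec = rsd.default_cohort_spec(
            n_sites=1, cell_sizes=((200, 200, 200, 200),), rng_seed=5
        )
        t = rsd.generate_phenotypes(spec, rsd.default_sites(1))
        means = t.groupby("dx")["fiq"].mean()
        assert abs(means["ASD"] - 106) < 2
        assert abs(means["NT"] - 112) < 2
        assert t["age"].between(7, 18).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            rsd.default_cohort_spec(grid_dims=(13, 12, 8))
        with pytest.raises(ValueError):
            rsd.default_cohort_spec(tr=0.0)
        with pytest.raises(ValueError):
            rsd.default_cohort_spec(age_range=(18.0, 7.0))


class TestMotion:
    def test_zero_target_constant(self, small_spec, rng):
        sub = {"target_mfd": 0.0}
        m = rsd.generate_motion(small_spec, sub, rng)
        assert m.shape == (small_spec.n_timepoints, 6)
        assert np.all(m == 0)
        assert np.all(rsd.framewise_displacement(m) == 0)

    def test_realized_mfd_near_target(self, small_spec, rng):
        sub = {"target_mfd": 0.15}
        m = rsd.generate_motion(small_spec, sub, rng)
        assert 0.12 <= rsd.mean_fd(m) <= 0.18

    def test_deterministic(self, small_spec):
        sub = {"target_mfd": 0.1}
        a = rsd.generate_motion(small_spec, sub, np.random.default_rng(3))
        b = rsd.generate_motion(small_spec, sub, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_too_short_series(self, rng):
        spec = rsd.default_cohort_spec()
        bad = dataclasses.replace(spec, n_timepoints=80)
        assert rsd.generate_motion(bad, {"target_mfd": 0.1}, rng).shape[0] == 80
        with pytest.raises(ValueError):
            dataclasses.replace(spec, n_timepoints=1)


class TestBold:
    def test_full_coupling_no_noise_gives_perfect_vmhc(self, rng):
        spec = rsd.default_cohort_spec(grid_dims=(12, 12, 8), n_timepoints=60)
        eff = _noise_free_effects(spec.grid_dims, base_coupling=1.0, homotopic=())
        sub = {"dx": "NT", "sex": "M"}
        b = rsd.generate_bold(sub, spec, eff, rsd.SiteSpec(), rng)
        v = rsd.vmhc(b)
        # r = 1 everywhere -> the clipped Fisher z value
        expected = np.arctanh(1 - 1e-7)
        assert np.allclose(v.data[b.mask], expected, atol=1e-6)

    def test_interaction_produces_gender_incoherence_ordering(self):
        spec = rsd.default_cohort_spec(
            n_sites=1, cell_sizes=((40, 40, 40, 40),),
            grid_dims=(12, 12, 8), n_timepoints=80, rng_seed=7,
        )
        eff = rsd.default_effects(spec.grid_dims)
        eff.seed_roi = None
        t = rsd.generate_phenotypes(spec, [rsd.SiteSpec()])
        roi = eff.rois["dlo"]
        master = np.random.default_rng(7)
        cell_vals = {}
        for _, row in t.iterrows():
            b = rsd.generate_bold(row, spec, eff, rsd.SiteSpec(), master)
            z = rsd.vmhc(b).data[roi].mean()
            cell_vals.setdefault((row["dx"], row["sex"]), []).append(z)
        means = {k: np.mean(v) for k, v in cell_vals.items()}
        assert max(means, key=means.get) == ("NT", "F")
        assert min(means, key=means.get) == ("ASD", "F")

    def test_site_offsets_separate_metric_means(self, rng):
        # gamma = +-0.5 on the Fisher-z coupling scale, no noise, no effects:
        # extracted mean VMHC z differs by ~1.0 between sites
        spec = rsd.default_cohort_spec(grid_dims=(12, 12, 8), n_timepoints=400)
        eff = _noise_free_effects(spec.grid_dims, homotopic=())
        sub = {"dx": "NT", "sex": "M"}
        means = {}
        for g in (+0.5, -0.5):
            b = rsd.generate_bold(sub, spec, eff, rsd.SiteSpec(gamma=g), rng)
            means[g] = rsd.vmhc(b).data[b.mask].mean()
        assert abs((means[0.5] - means[-0.5]) - 1.0) < 0.1

    def test_deterministic_under_seed(self, small_spec):
        eff = rsd.default_effects(small_spec.grid_dims)
        sub = {"dx": "ASD", "sex": "F"}
        a = rsd.generate_bold(sub, small_spec, eff, rsd.SiteSpec(), np.random.default_rng(9))
        b = rsd.generate_bold(sub, small_spec, eff, rsd.SiteSpec(), np.random.default_rng(9))
        np.testing.assert_array_equal(a.data, b.data)

    def test_coupling_out_of_range_rejected(self, small_spec, rng):
        eff = rsd.default_effects(small_spec.grid_dims)
        eff.homotopic = (rsd.ChannelEffect("dlo", beta_int=0.9),)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            rsd.generate_bold(
                {"dx": "ASD", "sex": "F"}, small_spec, eff, rsd.SiteSpec(), rng
            )

    def test_roi_outside_mask_rejected(self, small_spec, rng):
        eff = rsd.default_effects(small_spec.grid_dims)
        bad = np.zeros(small_spec.grid_dims, bool)
        bad[0, 0, 0] = True  # outside the ellipsoid mask
        eff.rois["bad"] = bad
        eff.homotopic = (rsd.ChannelEffect("bad", beta_dx=0.1),)
        with pytest.raises(ValueError, match="outside"):
            rsd.generate_bold(
                {"dx": "ASD", "sex": "M"}, small_spec, eff, rsd.SiteSpec(), rng
            )

    def test_effect_magnitude_monotonically_recovered(self):
        """Larger |beta_int| on homotopic coupling -> larger cluster eta_p^2."""
        spec = rsd.default_cohort_spec(
            n_sites=1, cell_sizes=((10, 10, 10, 10),),
            grid_dims=(12, 12, 8), n_timepoints=80,
        )
        betas = (-0.05, -0.125, -0.20, -0.275, -0.35)
        mean_eta = []
        for bi, beta in enumerate(betas):
            etas = []
            for rep in range(8):
                s = dataclasses.replace(spec, rng_seed=1000 * bi + rep)
                eff = rsd.default_effects(spec.grid_dims)
                eff.seed_roi = None
                eff.homotopic = (rsd.ChannelEffect("dlo", beta_int=beta),)
                t = rsd.generate_phenotypes(s, [rsd.SiteSpec()])
                t["mfd"] = t["target_mfd"]
                master = np.random.default_rng(s.rng_seed)
                roi = eff.rois["dlo"]
                vals = [
                    rsd.vmhc(
                        rsd.generate_bold(row, s, eff, rsd.SiteSpec(), master)
                    ).data[roi].mean()
                    for _, row in t.iterrows()
                ]
                res = rsd.ClusterEffects(np.array(vals), t).fit()
                etas.append(res["dx_by_sex"].eta_sq)
            mean_eta.append(np.mean(etas))
        rho = stats.spearmanr([abs(b) for b in betas], mean_eta).statistic
        assert rho > 0.9


class TestBehavior:
    def _asd_table(self, n_per_sex=500, seed=3):
        spec = rsd.default_cohort_spec(
            n_sites=1, cell_sizes=((n_per_sex, n_per_sex, 5, 5),), rng_seed=seed
        )
        return rsd.generate_phenotypes(spec, [rsd.SiteSpec()])

    def test_within_sex_correlations_recovered(self, rng):
        t = self._asd_table()
        signal = rng.standard_normal(len(t))
        out = rsd.generate_behavior(t, signal, rsd.BehaviorSpec(), rng)
        asd = out["dx"] == "ASD"
        for sex, lo, hi in (("F", -0.4, -0.2), ("M", -0.1, 0.1)):
            sel = asd & (out["sex"] == sex)
            r = np.corrcoef(signal[sel], out.loc[sel, "ados_sa"])[0, 1]
            assert lo <= r <= hi

    def test_nt_rows_stay_missing_and_ranges_hold(self, rng):
        t = self._asd_table(n_per_sex=50)
        out = rsd.generate_behavior(t, rng.standard_normal(len(t)), rsd.BehaviorSpec(), rng)
        nt = out["dx"] == "NT"
        assert out.loc[nt, ["ados_css", "ados_sa", "ados_rrb", "ados_module"]].isna().all().all()
        spec = rsd.BehaviorSpec()
        for col, (lo, hi) in spec.score_ranges.items():
            vals = out.loc[~nt, col].dropna()
            assert vals.between(lo, hi).all()
            assert np.allclose(vals, np.round(vals))
        assert out.loc[~nt, "ados_module"].isin([2, 3, 4]).all()

    def test_empty_stratum_with_target_r_errors(self, rng):
        spec = rsd.default_cohort_spec(n_sites=1, cell_sizes=((20, 0, 5, 5),))
        t = rsd.generate_phenotypes(spec, [rsd.SiteSpec()])
        with pytest.raises(ValueError, match="empty stratum"):
            rsd.generate_behavior(
                t, np.zeros(len(t)), rsd.BehaviorSpec(r_female=-0.3), rng
            )


def test_cluster_mean_generator_null_and_effect(rng):
    spec = rsd.default_cohort_spec(n_sites=1, cell_sizes=((100, 100, 100, 100),))
    t = rsd.generate_phenotypes(spec, [rsd.SiteSpec()])
    t["mfd"] = t["target_mfd"]
    y0 = simulate_cluster_means(t, rng)
    y1 = simulate_cluster_means(t, rng, beta_int=-0.2)
    r0 = rsd.ClusterEffects(y0, t).fit()["dx_by_sex"]
    r1 = rsd.ClusterEffects(y1, t).fit()["dx_by_sex"]
    assert r1.eta_sq > r0.eta_sq
    assert r1.direction == -1
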