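import numpy as np
import pytest

from paleomonsoon import agemodel, helium, stats, synthetic, wavelet
from paleomonsoon.records import ProxyRecord


class TestForcedSeries:
    def test_noise_free_local_only_series_tracks_insolation_exactly(self, ages_3kyr):
        spec = synthetic.ForcingMixSpec(beta_gradient=0.0, noise_sigma=0.0, seed=0)
        out = synthetic.gen_forced_series(spec, ages_3kyr)
        r = np.corrcoef(out.record.values, out.local_norm.values)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_gradient_only_series_shows_both_orbital_bands(self, ages_3kyr):
        spec = synthetic.ForcingMixSpec(beta_local=0.0, beta_gradient=20.0,
                                        noise_sigma=1.0, seed=1)
        out = synthetic.gen_forced_series(spec, ages_3kyr)
        res = wavelet.cwt_morlet(wavelet.resample_uniform(out.record))
        avg = res.power.mean(axis=1)
        peaks = [res.periods[i] for i in range(1, len(avg) - 1)
                 if avg[i] > avg[i - 1] and avg[i] > avg[i + 1]]
        assert any(abs(np.log2(p / 23.0)) < 0.5 for p in peaks)
        assert any(abs(np.log2(p / 41.0)) < 0.5 for p in peaks)

    def test_regression_recovers_generating_weights(self, ages_3kyr):
        import statsmodels.api as sm
        zs = []
        for seed in range(8):
            spec = synthetic.ForcingMixSpec(seed=seed)
            out = synthetic.gen_forced_series(spec, ages_3kyr)
            X = sm.add_constant(np.column_stack(
                [out.local_norm.values, out.gradient_norm.values]))
            fit = sm.OLS(out.record.values, X).fit(
                cov_type="HAC", cov_kwds={"maxlags": 5})
            truth = [spec.intercept, spec.beta_local, spec.beta_gradient]
            zs.append((fit.params - truth) / fit.bse)
        pooled = np.mean(zs, axis=0)
        # unbiased recovery: pooled z-scores of 8 replicates ~ N(0, 1/sqrt(8))
        assert np.all(np.abs(pooled) < 1.0)


class TestWaxGenerator:
    def test_zero_noise_inverse_consistency(self, ages_3kyr, wax_config):
        from paleomonsoon import wax
        dD = ProxyRecord(ages_3kyr, -40 + 8 * np.sin(ages_3kyr / 11))
        f = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), 1.0))
        samples = synthetic.gen_wax_samples(dD, f, wax_config,
                                            d13C_sigma=0.0, dD_sigma=0.0)
        # pure C4 truth -> generated d13C constant at the C4 end member
        assert all(s.d13C == pytest.approx(-19.9) for s in samples)
        dp, fc = wax.apply_chain(samples, wax_config, propagate=False)
        np.testing.assert_allclose(dp.values, dD.values, atol=1e-6)

    def test_noisy_recovery_is_unbiased(self, ages_3kyr, wax_config):
        from paleomonsoon import wax
        dD = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), -40.0))
        f = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), 0.6))
        rng_seeds = range(4)
        errs = []
        for s in rng_seeds:
            samples = synthetic.gen_wax_samples(dD, f, wax_config, seed=s)
            dp, _ = wax.apply_chain(samples, wax_config, propagate=False)
            errs.append(np.mean(dp.values - dD.values))
        # mean error across ~680 samples << one measurement sigma (~3.4)
        assert abs(np.mean(errs)) < 0.34

    def test_out_of_range_truth_rejected(self, ages_3kyr, wax_config):
        dD = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), -40.0))
        f = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), 1.2))
        with pytest.raises(ValueError, match="0, 1"):
            synthetic.gen_wax_samples(dD, f, wax_config)


class TestHeliumColumn:
    def test_focusing_changes_stratigraphic_but_not_he_normalized_flux(
            self, column_factory):
        em = helium.EndMemberConfig()
        out = {}
        for psi in (1.0, 3.0):
            col = column_factory(focusing=psi, seed=42)
            real = synthetic.gen_helium_column(col)
            recs = helium.dust_flux_series(real.measurements, em,
                                           n_draws=1000, seed=7)
            model = agemodel.AgeDepthModel(real.tie_points)
            mids = 0.5 * (real.depths[:-1] + real.depths[1:])
            smar = model.stratigraphic_mar(mids, col.dry_bulk_density)
            out[psi] = (np.array([r.dust_flux for r in recs]),
                        np.array([r.dust_flux_sigma for r in recs]), smar)
        f1, s1, m1 = out[1.0]
        f3, s3, m3 = out[3.0]
        assert np.all(np.abs(f1 - f3) <= np.hypot(s1, s3))
        np.testing.assert_allclose(m3 / m1, 3.0, rtol=0.10)

    def test_he_normalized_mar_recovers_vertical_flux_despite_focusing(
            self, column_factory):
        col = column_factory(focusing=2.5, seed=8)
        real = synthetic.gen_helium_column(col)
        em = helium.EndMemberConfig(ratio_terr=col.r_terr_true)
        mars = np.array([helium.mar_from_he3et(
            helium.he3_et(m, em, warn=False), em) for m in real.measurements])
        ratio = mars / col.vertical_mass_flux
        # unbiased within the 23% concentration noise, independent of psi=2.5
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_zero_dust_limit_ratio_approaches_idp_endmember(self, ages_3kyr):
        col = synthetic.SyntheticColumn(
            ages=ages_3kyr[:40], true_dust_flux=1e-9, f_caco3=0.0,
            focusing_factor=1.0, he3_noise_frac=0.0, he4_noise_frac=0.0, seed=0)
        real = synthetic.gen_helium_column(col)
        ratios = np.array([m.ratio_meas for m in real.measurements])
        np.testing.assert_allclose(ratios, 2.4e-4, rtol=0.05)

    def test_paired_samples_span_the_flux_range(self, column_factory):
        col = column_factory(seed=5)
        real = synthetic.gen_helium_column(col, n_pairs=5)
        fv = col.vertical_mass_flux
        th = [p.th_mar for p in real.paired]
        assert max(th) / min(th) > 0.5 * fv.max() / fv.min()


class TestTransectGenerator:
    def test_zero_width_is_a_step_function(self):
        spec = synthetic.TransectSpec(transition_width=0.0)
        north = synthetic.transect_truth(spec, 20.0, "late_holocene")
        south = synthetic.transect_truth(spec, 5.0, "late_holocene")
        assert north == spec.c3_plateau
        assert south == spec.c4_plateau

    def test_uniform_offset_recovered_at_all_latitudes(self):
        spec = synthetic.TransectSpec(
            ecotone_latitude={"late_holocene": 14.0, "lgm": 14.0},
            slice_offset={"lgm": 2.0}, noise_sigma=0.1, seed=2)
        pts = synthetic.gen_transect(spec)
        out = stats.slice_anomaly(pts, "lgm", "late_holocene")
        assert out["anomaly_permil"].mean() == pytest.approx(2.0, abs=0.15)
        assert out["anomaly_permil"].std() < 0.5


class TestBenthicStack:
    def test_zero_noise_is_exact_normalized_sawtooth(self, ages_3kyr):
        out = synthetic.gen_benthic_stack(ages_3kyr, noise_sigma=0.0)
        assert out.values[0] == 0.0
        assert out.values.max() == pytest.approx(1.0)
        assert out.values.min() >= 0.0

    def test_co2_coupling_recovers_imposed_sign(self, ages_3kyr, wax_config):
        from paleomonsoon import wax
        stack = synthetic.gen_benthic_stack(ages_3kyr, noise_sigma=0.03, seed=4)
        co2 = synthetic.co2_from_stack(stack)
        f_truth = synthetic.f_c4_from_co2(co2)
        dD = ProxyRecord(ages_3kyr, np.full(len(ages_3kyr), -40.0))
        samples = synthetic.gen_wax_samples(dD, f_truth, wax_config, seed=5)
        d13c = ProxyRecord(ages_3kyr, np.array([s.d13C for s in samples]))
        res = stats.correlate_adjusted(d13c, co2)
        assert res.r < 0 and res.p < 0.01


def test_fixture_set_is_deterministic(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    synthetic.generate_fixture_set(a, seed=1)
    synthetic.generate_fixture_set(b, seed=1)
    for f in sorted(a.iterdir()):
        assert (b / f.name).read_bytes() == f.read_bytes()
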