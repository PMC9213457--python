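import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomonsoon import synthetic, wax
from paleomonsoon.records import ProxyRecord


@pytest.fixture()
def em():
    return wax.MixingEndMembers()


@pytest.fixture()
def fp():
    return wax.FractionationParams(eps_C3=-110.0, eps_C4=-130.0)


class TestFcFour:
    def test_exact_at_end_members(self, em):
        assert wax.f_c4(-33.6, em) == 0.0
        assert wax.f_c4(-19.9, em) == 1.0

    def test_reported_range_implies_56_to_72_percent_c4(self, em):
        # the observed d13C range of the C31 alkane maps to a mixed
        # C3/C4 source with a grassy majority
        lo = wax.f_c4(-25.98, em)
        hi = wax.f_c4(-23.82, em)
        assert round(100 * lo) == 56
        assert 71 <= round(100 * hi) <= 72

    def test_out_of_range_clipped_with_warning(self, em):
        with pytest.warns(wax.FcFourClipWarning):
            assert wax.f_c4(-35.0, em) == 0.0
        with pytest.warns(wax.FcFourClipWarning):
            assert wax.f_c4(-15.0, em) == 1.0

    def test_degenerate_end_members_rejected(self):
        with pytest.raises(ValueError):
            wax.MixingEndMembers(d13C_C3=-20.0, d13C_C4=-20.0)

    @given(st.floats(-33.6, -19.9))
    @settings(max_examples=50, deadline=None)
    def test_affine_in_measured_value(self, d13c):
        e = wax.MixingEndMembers()
        f = wax.f_c4(d13c, e)
        reconstructed = e.d13C_C3 + f * (e.d13C_C4 - e.d13C_C3)
        assert reconstructed == pytest.approx(d13c, abs=1e-9)


class TestEpsilonLandscape:
    def test_end_member_limits_and_midpoint(self, fp):
        assert wax.epsilon_landscape(0.0, fp) == fp.eps_C3
        assert wax.epsilon_landscape(1.0, fp) == fp.eps_C4
        assert wax.epsilon_landscape(0.5, fp) == pytest.approx(-120.0)

    def test_fractionation_requires_explicit_configuration(self):
        with pytest.raises((TypeError, ValueError)):
            wax.FractionationParams(eps_C3=None, eps_C4=-130.0)
        with pytest.raises(ValueError):
            wax.FractionationParams(eps_C3=110.0, eps_C4=-130.0)


class TestIceVolumeCorrection:
    @pytest.fixture()
    def sw(self):
        return wax.SeawaterCorrection(np.array([0.0, 50.0]),
                                      np.array([1.0, 1.0]))

    def test_zero_anomaly_is_identity(self):
        sw0 = wax.SeawaterCorrection(np.array([0.0, 50.0]),
                                     np.array([0.0, 0.0]))
        assert wax.ice_volume_correct(-150.0, 10.0, sw0) == pytest.approx(-150.0)

    def test_one_permil_seawater_oracle(self, sw):
        # dD_sw = 8 permil; (0.850/1.008) - 1 = -156.746 permil
        out = wax.ice_volume_correct(-150.0, 10.0, sw)
        assert out == pytest.approx(1000 * (0.850 / 1.008 - 1.0), abs=1e-9)

    def test_round_trip_is_exact(self, sw):
        out = wax.ice_volume_correct(-150.0, 10.0, sw)
        back = wax.uncorrect_ice_volume(out, 10.0, sw)
        assert back == pytest.approx(-150.0, abs=1e-9)

    def test_age_outside_span_raises(self, sw):
        with pytest.raises(ValueError, match="span"):
            wax.ice_volume_correct(-150.0, 60.0, sw)


class TestDeltaDPrecip:
    def test_zero_fractionation_is_identity(self):
        assert wax.delta_d_precip(-150.0, 0.0) == pytest.approx(-150.0)

    def test_arithmetic_oracle(self):
        assert wax.delta_d_precip(-150.0, -120.0) == pytest.approx(
            1000 * (0.850 / 0.880 - 1.0), abs=1e-9)

    def test_monotone_in_epsilon_and_in_wax_value(self):
        outs = [wax.delta_d_precip(-150.0, e) for e in (-100.0, -120.0, -140.0)]
        assert outs[0] < outs[1] < outs[2]
        outs = [wax.delta_d_precip(d, -120.0) for d in (-160.0, -150.0, -140.0)]
        assert outs[0] < outs[1] < outs[2]

    def test_inverse_composition(self):
        for dp in (-60.0, -20.0):
            assert wax.delta_d_precip(
                wax.apply_fractionation(dp, -125.0), -125.0) == pytest.approx(dp)


class TestUncertaintyPropagation:
    def test_zero_sigma_collapses_to_deterministic_value(self, wax_config):
        s = wax.WaxSample(100.0, -26.0, 0.0, -150.0, 0.0)
        dp, dps, f, fs = wax.propagate_wax_uncertainty(s, wax_config,
                                                       n_draws=2000, seed=0)
        assert dps == pytest.approx(0.0, abs=1e-9)
        assert fs == pytest.approx(0.0, abs=1e-12)
        f0 = wax.f_c4(-26.0, wax_config.endmembers)
        eps = wax.epsilon_landscape(f0, wax_config.fractionation)
        expected = wax.delta_d_precip(
            wax.ice_volume_correct(-150.0, 100.0, wax_config.seawater), eps)
        assert dp == pytest.approx(expected)
        assert f == pytest.approx(f0)

    def test_dd_only_sigma_matches_linear_propagation(self, wax_config):
        s = wax.WaxSample(100.0, -26.0, 0.0, -150.0, 2.0)
        _, dps, _, _ = wax.propagate_wax_uncertainty(s, wax_config,
                                                     n_draws=100_000, seed=1)
        f0 = wax.f_c4(-26.0, wax_config.endmembers)
        eps = wax.epsilon_landscape(f0, wax_config.fractionation) / 1000.0
        assert dps == pytest.approx(2.0 / (1.0 + eps), rel=0.02)

    def test_doubling_input_sigmas_doubles_output_sigma(self, wax_config):
        s1 = wax.WaxSample(100.0, -26.0, 0.2, -150.0, 2.0)
        s2 = wax.WaxSample(100.0, -26.0, 0.4, -150.0, 4.0)
        _, a, _, _ = wax.propagate_wax_uncertainty(s1, wax_config,
                                                   n_draws=100_000, seed=2)
        _, b, _, _ = wax.propagate_wax_uncertainty(s2, wax_config,
                                                   n_draws=100_000, seed=2)
        assert b == pytest.approx(2.0 * a, rel=0.03)


class TestApplyChain:
    def test_forward_inverse_consistency(self, ages_3kyr, wax_config):
        dD_truth = ProxyRecord(ages_3kyr, -40 + 10 * np.sin(2 * np.pi * ages_3kyr / 23))
        f_truth = ProxyRecord(ages_3kyr, 0.5 + 0.3 * np.sin(2 * np.pi * ages_3kyr / 100))
        samples = synthetic.gen_wax_samples(dD_truth, f_truth, wax_config,
                                            d13C_sigma=0.0, dD_sigma=0.0)
        dp, fc = wax.apply_chain(samples, wax_config, propagate=False)
        np.testing.assert_allclose(dp.values, dD_truth.values, atol=1e-6)
        np.testing.assert_allclose(fc.values, f_truth.values, atol=1e-9)

    def test_degenerate_mixing_reduces_to_hydrogen_chain(self, ages_3kyr, wax_config):
        # equal C3/C4 fractionations make the d13C step irrelevant
        cfg = wax.WaxChainConfig(
            wax_config.endmembers,
            wax.FractionationParams(eps_C3=-120.0, eps_C4=-120.0),
            wax_config.seawater)
        s = wax.WaxSample(100.0, -33.6, 0.0, -150.0, 0.0)
        dp, fc = wax.apply_chain([s], cfg, propagate=False)
        expected = wax.delta_d_precip(
            wax.ice_volume_correct(-150.0, 100.0, cfg.seawater), -120.0)
        assert dp.values[0] == pytest.approx(expected)
        assert fc.values[0] == 0.0

    def test_co2_correction_off_by_default_is_bitwise_identical(
            self, ages_3kyr, wax_config):
        s = [wax.WaxSample(a, -26.0, 0.0, -150.0, 0.0) for a in (10.0, 50.0)]
        base, _ = wax.apply_chain(s, wax_config, propagate=False)
        cfg_off = wax.WaxChainConfig(wax_config.endmembers,
                                     wax_config.fractionation,
                                     wax_config.seawater,
                                     d13C_co2_anomaly=None)
        again, _ = wax.apply_chain(s, cfg_off, propagate=False)
        assert np.array_equal(base.values, again.values)

    def test_co2_correction_shifts_measured_d13c(self, wax_config):
        anomaly = ProxyRecord(np.array([0.0, 500.0]), np.array([0.5, 0.5]))
        cfg = wax.WaxChainConfig(wax_config.endmembers, wax_config.fractionation,
                                 wax_config.seawater, d13C_co2_anomaly=anomaly)
        s = [wax.WaxSample(100.0, -26.0, 0.0, -150.0, 0.0)]
        _, fc_corr = wax.apply_chain(s, cfg, propagate=False)
        _, fc_raw = wax.apply_chain(s, wax_config, propagate=False)
        assert fc_corr.values[0] == pytest.approx(
            wax.f_c4(-26.5, wax_config.endmembers))
        assert fc_corr.values[0] < fc_raw.values[0]
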