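"""Eddy-covariance pipeline stages: filtering, despiking, rotation,
Reynolds decomposition, time-shift, fluxes and hydrodynamic diagnostics."""

import numpy as np
import pandas as pd
import pytest

import streammetab as smb
from streammetab.aec import flux_standard_error
from streammetab.series import HighFreqSeries


def make_series(u, v=None, w=None, o2=None, rate=8.0, beam=None, snr=None):
    n = len(u)
    u = np.asarray(u, float)
    zeros = np.zeros(n)
    return HighFreqSeries(
        time=np.arange(n) / rate, u=u,
        v=zeros.copy() if v is None else np.asarray(v, float),
        w=zeros.copy() if w is None else np.asarray(w, float),
        o2=np.full(n, 300.0) if o2 is None else np.asarray(o2, float),
        beam_correlation=np.full(n, 90.0) if beam is None else np.asarray(beam, float),
        snr=np.full(n, 20.0) if snr is None else np.asarray(snr, float),
        sample_rate=rate)


class TestQualityFilter:
    def test_all_passing_unchanged(self):
        s = make_series(np.linspace(0, 1, 100))
        out, gap = smb.quality_filter(s)
        assert gap == 0.0
        np.testing.assert_array_equal(out.u, s.u)

    def test_failing_sample_linearly_interpolated(self):
        u = np.array([1.0, 99.0, 3.0, 3.0, 3.0])
        beam = np.array([90.0, 10.0, 90.0, 90.0, 90.0])
        out, gap = smb.quality_filter(make_series(u, beam=beam),
                                      max_gap_fraction=0.5)
        assert out.u[1] == pytest.approx(2.0)
        assert gap == pytest.approx(0.2, abs=1e-12)

    def test_gap_ceiling_enforced(self):
        beam = np.full(100, 10.0)
        with pytest.raises(ValueError):
            smb.quality_filter(make_series(np.zeros(100), beam=beam))


class TestBlockAverage:
    def test_constant_series_unchanged(self):
        s = make_series(np.full(640, 2.5), rate=64.0)
        out = smb.block_average(s, 8.0)
        assert len(out) == 80
        np.testing.assert_allclose(out.u, 2.5)

    def test_alternating_signs_average_to_zero(self):
        u = np.tile([1.0, -1.0], 320)
        out = smb.block_average(make_series(u, rate=64.0), 8.0)
        np.testing.assert_allclose(out.u, 0.0, atol=1e-15)

    def test_non_divisible_rate_rejected(self):
        with pytest.raises(ValueError):
            smb.block_average(make_series(np.zeros(64), rate=64.0), 7.0)

    def test_flux_preserved_through_averaging(self):
        # covariance carried by eddies slower than the averaging block
        spec = smb.TurbulenceSpec(sample_rate=64.0, duration=1800.0,
                                  true_flux=-5.0, spike_rate=0.0,
                                  qc_fail_fraction=0.0, sensor_lag=0.0, seed=9)
        series, _ = smb.gen_turbulence(spec)

        def flux_of(s):
            from streammetab.aec import detrend_fluctuations, compute_flux
            w, widx = detrend_fluctuations(s.w, s.sample_rate, 300.0)
            c, _ = detrend_fluctuations(s.o2, s.sample_rate, 300.0)
            return compute_flux(w, c, widx)["f_ec"].mean()

        f64 = flux_of(series)
        f8 = flux_of(smb.block_average(series, 8.0))
        assert f8 == pytest.approx(f64, rel=0.05)


class TestDespike:
    def test_gaussian_false_positive_rate(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        _, count = smb.despike_phase_space(x)
        assert count / len(x) <= 0.001

    def test_single_large_spike_replaced_within_neighbors(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        x[2500] = 10.0 * x.std()
        cleaned, count = smb.despike_phase_space(x)
        assert count >= 1
        lo = min(x[2498], x[2503]) - 3.0
        hi = max(x[2498], x[2503]) + 3.0
        assert lo <= cleaned[2500] <= hi
        assert abs(cleaned[2500]) < 5.0

    def test_constant_series_no_spikes(self):
        cleaned, count = smb.despike_phase_space(np.full(1000, 3.0))
        assert count == 0
        np.testing.assert_array_equal(cleaned, 3.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            smb.despike_phase_space(np.array([1.0, np.nan, 2.0]))


class TestDoubleRotation:
    def test_already_aligned_series_unchanged(self):
        rng = np.random.default_rng(2)
        u = 0.2 + 0.01 * rng.standard_normal(1000)
        v = rng.standard_normal(1000) * 0.01
        w = rng.standard_normal(1000) * 0.01
        v -= v.mean()
        w -= w.mean()
        u2, v2, w2, yaw, pitch = smb.double_rotation(u, v, w)
        assert abs(yaw) < 1e-10 and abs(pitch) < 1e-10
        np.testing.assert_allclose(u2, u, atol=1e-8)

    def test_known_pitch_recovered_and_flux_preserved(self):
        spec = smb.TurbulenceSpec(true_flux=-5.0, duration=3600.0,
                                  spike_rate=0.0, qc_fail_fraction=0.0,
                                  sensor_lag=0.0, seed=3)
        series, _ = smb.gen_turbulence(spec)
        u0, v0, w0 = series.u, series.v, series.w - series.w.mean()
        tilt = np.radians(10.0)
        # forward-tilt the frame by a 10 degree pitch
        u_t = u0 * np.cos(tilt) - w0 * np.sin(tilt)
        w_t = u0 * np.sin(tilt) + w0 * np.cos(tilt)
        u2, v2, w2, yaw, pitch = smb.double_rotation(u_t, v0, w_t)
        assert np.degrees(pitch) == pytest.approx(10.0, abs=0.2)

        from streammetab.aec import detrend_fluctuations, compute_flux
        def flux(wv):
            wp, widx = detrend_fluctuations(wv, 8.0, 300.0)
            cp, _ = detrend_fluctuations(series.o2, 8.0, 300.0)
            return compute_flux(wp, cp, widx)["f_ec"].mean()
        assert flux(w2) == pytest.approx(flux(w0), rel=0.02)

    def test_vertical_offset_removed(self):
        rng = np.random.default_rng(4)
        u = 0.2 + 0.01 * rng.standard_normal(500)
        w = 0.01 + 0.005 * rng.standard_normal(500)
        _, _, w2, _, _ = smb.double_rotation(u, np.zeros(500), w)
        assert abs(w2.mean()) < 1e-10

    def test_speed_preserved_per_sample(self):
        rng = np.random.default_rng(5)
        u = 0.2 + 0.02 * rng.standard_normal(2000)
        v = 0.05 + 0.02 * rng.standard_normal(2000)
        w = 0.01 + 0.01 * rng.standard_normal(2000)
        u2, v2, w2, _, _ = smb.double_rotation(u, v, w)
        s0 = np.sqrt(u ** 2 + v ** 2 + w ** 2)
        s1 = np.sqrt(u2 ** 2 + v2 ** 2 + w2 ** 2)
        np.testing.assert_allclose(s1, s0, rtol=1e-12)

    def test_zero_mean_flow_rejected(self):
        with pytest.raises(ValueError):
            smb.double_rotation(np.zeros(10), np.zeros(10), np.ones(10))


class TestDetrend:
    def test_linear_ramp_gives_zero_fluctuations(self):
        x = np.linspace(0, 5, 8 * 600)
        f, _ = smb.detrend_fluctuations(x, 8.0, 300.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_sine_on_ramp_recovered(self):
        rate, win = 8.0, 300.0
        t = np.arange(int(rate * 900)) / rate
        sine = 0.5 * np.sin(2 * np.pi * t / 2.5)  # period << window
        f, _ = smb.detrend_fluctuations(3.0 + 0.01 * t + sine, rate, win)
        # amplitude preserved within 1%
        assert f.max() == pytest.approx(0.5, rel=0.01)
        assert np.std(f) == pytest.approx(np.std(sine), rel=0.01)

    def test_constant_whole_series_window(self):
        x = np.full(8 * 300, 7.7)
        f, widx = smb.detrend_fluctuations(x, 8.0, 300.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        assert widx.max() == 0

    def test_zero_mean_per_window(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(8 * 1200)
        f, widx = smb.detrend_fluctuations(x, 8.0, 300.0)
        for k in np.unique(widx):
            assert abs(f[widx == k].mean()) < 1e-10

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            smb.detrend_fluctuations(np.zeros(100), 8.0, 300.0)


class TestTimeShift:
    def test_unlagged_pair_keeps_lag_zero(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal(8000)
        c = 2.0 * w + 0.1 * rng.standard_normal(8000)
        shifted, lag = smb.time_shift_correct(w, c, 8.0)
        assert lag == 0.0
        np.testing.assert_array_equal(shifted, c)

    def test_generator_lag_recovered(self):
        spec = smb.TurbulenceSpec(sensor_lag=0.5, true_flux=-5.0,
                                  spike_rate=0.0, qc_fail_fraction=0.0, seed=8)
        series, truth = smb.gen_turbulence(spec)
        from streammetab.aec import detrend_fluctuations, compute_flux
        wp, widx = detrend_fluctuations(series.w, 8.0, 300.0)
        cp, _ = detrend_fluctuations(series.o2, 8.0, 300.0)
        shifted, lag = smb.time_shift_correct(wp, cp, 8.0)
        assert lag == pytest.approx(0.5)
        flux = compute_flux(wp, shifted, widx)["f_ec"].mean()
        assert flux == pytest.approx(truth["true_flux_mmol_m2_h"], rel=0.05)

    def test_white_noise_pair_no_lag_fishing_bias(self):
        # maximizing |cov| over lags must not conjure flux from noise
        rng = np.random.default_rng(9)
        fluxes = []
        for _ in range(20):
            w = rng.standard_normal(8 * 3600) * 0.01
            c = rng.standard_normal(8 * 3600) * 0.5
            shifted, _ = smb.time_shift_correct(w, c, 8.0)
            fluxes.append(np.mean(w * shifted) * 3600.0)
        fluxes = np.asarray(fluxes)
        se = fluxes.std(ddof=1) / np.sqrt(len(fluxes))
        assert abs(fluxes.mean()) < 3 * se
        assert np.abs(fluxes).max() < 0.5  # mmol m-2 h-1, tiny vs field fluxes

    def test_degenerate_input_warns_and_returns_zero_lag(self):
        with pytest.warns(UserWarning):
            _, lag = smb.time_shift_correct(np.zeros(100), np.ones(100), 8.0)
        assert lag == 0.0


class TestFluxAndDiagnostics:
    def test_proportional_signals_exact_flux(self):
        rng = np.random.default_rng(10)
        c = rng.standard_normal(8 * 300) * 2.0   # var 4 (mmol/m3)^2
        c = (c - c.mean()) / c.std() * 2.0
        w = 0.001 * c
        tbl = smb.compute_flux(w, c, np.zeros(len(c), dtype=int))
        assert tbl["f_ec"].iloc[0] == pytest.approx(0.004 * 3600.0, rel=1e-12)

    def test_independent_noise_flux_within_two_se(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal(8 * 3600) * 0.01
        c = rng.standard_normal(8 * 3600) * 0.5
        widx = np.repeat(np.arange(12), 8 * 300)
        tbl = smb.compute_flux(w, c, widx)
        se = flux_standard_error(tbl["f_ec"].to_numpy())
        assert abs(tbl["f_ec"].mean()) < 2 * se

    def test_friction_velocity_exact_and_floored(self):
        rng = np.random.default_rng(12)
        w = rng.standard_normal(10000)
        u = -w * (1e-4 / np.mean(w * w))
        us, flagged = smb.friction_velocity(u, w)
        assert us == pytest.approx(0.01, rel=1e-12)
        assert not flagged
        us2, flagged2 = smb.friction_velocity(w, w)  # positive stress
        assert us2 == 0.0 and flagged2

    def test_roughness_z0_value_and_roundtrip(self):
        z0 = smb.roughness_z0(0.15, 0.20, 0.0115)
        assert z0 == pytest.approx(0.15 * np.exp(-0.41 * 0.20 / 0.0115), rel=1e-12)
        assert z0 == pytest.approx(1.2e-4, rel=0.05)
        # algebraic inverse: U = (u*/kappa) ln(h/z0)
        u_back = (0.0115 / 0.41) * np.log(0.15 / z0)
        assert u_back == pytest.approx(0.20, rel=1e-12)
        with pytest.raises(ValueError):
            smb.roughness_z0(0.15, 0.20, 0.0)

    def test_z0_approaches_h_for_vanishing_shear_ratio(self):
        assert smb.roughness_z0(0.15, 1e-9, 1.0) == pytest.approx(0.15, rel=1e-6)

    def test_drag_coefficient_values(self):
        assert smb.drag_coefficient(1.0, 0.0574) == pytest.approx(0.0033, rel=0.01)
        assert smb.drag_coefficient(0.3, 0.3) == 1.0
        assert smb.drag_coefficient(0.3, 0.0) == 0.0

    def test_storage_flux_values(self):
        # fastest observed hourly O2 change over a mid-range sensor height
        f = smb.storage_flux(np.array([300.0, 341.8]), 0.15)
        assert f[0] == pytest.approx(6.27, rel=1e-9)
        np.testing.assert_allclose(smb.storage_flux(np.full(5, 280.0), 0.15), 0.0)
        ramp = 280.0 + 3.0 * np.arange(6)
        np.testing.assert_allclose(smb.storage_flux(ramp, 0.2), 0.6, rtol=1e-12)

    def test_benthic_flux_is_sum(self):
        assert smb.benthic_flux(-4.0, 1.0) == pytest.approx(-3.0)
        assert smb.benthic_flux(-4.0, 0.0) == pytest.approx(-4.0)
        # daytime O2 rise (positive storage) raises inferred production
        assert smb.benthic_flux(2.0, 1.5) > smb.benthic_flux(2.0, 0.0)

    def test_footprint_monotonic_and_envelope(self):
        l1, _, _ = smb.footprint(0.10, 8e-4)
        l2, _, _ = smb.footprint(0.20, 8e-4)
        assert l2 > l1
        l3, _, _ = smb.footprint(0.10, 2e-4)
        assert l3 > l1  # smaller roughness -> longer footprint
        # field parameter ranges stay inside the reported envelope
        for h in (0.10, 0.15, 0.19):
            for z0 in (4e-4, 8e-4, 1.2e-3):
                length, width, area = smb.footprint(h, z0)
                assert 22.0 <= length <= 181.0
                assert 0.5 <= width <= 1.5
        # z0 approaching h collapses the footprint
        lmin, _, _ = smb.footprint(0.10, 0.0999)
        assert lmin < l1
        with pytest.raises(ValueError):
            smb.footprint(0.10, 0.2)

    def test_hourly_bin_means(self):
        tbl = pd.DataFrame({"window": np.arange(12), "f_ec": np.full(12, 2.0)})
        out = smb.hourly_bin(tbl, windows_per_hour=12)
        assert out["f_ec"].iloc[0] == 2.0
        assert out["f_ec_se"].iloc[0] == 0.0
        alt = pd.DataFrame({"window": np.arange(12),
                            "f_ec": np.tile([1.0, 3.0], 6)})
        assert smb.hourly_bin(alt, 12)["f_ec"].iloc[0] == pytest.approx(2.0)


class TestPipeline:
    def test_storage_correction_recovers_benthic_flux(self):
        # EC flux -4 at sensor height plus an O2 build-up worth +1 of storage
        spec = smb.TurbulenceSpec(true_flux=-4.0, storage_slope=20.0 / 3.0,
                                  seed=13)
        series, _ = smb.gen_turbulence(spec)
        hourly, _ = smb.process_deployment(series, smb.DeploymentMeta(0.15, 0.4))
        assert hourly["f_ec_mmol_m2_h"].mean() == pytest.approx(-4.0, abs=0.4)
        assert hourly["f_storage_mmol_m2_h"].mean() == pytest.approx(1.0, rel=0.05)
        assert hourly["f_benthic_mmol_m2_h"].mean() == pytest.approx(-3.0, abs=0.4)

    def test_quality_failures_do_not_bias_flux(self):
        base = dict(true_flux=-5.0, spike_rate=0.0, sensor_lag=0.0, seed=14)
        clean, _ = smb.gen_turbulence(smb.TurbulenceSpec(qc_fail_fraction=0.0, **base))
        dirty, _ = smb.gen_turbulence(smb.TurbulenceSpec(qc_fail_fraction=0.005, **base))
        meta = smb.DeploymentMeta(0.15, 0.4)
        f_clean = smb.process_deployment(clean, meta)[0]["f_ec_mmol_m2_h"].mean()
        f_dirty = smb.process_deployment(dirty, meta)[0]["f_ec_mmol_m2_h"].mean()
        assert f_dirty == pytest.approx(f_clean, rel=0.02)

    def test_diel_light_response_tracked_hourly(self):
        camp = smb.CampaignSpec(pe_truth=(10.0, 150.0, 2.0), seed=15)
        tbl = smb.gen_diel_flux(camp, n_days=2, noise_sd=0.3)
        expected = 10.0 * np.tanh(tbl["par_umol_m2_s"] / 150.0) - 2.0
        resid = tbl["flux_mmol_m2_h"] - expected
        assert np.abs(resid).max() < 1.5  # within noise

    def test_pipeline_order_logged(self):
        spec = smb.TurbulenceSpec(duration=1800.0, seed=16)
        series, _ = smb.gen_turbulence(spec)
        _, diag = smb.process_deployment(series, smb.DeploymentMeta(0.15, 0.4))
        assert diag["pipeline"] == ["quality_filter", "block_average", "despike",
                                    "double_rotation", "detrend", "time_shift",
                                    "flux"]
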