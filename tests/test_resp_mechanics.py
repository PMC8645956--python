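import numpy as np
import pytest

from vilipower import (
    LungModelParams,
    VentSettings,
    WaveformRecording,
    breath_pressures,
    fit_equation_of_motion,
    integrate_volume,
    read_waveform,
    segment_breaths,
    simulate_ventilation,
    transpulmonary,
    write_waveform,
)
from vilipower.resp_mechanics import (
    FitError,
    WaveformDataError,
    WaveformFormatError,
    tidal_volume,
)


class TestWaveformIO:
    def test_round_trip_is_bit_identical(self, clean_recording, tmp_path):
        path = tmp_path / "wave.csv"
        write_waveform(clean_recording, path)
        back = read_waveform(path)
        np.testing.assert_array_equal(back.paw, clean_recording.paw)
        np.testing.assert_array_equal(back.flow, clean_recording.flow)
        np.testing.assert_array_equal(back.peso, clean_recording.peso)

    def test_flow_unit_conversion_from_l_per_min(self, tmp_path):
        path = tmp_path / "wave.csv"
        path.write_text(
            "time_s,paw_cmH2O,flow_Lpm\n0.0,5,30\n0.01,5,30\n0.02,5,30\n")
        rec = read_waveform(path, {"flow": "flow_Lpm", "flow_units": "L/min"})
        np.testing.assert_allclose(rec.flow, 0.5)

    def test_missing_channel_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,paw_cmH2O\n0.0,5\n0.01,5\n")
        with pytest.raises(WaveformFormatError):
            read_waveform(path)

    def test_single_row_is_data_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("time_s,paw_cmH2O,flow_Lps\n0.0,5,0\n")
        with pytest.raises(WaveformDataError):
            read_waveform(path)

    def test_non_monotone_time_is_data_error(self):
        with pytest.raises(WaveformDataError):
            WaveformRecording(time=[0.0, 0.02, 0.01], paw=[5, 5, 5],
                              flow=[0, 0, 0])


class TestSegmentation:
    def test_zero_flow_gives_no_breaths(self):
        rec = WaveformRecording(time=np.arange(200) / 100.0,
                                paw=np.full(200, 5.0), flow=np.zeros(200),
                                sample_rate=100.0)
        assert segment_breaths(rec) == []

    def test_ten_cycles_give_ten_breaths_at_set_rate(self, clean_recording):
        breaths = segment_breaths(clean_recording)
        assert len(breaths) == 10
        for b in breaths:
            assert b.respiratory_rate(clean_recording) == pytest.approx(
                20.0, abs=0.1)

    def test_truncated_inspiration_drops_partial_breath(
            self, vcv_settings, linear_lung):
        rec = simulate_ventilation(vcv_settings, linear_lung, n_breaths=3)
        # cut inside the third inspiration (0.25 s after its onset)
        cut = int((0.2 + 2 * 3.0 + 0.25) * rec.sample_rate)
        trunc = WaveformRecording(time=rec.time[:cut], paw=rec.paw[:cut],
                                  flow=rec.flow[:cut],
                                  sample_rate=rec.sample_rate)
        assert len(segment_breaths(trunc)) == 2

    def test_breath_count_times_cycle_covers_recording(self, clean_recording):
        breaths = segment_breaths(clean_recording)
        total = sum(b.duration(clean_recording) for b in breaths)
        assert abs(clean_recording.duration - total) < 60.0 / 20.0 + 0.3


class TestVolumes:
    def test_zero_flow_integrates_to_zero(self):
        rec = WaveformRecording(time=np.arange(100) / 100.0,
                                paw=np.full(100, 5.0), flow=np.zeros(100),
                                sample_rate=100.0)
        from vilipower.resp_mechanics import Breath

        vol = integrate_volume(rec, Breath(onset=0, insp_end=50, end=100))
        np.testing.assert_array_equal(vol, 0.0)

    def test_square_flow_rectangle_area(self, square_breath_recording):
        (breath,) = segment_breaths(square_breath_recording, min_duration=0.1)
        assert tidal_volume(square_breath_recording, breath) == pytest.approx(
            0.300, rel=1e-12)

    def test_simulator_vt_recovered(self, vcv_settings, linear_lung):
        settings = VentSettings(vt_ml_kg=6.2, body_mass_kg=50.0, rr=20.0,
                                insp_flow_lpm=36.0)
        rec = simulate_ventilation(settings, linear_lung, n_breaths=3)
        b = segment_breaths(rec)[0]
        assert tidal_volume(rec, b) == pytest.approx(0.310, rel=0.01)


class TestBreathPressures:
    def test_constant_paw_summary(self, square_breath_recording):
        (breath,) = segment_breaths(square_breath_recording, min_duration=0.1)
        mech = breath_pressures(square_breath_recording, breath)
        assert mech.Ppeak == mech.Pmean == mech.PEEP_measured == 5.0
        assert mech.dP == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_closed_form_driving_pressure(self):
        rec = simulate_ventilation(
            VentSettings(vt_ml_kg=6.0, body_mass_kg=50.0, rr=20.0,
                         insp_flow_lpm=36.0),
            LungModelParams(E1=60.0, E2=0.0, R=12.0, PEEP=5.0), n_breaths=3)
        mech = breath_pressures(rec, segment_breaths(rec)[0])
        assert mech.Pplat == pytest.approx(23.0, abs=1e-9)
        assert mech.dP == pytest.approx(18.0, abs=1e-9)
        # dP identity holds exactly by construction
        assert mech.dP == mech.Pplat - mech.PEEP_measured

    def test_noisy_driving_pressure_close_to_truth(self):
        rec = simulate_ventilation(
            VentSettings(vt_ml_kg=6.0, body_mass_kg=50.0, rr=20.0,
                         insp_flow_lpm=36.0),
            LungModelParams(E1=60.0, E2=0.0, R=12.0, PEEP=5.0,
                            noise_sigma=0.2, seed=4), n_breaths=5)
        for b in segment_breaths(rec):
            mech = breath_pressures(rec, b)
            assert mech.dP == pytest.approx(18.0, abs=0.2)

    def test_no_pause_flags_pplat_unavailable(self, square_breath_recording):
        rec = square_breath_recording
        # make expiration follow flow cut-off immediately
        rec = WaveformRecording(
            time=rec.time,
            paw=rec.paw,
            flow=np.where(np.arange(rec.flow.size) >= 71,
                          np.where(np.arange(rec.flow.size) < 150, -0.3, 0.0),
                          rec.flow),
            sample_rate=rec.sample_rate)
        (breath,) = segment_breaths(rec, min_duration=0.1)
        mech = breath_pressures(rec, breath)
        assert not breath.has_pause
        assert np.isnan(mech.Pplat) and np.isnan(mech.dP)
        assert any("no_pause" in f for f in mech.flags)


class TestTranspulmonary:
    def test_zero_peso_gives_ptrans_equal_paw(self, vcv_settings):
        lung = LungModelParams(E1=60.0, R=12.0, PEEP=5.0, E_cw=0.0,
                               peso_baseline=0.0)
        rec = simulate_ventilation(vcv_settings, lung, n_breaths=3)
        b = segment_breaths(rec)[0]
        mech = transpulmonary(rec, b, breath_pressures(rec, b))
        assert mech.Ptrans_peak == pytest.approx(mech.Ppeak, abs=1e-9)

    def test_closed_form_transpulmonary_driving_pressure(self, vcv_settings):
        # plateau Ptrans − min Ptrans = E1·VT for the linear lung (the
        # chest-wall term cancels between plateau and early expiration)
        lung = LungModelParams(E1=60.0, R=12.0, PEEP=5.0, E_cw=10.0)
        rec = simulate_ventilation(vcv_settings, lung, n_breaths=3)
        b = segment_breaths(rec)[0]
        mech = transpulmonary(rec, b, breath_pressures(rec, b))
        assert mech.dPtrans == pytest.approx(60.0 * 0.3, rel=0.02)

    def test_negative_end_expiratory_ptrans(self, vcv_settings):
        lung = LungModelParams(E1=60.0, R=12.0, PEEP=5.0, E_cw=10.0,
                               peso_baseline=8.0)
        rec = simulate_ventilation(vcv_settings, lung, n_breaths=3)
        b = segment_breaths(rec)[0]
        mech = transpulmonary(rec, b, breath_pressures(rec, b))
        assert mech.Ptrans_endex == pytest.approx(-3.0, abs=0.1)

    def test_missing_peso_flags_unavailable(self, square_breath_recording):
        (breath,) = segment_breaths(square_breath_recording, min_duration=0.1)
        mech = transpulmonary(square_breath_recording, breath,
                              breath_pressures(square_breath_recording, breath))
        assert np.isnan(mech.Ptrans_peak)
        assert any("no_peso" in f for f in mech.flags)


class TestEquationOfMotion:
    def test_exact_recovery_on_noiseless_linear_data(self, clean_recording):
        b = segment_breaths(clean_recording)[0]
        fit = fit_equation_of_motion(clean_recording, b, model="linear")
        assert fit.E == pytest.approx(57.3, rel=1e-6)
        assert fit.R == pytest.approx(12.4, rel=1e-6)
        assert fit.P0 == pytest.approx(5.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_volume_dependent_recovery_and_negative_pctE2(self, vcv_settings):
        lung = LungModelParams(E1=70.0, E2=-45.0, R=12.4, PEEP=9.0)
        rec = simulate_ventilation(vcv_settings, lung, n_breaths=3)
        b = segment_breaths(rec)[0]
        fit = fit_equation_of_motion(rec, b, model="volume_dependent")
        assert fit.E1 == pytest.approx(70.0, rel=1e-6)
        assert fit.E2 == pytest.approx(-45.0, rel=1e-6)
        vt = 0.300
        assert fit.pctE2 == pytest.approx(
            100.0 * -45.0 * vt / (70.0 - 45.0 * vt), rel=1e-6)
        assert fit.pctE2 < 0

    def test_noisy_monte_carlo_recovery(self, vcv_settings):
        # per-breath E and R stay within 5 % of truth at sigma=0.5 cmH2O
        for seed in range(5):
            lung = LungModelParams(E1=57.3, E2=0.0, R=12.4, PEEP=5.0,
                                   noise_sigma=0.5, seed=seed)
            rec = simulate_ventilation(vcv_settings, lung, n_breaths=4)
            for b in segment_breaths(rec):
                fit = fit_equation_of_motion(rec, b, model="linear")
                assert fit.E == pytest.approx(57.3, rel=0.05)
                assert fit.R == pytest.approx(12.4, rel=0.05)

    def test_zero_flow_design_is_rank_deficient(self):
        rec = WaveformRecording(time=np.arange(100) / 100.0,
                                paw=np.full(100, 5.0), flow=np.zeros(100),
                                sample_rate=100.0)
        from vilipower.resp_mechanics import Breath

        breath = Breath(onset=0, insp_end=50, end=100)
        breath.volume = integrate_volume(rec, breath)
        with pytest.raises(FitError):
            fit_equation_of_motion(rec, breath, model="linear")
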