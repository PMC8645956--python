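import numpy as np
import pytest

from vilipower import (
    PlasmaInput,
    TimeActivityCurve,
    TracerModelParams,
    delta_kis,
    fit_2tc_irreversible,
    interpolate_plasma,
    normalize_kis,
    patlak_fit,
    simulate_tracer,
)
from vilipower.pet_kinetics import (
    KineticsError,
    _frame_means,
    _solve_2tc,
    _tissue_grid,
    patlak_map,
    roi_median_from_nifti,
)
from vilipower.synthetic_data import feng_plasma


class TestPlasmaInterpolation:
    def test_constant_input_integrates_linearly(self):
        plasma = PlasmaInput(times=[0.0, 10.0, 20.0], activity=[3.0, 3.0, 3.0])
        cp, integral = interpolate_plasma(plasma, [5.0, 17.0])
        np.testing.assert_allclose(cp, 3.0)
        np.testing.assert_allclose(integral, [15.0, 51.0])

    def test_linear_decay_matches_trapezoid(self):
        plasma = PlasmaInput(times=[0.0, 1.0, 2.0], activity=[10.0, 6.0, 2.0])
        _, integral = interpolate_plasma(plasma, 1.5)
        assert integral[0] == pytest.approx(8.0 + (6.0 + 4.0) / 2 * 0.5)

    def test_feng_samples_integral_close_to_dense_oracle(self):
        # realistic schedule: 10-s sampling through the input peak, then
        # 0.5-min; the piecewise-linear integral tracks dense quadrature
        cp = feng_plasma()
        coarse_t = np.unique(np.concatenate([
            np.arange(0.0, 3.0, 10.0 / 60.0), np.arange(3.0, 60.01, 0.5)]))
        plasma = PlasmaInput(times=coarse_t,
                             activity=np.maximum(cp(coarse_t), 0.0))
        dense_t = np.linspace(0.0, 60.0, 120001)
        oracle = np.trapezoid(np.maximum(cp(dense_t), 0.0), dense_t)
        _, integral = interpolate_plasma(plasma, 60.0)
        assert integral[0] == pytest.approx(oracle, rel=0.01)

    def test_extrapolation_rejected(self):
        plasma = PlasmaInput(times=[0.0, 1.0, 2.0], activity=[1.0, 1.0, 1.0])
        with pytest.raises(KineticsError):
            interpolate_plasma(plasma, 2.5)


@pytest.fixture(scope="module")
def noiseless_2tc():
    """Noiseless pure-tissue (Vb=0) irreversible 2TC curve, Ki = 0.002/min."""
    params = TracerModelParams(K1=0.01, k2=0.2, k3=0.05, Vb=0.0)
    plasma, tac = simulate_tracer(params)
    return params, plasma, tac


class TestPatlak:
    def test_exact_linear_accumulation(self):
        plasma = PlasmaInput(times=np.arange(0.0, 75.1, 0.5),
                             activity=np.full(151, 4.0))
        starts = np.arange(0.0, 70.0, 5.0)
        durs = np.full_like(starts, 5.0)
        mids = starts + durs / 2
        _, icp = interpolate_plasma(plasma, mids)
        tac = TimeActivityCurve(frame_starts=starts, frame_durations=durs,
                                activity=0.01 * icp)
        fit = patlak_fit(tac, plasma, t_star=10.0)
        assert fit.Ki == pytest.approx(0.01, rel=1e-6)
        assert fit.V0 == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_2tc_simulation_recovery(self, noiseless_2tc):
        params, plasma, tac = noiseless_2tc
        fit = patlak_fit(tac, plasma, t_star=20.0)
        assert fit.Ki == pytest.approx(params.Ki_true, rel=0.05)

    def test_noisy_median_recovery(self):
        kis = []
        for seed in range(30):
            params = TracerModelParams(K1=0.01, k2=0.2, k3=0.05, Vb=0.0,
                                       noise_scale=0.05, seed=seed)
            plasma, tac = simulate_tracer(params)
            kis.append(patlak_fit(tac, plasma, t_star=20.0).Ki)
        assert np.median(kis) == pytest.approx(0.002, rel=0.10)

    def test_slope_approaches_ki_with_later_t_star(self, noiseless_2tc):
        params, plasma, tac = noiseless_2tc
        errs = [abs(patlak_fit(tac, plasma, t_star=ts).Ki - params.Ki_true)
                for ts in (5.0, 20.0, 40.0)]
        assert errs[2] < errs[0]

    def test_too_few_frames_rejected(self, noiseless_2tc):
        _, plasma, tac = noiseless_2tc
        with pytest.raises(KineticsError):
            patlak_fit(tac, plasma, t_star=70.0)


class TestCompartmentFit:
    def test_inverse_crime_recovery_is_exact(self):
        params = TracerModelParams(Vb=0.05)
        plasma, tac = simulate_tracer(params)
        starts, durs = tac.frame_starts, tac.frame_durations
        grid, cp = _tissue_grid(plasma, float(starts[-1] + durs[-1]))
        tissue = _solve_2tc(grid, cp, 0.01, 0.2, 0.05)
        act = (0.95 * _frame_means(grid, tissue, starts, durs)
               + 0.05 * _frame_means(grid, cp, starts, durs))
        self_gen = TimeActivityCurve(frame_starts=starts,
                                     frame_durations=durs, activity=act)
        fit = fit_2tc_irreversible(self_gen, plasma)
        assert fit.K1 == pytest.approx(0.01, rel=0.01)
        assert fit.k2 == pytest.approx(0.2, rel=0.01)
        assert fit.k3 == pytest.approx(0.05, rel=0.01)
        assert fit.Vb == pytest.approx(0.05, abs=0.01)

    def test_zero_blood_fraction_stays_small(self, noiseless_2tc):
        _, plasma, tac = noiseless_2tc
        fit = fit_2tc_irreversible(tac, plasma)
        assert fit.Vb <= 0.02

    def test_macro_parameter_agrees_with_patlak(self, noiseless_2tc):
        _, plasma, tac = noiseless_2tc
        comp = fit_2tc_irreversible(tac, plasma)
        pat = patlak_fit(tac, plasma, t_star=20.0)
        assert pat.Ki == pytest.approx(comp.Ki, rel=0.05)


class TestNormalization:
    def test_identity_without_gas_or_blood(self):
        assert normalize_kis(0.005, 0.0, 0.0).KiS == 0.005

    def test_arithmetic(self):
        res = normalize_kis(0.007, 0.5, 0.15)
        assert res.KiS == pytest.approx(0.02)
        assert res.F_Tissue == pytest.approx(0.35)

    def test_no_tissue_is_domain_error(self):
        with pytest.raises(ValueError):
            normalize_kis(0.007, 0.9, 0.1)

    def test_normalization_inflates(self):
        assert normalize_kis(0.004, 0.3, 0.1).KiS > 0.004

    def test_delta_kis_median_difference(self):
        rng = np.random.default_rng(0)
        first = rng.normal(0.0136, 0.002, 501)
        second = rng.normal(0.0320, 0.008, 501)
        expected = np.median(second) - np.median(first)
        assert delta_kis(first, second) == pytest.approx(expected)
        assert delta_kis(first, first) == 0.0
        assert delta_kis(first, first + 0.004) == pytest.approx(0.004)

    def test_reported_medians_difference(self):
        # scan medians 0.0136 and 0.0320 1/min give a 0.0184 increase
        assert delta_kis([0.0136], [0.0320]) == pytest.approx(0.0184)


class TestVoxelPathways:
    def test_patlak_map_matches_roi_fit(self, noiseless_2tc):
        _, plasma, tac = noiseless_2tc
        frames = np.tile(tac.activity, (2, 3, 1))
        ki_map = patlak_map(frames, tac.frame_starts, tac.frame_durations,
                            plasma, t_star=20.0)
        roi_fit = patlak_fit(tac, plasma, t_star=20.0)
        np.testing.assert_allclose(ki_map, roi_fit.Ki, rtol=1e-9)

    def test_roi_median_from_nifti(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        ki = np.arange(27, dtype=float).reshape(3, 3, 3) / 1000.0
        mask = np.zeros((3, 3, 3), dtype=np.uint8)
        mask[1] = 1
        nib.save(nib.Nifti1Image(ki, np.eye(4)), tmp_path / "ki.nii")
        nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "mask.nii")
        med = roi_median_from_nifti(tmp_path / "ki.nii", tmp_path / "mask.nii")
        assert med == pytest.approx(np.median(ki[mask > 0]))
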