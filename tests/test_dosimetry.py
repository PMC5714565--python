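"""Convolution dose-rate maps and decay integration to total dose."""

import numpy as np
import pytest
from scipy import integrate

import sirtdose as sd
from sirtdose.dosimetry import DecayModel, total_absorbed_energy_j
from sirtdose.errors import GeometryError, TimeError


def brute_force_dose_rate(activity, kernel):
    """Direct double-loop summation oracle (zero-padded boundary)."""
    pv = activity.values * activity.voxel_volume_cm3
    nx, ny, nz = pv.shape
    c = kernel.center
    out = np.zeros_like(pv)
    for (si, sj, sk), a in np.ndenumerate(pv):
        if a == 0:
            continue
        for (oi, oj, ok), s in np.ndenumerate(kernel.svalues):
            ti, tj, tk = si + oi - c[0], sj + oj - c[1], sk + ok - c[2]
            if 0 <= ti < nx and 0 <= tj < ny and 0 <= tk < nz:
                out[ti, tj, tk] += a * s
    return out


def make_activity(values, spacing, tref=None):
    return sd.ImageGrid(values, spacing, quantity=sd.Quantity.ACTIVITY_CONC,
                        reference_time_h=tref)


class TestDoseRateMap:
    def test_single_voxel_source_reproduces_kernel(self, kernel6):
        v = np.zeros((9, 9, 9))
        vox_ml = 6.0 ** 3 / 1000.0
        v[4, 4, 4] = 1.0 / vox_ml  # exactly 1 Bq in the central voxel
        rate = sd.dose_rate_map(make_activity(v, (6, 6, 6)), kernel6)
        err = np.abs(rate.values[1:8, 1:8, 1:8] - kernel6.svalues).max()
        assert err <= 1e-10 * kernel6.svalues.max()

    def test_linearity(self, kernel6, rng):
        v = rng.random((8, 8, 8)) * 1e4
        r1 = sd.dose_rate_map(make_activity(v, (6, 6, 6)), kernel6)
        r2 = sd.dose_rate_map(make_activity(2 * v, (6, 6, 6)), kernel6)
        assert np.abs(r2.values - 2 * r1.values).max() <= 1e-12 * r1.values.max()

    def test_matches_direct_summation_oracle(self, kernel6, rng):
        v = rng.random((10, 9, 8)) * 1e4
        act = make_activity(v, (6, 6, 6))
        rate = sd.dose_rate_map(act, kernel6)
        oracle = brute_force_dose_rate(act, kernel6)
        assert np.abs(rate.values - oracle).max() <= 1e-10 * oracle.max()

    def test_uniform_region_reaches_equilibrium_dose_rate(self, kernel6):
        """In a region large vs the kernel support the dose rate equals
        concentration x voxel volume x sum(S) — equivalently C.E/rho."""
        conc = 1e5  # Bq/ml
        act = make_activity(np.full((15, 15, 15), conc), (6, 6, 6))
        rate = sd.dose_rate_map(act, kernel6)
        expected = conc * act.voxel_volume_cm3 * kernel6.svalues.sum()
        assert rate.values[7, 7, 7] == pytest.approx(expected, rel=1e-10)
        # cross-check against the analytic equilibrium C * E / rho
        rho_kg_per_ml = 1e-3
        assert expected == pytest.approx(
            conc * kernel6.energy_per_decay_j / rho_kg_per_ml, rel=1e-12)

    def test_pitch_mismatch_rejected(self, kernel6):
        act = make_activity(np.ones((5, 5, 5)), (5.47, 5.47, 3.27))
        with pytest.raises(GeometryError, match="resample"):
            sd.dose_rate_map(act, kernel6)

    def test_negative_activity_rejected(self, kernel6):
        v = np.zeros((5, 5, 5))
        v[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            sd.dose_rate_map(make_activity(v, (6, 6, 6)), kernel6)


class TestDecayModel:
    def test_inconsistent_lambda_half_life_rejected(self):
        with pytest.raises(ValueError):
            DecayModel(lambda_per_day=0.30, half_life_days=2.67)

    def test_default_constants_consistent(self):
        d = DecayModel()
        assert d.lambda_per_day == pytest.approx(np.log(2) / 2.67, rel=1e-3)


class TestIntegrateToTotalDose:
    def test_zero_rate_gives_zero_dose(self):
        g = sd.ImageGrid(np.zeros((3, 3, 3)), (2, 2, 2),
                         quantity=sd.Quantity.DOSE_RATE, reference_time_h=0.0)
        dose = sd.integrate_to_total_dose(g, DecayModel())
        assert np.all(dose.values == 0)
        assert dose.quantity is sd.Quantity.DOSE

    def test_closed_form_matches_numerical_quadrature(self):
        """R0 = 4 Gy/h at administration integrates to ~369.8 Gy."""
        decay = DecayModel()
        r0_gy_per_s = 4.0 / 3600.0
        g = sd.ImageGrid(np.full((2, 2, 2), r0_gy_per_s), (2, 2, 2),
                         quantity=sd.Quantity.DOSE_RATE, reference_time_h=0.0)
        dose = sd.integrate_to_total_dose(g, decay)
        lam_h = decay.lambda_per_hour
        assert dose.values[0, 0, 0] == pytest.approx(4.0 / lam_h, rel=1e-12)
        assert dose.values[0, 0, 0] == pytest.approx(369.8, abs=0.1)
        quad, _ = integrate.quad(lambda t: 4.0 * np.exp(-lam_h * t),
                                 0, 10 * decay.half_life_days * 24)
        assert dose.values[0, 0, 0] == pytest.approx(quad, rel=1e-3)

    @pytest.mark.parametrize("lam", [0.1, 0.2596, 0.5, 1.0])
    def test_quadrature_agreement_across_decay_constants(self, lam):
        decay = DecayModel.from_half_life(np.log(2) / lam)
        g = sd.ImageGrid(np.full((2, 2, 2), 1e-3), (2, 2, 2),
                         quantity=sd.Quantity.DOSE_RATE, reference_time_h=0.0)
        dose = sd.integrate_to_total_dose(g, decay)
        quad, _ = integrate.quad(
            lambda t: 1e-3 * np.exp(-decay.lambda_per_second * t),
            0, 200 / decay.lambda_per_second, limit=200)
        assert dose.values[0, 0, 0] == pytest.approx(quad, rel=1e-3)

    def test_decay_correction_factor_at_5_hours(self):
        decay = DecayModel()
        g = sd.ImageGrid(np.full((2, 2, 2), 1e-3), (2, 2, 2),
                         quantity=sd.Quantity.DOSE_RATE, reference_time_h=5.0)
        corrected = sd.integrate_to_total_dose(g, decay)
        uncorrected = sd.integrate_to_total_dose(g, decay, decay_correct=False)
        factor = corrected.values[0, 0, 0] / uncorrected.values[0, 0, 0]
        assert factor == pytest.approx(np.exp(decay.lambda_per_day * 5 / 24),
                                       rel=1e-12)
        assert factor == pytest.approx(1.0556, abs=2e-4)

    def test_imaging_before_administration_rejected(self):
        g = sd.ImageGrid(np.zeros((2, 2, 2)), (2, 2, 2),
                         quantity=sd.Quantity.DOSE_RATE, reference_time_h=1.0)
        with pytest.raises(TimeError):
            sd.integrate_to_total_dose(g, DecayModel(), t_admin_h=2.0)


class TestPipeline:
    def test_recovers_forward_simulated_dose(self, small_patient):
        vp = small_patient
        counts = sd.activity_to_counts(vp.activity_truth, 0.32)
        dose = sd.run_dose_pipeline(counts, 0.32, vp.kernel, vp.decay)
        rmse = np.sqrt(np.mean((dose.values - vp.dose_truth.values) ** 2))
        assert rmse < 0.02 * vp.dose_truth.values.max()

    def test_total_energy_closes_against_activity_budget(self, small_patient):
        vp = small_patient
        expected = (vp.admin_activity_gbq * 1e9 / vp.decay.lambda_per_second
                    * vp.kernel.energy_per_decay_j)
        measured = total_absorbed_energy_j(vp.dose_truth)
        tol = abs(vp.kernel.truncation_fraction()) + 0.01
        assert abs(measured / expected - 1.0) < tol

    def test_zero_count_pet_gives_zero_dose(self, kernel6, tmp_path):
        pet = sd.ImageGrid(np.zeros((12, 12, 12)), (6, 6, 6),
                           quantity=sd.Quantity.COUNT_RATE, reference_time_h=0.0)
        dose = sd.run_dose_pipeline(pet, 0.32, kernel6,
                                    rtdose_path=tmp_path / "z.dcm")
        assert np.all(dose.values == 0)
        assert np.all(sd.read_image(tmp_path / "z.dcm").values == 0)

    def test_resample_and_integration_commute(self, small_patient):
        """Both maps are linear, so CT-grid resampling before or after the
        decay integration gives identical dose grids."""
        vp = small_patient
        rate = sd.dose_rate_map(vp.activity_truth, vp.kernel)
        tgt = sd.GridGeometry((48, 48, 48), (6.0, 6.0, 6.0), (10.0, 10.0, 10.0))
        a = sd.integrate_to_total_dose(
            sd.resample_to_grid(rate, tgt), vp.decay)
        b = sd.resample_to_grid(
            sd.integrate_to_total_dose(rate, vp.decay), tgt)
        assert np.allclose(a.values, b.values, rtol=1e-12)
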