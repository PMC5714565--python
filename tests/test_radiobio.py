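"""LQ-model BED/EQ2 conversions and the Poisson TCP model."""

import numpy as np
import pytest
from scipy import integrate

import sirtdose as sd
from sirtdose.dvh import DoseQuantity, DVHCurve
from sirtdose.errors import MaskError, QuantityError
from sirtdose.radiobio import eq2_from_dose


def uniform_curve(dose_gy, volume_cm3, width=0.5):
    n = int(np.ceil(dose_gy / width)) + 1
    edges = width * np.arange(n + 1)
    vols = np.zeros(n)
    vols[int(dose_gy / width)] = volume_cm3
    return DVHCurve(edges, vols, "roi")


class TestBed:
    def test_zero_dose_zero_bed(self, tumor_params):
        assert sd.bed_from_dose(0.0, tumor_params) == 0.0

    def test_permanent_implant_worked_example(self, tumor_params):
        """112.5 Gy with alpha/beta 10, repair T1/2 1 h, lambda 0.2596/d:
        mu = 16.64/d, R0 = 29.2 Gy/d, BED ~ 131.9 Gy."""
        assert tumor_params.mu_per_day == pytest.approx(16.636, abs=1e-3)
        bed = sd.bed_from_dose(112.5, tumor_params)
        assert bed == pytest.approx(131.9, abs=0.05)

    def test_closed_form_matches_lea_catcheside_quadrature(self, tumor_params):
        """Oracle: BED = D(1 + G.D/(a/b)) with the dose-protraction factor
        G = 2/D^2 * int R(t) int R(t') e^(-mu(t-t')) dt' dt for a
        mono-exponential dose rate, evaluated numerically."""
        p = tumor_params
        d_total = 80.0
        lam, mu = p.lambda_per_day, p.mu_per_day
        r0 = d_total * lam  # Gy/day

        def inner(t):
            f, _ = integrate.quad(
                lambda u: r0 * np.exp(-lam * u) * np.exp(-mu * (t - u)), 0, t)
            return r0 * np.exp(-lam * t) * f

        num, _ = integrate.quad(inner, 0, 120, limit=300)
        g_factor = 2.0 * num / d_total ** 2
        bed_oracle = d_total * (1.0 + g_factor * d_total / p.alpha_beta_gy)
        assert sd.bed_from_dose(d_total, p) == pytest.approx(bed_oracle, rel=1e-4)

    def test_bed_exceeds_dose_and_is_convex(self, tumor_params):
        d = np.linspace(0, 200, 50)
        bed = sd.bed_from_dose(d, tumor_params)
        assert np.all(bed[1:] > d[1:])
        assert np.all(np.diff(bed, 2) > -1e-9)  # convex

    def test_high_alpha_beta_limit_recovers_physical_dose(self):
        p = sd.RadiobioParams(alpha_beta_gy=1e9)
        assert sd.bed_from_dose(100.0, p) == pytest.approx(100.0, rel=1e-6)

    def test_negative_dose_rejected(self, tumor_params):
        with pytest.raises(ValueError):
            sd.bed_from_dose(-1.0, tumor_params)


class TestEq2:
    @pytest.mark.parametrize("bed,alpha_beta,expected", [
        (139.3, 10.0, 116.1),   # target rows
        (140.3, 10.0, 116.9),
        (62.0, 10.0, 51.7),
        (151.7, 10.0, 126.4),
        (195.6, 10.0, 163.0),
        (54.4, 2.5, 30.2),      # normal-liver row
    ])
    def test_reference_conversions(self, bed, alpha_beta, expected):
        p = sd.RadiobioParams(alpha_beta_gy=alpha_beta)
        assert round(sd.eq2_from_bed(bed, p), 1) == expected

    def test_zero_maps_to_zero(self, tumor_params):
        assert sd.eq2_from_bed(0.0, tumor_params) == 0.0

    def test_low_dose_rate_limit_consistent_with_fractionation(self):
        """As repair becomes instantaneous (mu -> inf), BED -> D and
        EQ2 -> D/(1 + 2/(a/b)): the fractionated formula at vanishing
        dose per fraction."""
        p = sd.RadiobioParams(alpha_beta_gy=10.0, repair_half_life_h=1e-9)
        assert sd.bed_from_dose(60.0, p) == pytest.approx(60.0, rel=1e-6)
        assert eq2_from_dose(60.0, p) == pytest.approx(60.0 / 1.2, rel=1e-6)


class TestTransformDvh:
    def test_single_bin_maps_through_bed(self, tumor_params):
        curve = uniform_curve(112.5, 80.0)
        out = sd.transform_dvh(curve, tumor_params, DoseQuantity.BED)
        assert out.total_volume_cm3 == pytest.approx(80.0)
        occupied = out.bin_centers[out.diff_volume_cm3 > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(131.9, abs=out.bin_width)

    def test_volume_conserved_for_random_curves(self, rng):
        for _ in range(10):
            n = rng.integers(5, 60)
            vols = rng.random(n) * 10
            curve = DVHCurve(0.5 * np.arange(n + 1), vols, "roi")
            out = sd.transform_dvh(curve, sd.RadiobioParams.tumor(), "EQ2")
            assert out.total_volume_cm3 == pytest.approx(curve.total_volume_cm3,
                                                         rel=1e-12)

    def test_mean_bed_exceeds_bed_of_mean_by_jensen(self, tumor_params):
        """BED is strictly convex in dose, so the dDVH-wise mean BED of an
        inhomogeneous structure exceeds the BED of its mean dose."""
        edges = np.array([0.0, 0.5, 199.5, 200.0])
        vols = np.array([50.0, 0.0, 50.0])
        curve = DVHCurve(edges, vols, "roi")
        out = sd.transform_dvh(curve, tumor_params, DoseQuantity.BED)
        mean_dose = (curve.bin_centers * vols).sum() / vols.sum()
        assert out.mean_gy > sd.bed_from_dose(mean_dose, tumor_params)

    def test_non_physical_input_rejected(self, tumor_params):
        curve = uniform_curve(50.0, 10.0)
        bed = sd.transform_dvh(curve, tumor_params, DoseQuantity.BED)
        with pytest.raises(QuantityError):
            sd.transform_dvh(bed, tumor_params, DoseQuantity.EQ2)

    def test_eq2_curve_dominates_physical_at_high_dose(self, small_patient,
                                                       tumor_params):
        """Cumulative EQ2 DVH of a hot tumour lies above the physical DVH at
        high doses: per-bin BED inflation shifts volume upward."""
        vp = small_patient
        curve = sd.compute_dvh(vp.dose_truth, vp.gtv_masks[0])
        eq2 = sd.transform_dvh(curve, tumor_params, DoseQuantity.EQ2)
        d_probe = np.quantile(vp.dose_truth.values[vp.gtv_masks[0].indices], 0.8)
        assert eq2.volume_at_least(d_probe) > curve.volume_at_least(d_probe)


class TestTcp:
    def test_cold_bin_drives_tcp_to_zero(self, tumor_params):
        """Any zero-dose bin of >= 1 cm3 at rho = 1e7 contributes a factor
        exp(-1e7): TCP underflows to exactly 0.0."""
        edges = np.array([0.0, 0.5, 99.5, 100.0])
        vols = np.array([1.0, 0.0, 200.0])
        curve = DVHCurve(edges, vols, "roi")
        assert sd.tcp_from_dvh(curve, tumor_params) == 0.0

    def test_half_control_crossing_dose(self, tumor_params):
        """For a single bin with rho.V = 1e7, TCP = 0.5 exactly at
        D = ln(rho V / ln 2)/alpha ~ 49.95 Gy."""
        d50 = np.log(1e7 / np.log(2)) / tumor_params.alpha_per_gy
        assert d50 == pytest.approx(49.95, abs=0.01)
        curve = DVHCurve(np.array([d50 - 0.005, d50 + 0.005]), np.array([1.0]),
                         "roi")
        assert sd.tcp_from_dvh(curve, tumor_params) == pytest.approx(0.5, abs=1e-3)

    def test_monotone_in_dose_and_density(self, tumor_params):
        tcps = [sd.tcp_from_dvh(uniform_curve(d, 1.0), tumor_params)
                for d in (55, 60, 65, 70)]
        assert np.all(np.diff(tcps) > 0)
        dense = sd.RadiobioParams.tumor(clonogen_density_per_cm3=1e8)
        assert (sd.tcp_from_dvh(uniform_curve(60, 1.0), dense)
                < sd.tcp_from_dvh(uniform_curve(60, 1.0), tumor_params))

    def test_binned_tcp_matches_voxelwise_product(self, small_patient,
                                                  tumor_params):
        vp = small_patient
        gtv = vp.gtv_masks[0]
        doses = vp.dose_truth.values[gtv.indices]
        oracle = sd.tcp_from_voxels(doses, vp.dose_truth.voxel_volume_cm3,
                                    tumor_params)
        curve = sd.compute_dvh(vp.dose_truth, gtv, bin_width_gy=0.01)
        tcp = sd.tcp_from_dvh(curve, tumor_params)
        if oracle == 0.0:
            assert tcp == 0.0
        else:
            assert tcp == pytest.approx(oracle, rel=1e-3)

    def test_empty_structure_rejected(self, tumor_params):
        curve = DVHCurve(np.array([0.0, 0.5]), np.array([0.0]), "roi")
        with pytest.raises(MaskError):
            sd.tcp_from_dvh(curve, tumor_params)


class TestMeanDoseTable:
    def test_uniform_structure_mean_bed_equals_pointwise(self, tumor_params):
        curve = uniform_curve(100.0, 60.0)
        row = sd.mean_dose_table([(curve, tumor_params)]).iloc[0]
        center = curve.bin_centers[curve.diff_volume_cm3 > 0][0]
        assert row["mean_bed_gy"] == pytest.approx(
            sd.bed_from_dose(center, tumor_params), rel=1e-12)

    def test_two_level_structure_shows_jensen_gap(self, tumor_params):
        edges = np.array([0.0, 0.5, 149.5, 150.0])
        curve = DVHCurve(edges, np.array([30.0, 0.0, 30.0]), "roi")
        row = sd.mean_dose_table([(curve, tumor_params)]).iloc[0]
        assert row["mean_bed_gy"] > sd.bed_from_dose(row["mean_dose_gy"],
                                                     tumor_params)

    def test_eq2_column_relation(self, small_patient):
        """Mean EQ2 is the bin-wise EQ2 mean; for each structure it equals
        the BED mean scaled per bin, not mean BED / 1.2 exactly — but with a
        dose-independent denominator the two coincide."""
        vp = small_patient
        params = sd.RadiobioParams.tumor()
        curve = sd.compute_dvh(vp.dose_truth, vp.gtv_masks[0])
        row = sd.mean_dose_table([(curve, params)]).iloc[0]
        assert row["mean_eq2_gy"] == pytest.approx(
            row["mean_bed_gy"] / (1 + 2 / params.alpha_beta_gy), rel=1e-12)
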