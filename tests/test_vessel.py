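import numpy as np
import pytest

import balloonmech as bm
from balloonmech.errors import InvalidInputError
from balloonmech.synthetic import NoiseSpec, gen_compliance
from balloonmech.vessel import (
    ComplianceRecord,
    CylinderPhantom,
    compare_final_volume,
    cylinder_pv_response,
    distensibility,
    hoop_strain,
    hoop_stress,
    linearized_distensibility,
    load_composite_table,
    radius_from_volume,
    young_modulus_from_compliance,
)


@pytest.fixture()
def soft_cylinder():
    """Uniform thin-walled test cylinder (no end bands)."""
    return CylinderPhantom(inner_diameter_mm=20.0, thickness_mm=0.8, length_mm=60.0)


@pytest.fixture()
def soft_material():
    return bm.LinearElasticModel(young_modulus=1.0, poisson=0.25)


class TestLaplaceBlock:
    def test_radius_from_volume_inverts_cylinder_volume(self):
        assert radius_from_volume(12.566, 40.0) == pytest.approx(10.0, abs=1e-3)

    def test_radius_roundtrip_with_revolved_volume(self):
        from balloonmech.geometry import solid_of_revolution_volume
        from balloonmech.units import mm3_to_ml

        z = np.linspace(0.0, 55.0, 20)
        r = np.full(20, 7.3)
        v = mm3_to_ml(solid_of_revolution_volume(z, r))
        assert radius_from_volume(v, 55.0) == pytest.approx(7.3, rel=1e-12)

    def test_hoop_stress_arithmetic_and_scaling(self):
        assert hoop_stress(0.0, 2.0, 0.5) == 0.0
        assert hoop_stress(1.0, 2.0, 0.5) == pytest.approx(4.0)
        assert hoop_stress(1.0, 2.0, 1.0) == pytest.approx(2.0)  # doubling t halves
        with pytest.raises(InvalidInputError):
            hoop_stress(1.0, 2.0, 0.0)

    def test_hoop_strain_sign_convention(self):
        assert hoop_strain(10.0, 10.0) == 0.0
        assert hoop_strain(11.0, 10.0) == pytest.approx(0.1)
        assert hoop_strain(9.0, 10.0) < 0.0
        with pytest.raises(InvalidInputError):
            hoop_strain(1.0, 0.0)


class TestDistensibility:
    def test_definition_arithmetic(self):
        rec = ComplianceRecord(
            pressure_mmhg=[0.0, 10.0], volume_ml=[10.0, 11.0], initial_volume_ml=10.0
        )
        assert distensibility(rec) == pytest.approx(0.01)

    def test_matches_linearized_closed_form_on_synthetic_cylinder(
        self, soft_cylinder, soft_material
    ):
        rec = gen_compliance(
            soft_cylinder, soft_material, pressures_mmhg=np.linspace(0.0, 10.0, 11)
        )
        d = distensibility(rec)
        d_lin = linearized_distensibility(1.0, 10.0, 0.8)
        assert d == pytest.approx(d_lin, rel=0.02)

    def test_limit_equivalence_at_small_strain(self, soft_cylinder, soft_material):
        """distensibility -> 2r/(Et) as the pressure window shrinks."""
        rec = gen_compliance(
            soft_cylinder, soft_material, pressures_mmhg=np.linspace(0.0, 1.0, 5)
        )
        assert distensibility(rec) == pytest.approx(
            linearized_distensibility(1.0, 10.0, 0.8), rel=0.01
        )

    def test_zero_pressure_window_rejected(self):
        rec = ComplianceRecord(pressure_mmhg=[0.0, 0.0], volume_ml=[10.0, 10.5])
        with pytest.raises(InvalidInputError):
            distensibility(rec)


class TestYoungModulusRecovery:
    def test_roundtrip_at_one_percent_strain(self, soft_cylinder, soft_material):
        # P = E*t*eps/r: 1 % strain at E = 1 MPa, r/t = 12.5 -> 0.0008 MPa
        p_max = 0.008 * 1.0 * 0.8 / 10.0 / 1.33322e-4 / 10  # ~1 % strain in mmHg
        rec = gen_compliance(
            soft_cylinder, soft_material, pressures_mmhg=np.linspace(0.0, p_max, 11)
        )
        e = young_modulus_from_compliance(rec, soft_cylinder)
        assert e == pytest.approx(1.0, rel=0.02)

    def test_pressure_unit_invariance(self, soft_cylinder, soft_material):
        rec = gen_compliance(
            soft_cylinder, soft_material, pressures_mmhg=np.linspace(0.0, 5.0, 6)
        )
        e_mmhg = young_modulus_from_compliance(rec, soft_cylinder, "mmHg")
        rec_pa = ComplianceRecord(
            pressure_mmhg=rec.pressure_mmhg * 133.322,
            volume_ml=rec.volume_ml,
            initial_volume_ml=rec.initial_volume_ml,
        )
        e_pa = young_modulus_from_compliance(rec_pa, soft_cylinder, "Pa")
        assert e_pa == pytest.approx(e_mmhg, rel=1e-12)

    def test_recovery_bias_grows_with_strain(self, soft_cylinder, soft_material):
        """Finite-strain bias of the linear formulas is monotone in strain."""
        errs = []
        for p_max in (2.0, 10.0, 40.0):
            rec = gen_compliance(
                soft_cylinder, soft_material,
                pressures_mmhg=np.linspace(0.0, p_max, 11),
            )
            e = young_modulus_from_compliance(rec, soft_cylinder)
            errs.append(abs(e - 1.0))
        assert errs[0] < errs[1] < errs[2]

    def test_zero_dilation_rejected(self, soft_cylinder):
        rec = ComplianceRecord(pressure_mmhg=[0.0, 5.0], volume_ml=[10.0, 10.0])
        with pytest.raises(InvalidInputError):
            young_modulus_from_compliance(rec, soft_cylinder)


class TestLinearizedDistensibility:
    def test_t100_value_consistent_with_bench_measurement(self):
        """2r/(Et) for the softest composite reproduces its measured D."""
        d = linearized_distensibility(0.55, 10.0, 0.8)
        assert d == pytest.approx(6.06e-3, abs=5e-5)
        assert d == pytest.approx(0.0060, rel=0.02)

    def test_halves_when_thickness_doubles(self):
        assert linearized_distensibility(1.0, 10.0, 1.6) == pytest.approx(
            0.5 * linearized_distensibility(1.0, 10.0, 0.8)
        )


class TestCylinderPVResponse:
    def test_zero_pressure_gives_reference_volume(self, soft_cylinder, soft_material):
        resp = cylinder_pv_response(soft_cylinder, soft_material, 0.0)
        assert resp.volume_ml == pytest.approx(soft_cylinder.reference_volume_ml())

    def test_radial_stiffness_free_length_limit(self, soft_cylinder, soft_material):
        resp = cylinder_pv_response(soft_cylinder, soft_material, 5.0)
        assert resp.radial_stiffness_mpa_per_mm == pytest.approx(
            1.0 * 0.8 / 10.0**2, rel=1e-12
        )

    def test_banded_volume_matches_numerical_quadrature(self, soft_material):
        phantom = CylinderPhantom(
            inner_diameter_mm=20.0, thickness_mm=0.8, length_mm=60.0, end_band_mm=10.6
        )
        resp = cylinder_pv_response(phantom, soft_material, 10.0)
        # brute-force integration of the tapered radius profile
        r_in, r_free, lb, length = 10.0, resp.free_radius_mm, 10.6, 60.0
        z = np.linspace(0.0, length, 200001)
        r = np.where(
            z < lb, r_in + (r_free - r_in) * z / lb,
            np.where(z > length - lb, r_in + (r_free - r_in) * (length - z) / lb, r_free),
        )
        v_ref = np.trapezoid(np.pi * r**2, z) / 1000.0
        assert resp.volume_ml == pytest.approx(v_ref, rel=1e-3)

    def test_large_strain_flags_model_validity(self, soft_cylinder, soft_material):
        high = cylinder_pv_response(soft_cylinder, soft_material, 200.0)
        assert not high.thin_wall_linear_ok
        low = cylinder_pv_response(soft_cylinder, soft_material, 5.0)
        assert low.thin_wall_linear_ok


class TestCompositeTable:
    def test_stiffness_and_distensibility_trends_are_monotone(self):
        """More VeroWhite -> stiffer and less distensible across the series."""
        table = load_composite_table()
        series = table[table["name"].isin(["T100", "T92", "T83", "T75"])]
        series = series.sort_values("vero_pct")
        assert series["young_modulus_mpa"].is_monotonic_increasing
        assert series["distensibility_per_mmhg"].is_monotonic_decreasing

    def test_implantation_site_material_properties_present(self):
        table = load_composite_table().set_index("name")
        assert table.loc["T50", "distensibility_per_mmhg"] == pytest.approx(0.00025)
        assert table.loc["T50", "young_modulus_mpa"] == pytest.approx(13.19)


class TestVolumeComparison:
    def test_reports_all_three_denominator_conventions(self):
        out = compare_final_volume(10.26, 9.97)
        assert out["pct_of_experimental"] == pytest.approx(100 * 0.29 / 10.26, rel=1e-6)
        assert out["pct_of_computational"] == pytest.approx(100 * 0.29 / 9.97, rel=1e-6)
        assert out["pct_of_mean"] == pytest.approx(100 * 0.29 / 10.115, rel=1e-6)
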