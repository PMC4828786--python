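import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import balloonmech as bm
from balloonmech.errors import InvalidInputError
from balloonmech.materials import (
    OgdenModel,
    StressStrainCurve,
    StretchState,
    check_isotropy,
    fit_ogden,
    ogden_energy,
    ogden_uniaxial_stress,
    residual_strain,
)
from balloonmech.synthetic import NoiseSpec, gen_uniaxial


class TestOgdenEnergy:
    def test_undeformed_reference_is_zero(self, balloon_material):
        assert ogden_energy(StretchState((1.0, 1.0, 1.0)), balloon_material) == 0.0

    def test_permutation_symmetry(self, balloon_material):
        a = ogden_energy(StretchState((1.10, 0.95, 0.96)), balloon_material)
        b = ogden_energy(StretchState((0.95, 1.10, 0.96)), balloon_material)
        assert a == pytest.approx(b, rel=1e-12)

    def test_hand_evaluated_neo_hookean_value(self):
        # N=1, mu=1, alpha=2, incompressible uniaxial at lambda=2:
        # U = (2/4)(4 + 0.5 + 0.5 - 3) = 1.0
        model = OgdenModel(mu=(1.0,), alpha=(2.0,))
        state = StretchState((2.0, 2.0**-0.5, 2.0**-0.5))
        assert ogden_energy(state, model) == pytest.approx(1.0, rel=1e-12)

    def test_volumetric_term_with_positive_delta(self):
        model = OgdenModel(mu=(1.0,), alpha=(2.0,), delta=(0.5,))
        j = 1.1
        state = StretchState((j ** (1 / 3),) * 3)  # pure dilation
        assert ogden_energy(state, model) == pytest.approx((j - 1.0) ** 2 / 0.5)

    def test_non_positive_stretch_rejected(self, balloon_material):
        with pytest.raises(InvalidInputError):
            ogden_energy(StretchState((1.0, 1.0, -0.2)), balloon_material)

    @given(
        l1=st.floats(0.7, 1.5),
        l2=st.floats(0.7, 1.5),
    )
    def test_nonnegative_for_incompressible_states(self, l1, l2):
        """U >= 0 on the incompressible manifold for a stable material."""
        model = OgdenModel(mu=(0.8, 0.3), alpha=(2.0, 4.0))
        state = StretchState((l1, l2, 1.0 / (l1 * l2)))
        assert ogden_energy(state, model) >= -1e-12


class TestUniaxialStress:
    def test_reference_state_is_stress_free(self, balloon_material):
        for conv in ("cauchy", "nominal"):
            assert ogden_uniaxial_stress(1.0, balloon_material, conv) == 0.0

    @pytest.mark.parametrize("lam", [0.8, 1.05, 1.3, 2.0])
    def test_neo_hookean_closed_form(self, lam):
        mu = 0.7
        model = OgdenModel(mu=(mu,), alpha=(2.0,))
        expected = mu * (lam**2 - 1.0 / lam)
        assert ogden_uniaxial_stress(lam, model) == pytest.approx(expected, rel=1e-12)

    def test_initial_nominal_tangent_is_three_sum_mu(self, balloon_material):
        h = 1e-6
        slope = (
            ogden_uniaxial_stress(1.0 + h, balloon_material, "nominal")
            - ogden_uniaxial_stress(1.0 - h, balloon_material, "nominal")
        ) / (2.0 * h)
        assert slope == pytest.approx(3.0 * sum(balloon_material.mu), rel=1e-6)

    @pytest.mark.parametrize("lam", [0.95, 1.05, 1.10])
    def test_stress_is_derivative_of_energy_along_uniaxial_path(
        self, balloon_material, lam
    ):
        """Nominal stress = dU/dlambda on the incompressible uniaxial path."""
        h = 1e-6

        def u(la):
            return ogden_energy(
                StretchState((la, la**-0.5, la**-0.5)), balloon_material
            )

        fd = (u(lam + h) - u(lam - h)) / (2.0 * h)
        nominal = ogden_uniaxial_stress(lam, balloon_material, "nominal")
        assert nominal == pytest.approx(fd, rel=1e-6)

    def test_invalid_stretch_rejected(self, balloon_material):
        with pytest.raises(InvalidInputError):
            ogden_uniaxial_stress(-1.0, balloon_material)


class TestOgdenModelValidation:
    def test_balloon_coefficients_have_positive_shear_modulus(self, balloon_material):
        assert balloon_material.initial_shear_modulus > 0.0
        assert balloon_material.order == 3

    def test_negative_shear_modulus_rejected(self):
        with pytest.raises(InvalidInputError):
            OgdenModel(mu=(-1.0, 0.5), alpha=(2.0, 4.0))

    def test_negative_delta_rejected(self):
        with pytest.raises(InvalidInputError):
            OgdenModel(mu=(1.0,), alpha=(2.0,), delta=(-0.1,))


class TestFitOgden:
    def test_roundtrip_on_noiseless_synthetic_data(self):
        """The fitted stress curve reproduces the generating curve to 1e-6."""
        truth = OgdenModel(mu=(0.8, 0.35), alpha=(1.7, 3.9))
        strain = np.linspace(0.0, 0.5, 60)
        curve = gen_uniaxial(truth, strain=strain)
        fit = fit_ogden(curve, order=2)
        lam = 1.0 + strain[1:]
        s_true = ogden_uniaxial_stress(lam, truth, "nominal")
        s_fit = ogden_uniaxial_stress(lam, fit.model, "nominal")
        rel = np.max(np.abs(s_fit - s_true)) / np.max(np.abs(s_true))
        assert rel < 1e-6
        assert fit.model.initial_shear_modulus > 0.0

    def test_small_strain_limit_recovers_linear_modulus(self):
        lin = bm.LinearElasticModel(young_modulus=2.0)
        curve = gen_uniaxial(lin, strain=np.linspace(0.0, 0.01, 30))
        fit = fit_ogden(curve, order=1)
        assert 3.0 * sum(fit.model.mu) == pytest.approx(2.0, rel=0.01)

    def test_underdetermined_fit_rejected(self):
        curve = StressStrainCurve(strain=[0.0, 0.05, 0.1], stress=[0.0, 1.0, 2.0])
        with pytest.raises(InvalidInputError):
            fit_ogden(curve, order=3)

    def test_invariance_under_stress_rescaling(self):
        truth = OgdenModel(mu=(0.8, 0.35), alpha=(1.7, 3.9))
        strain = np.linspace(0.0, 0.4, 50)
        curve = gen_uniaxial(truth, strain=strain)
        scaled = StressStrainCurve(strain=curve.strain, stress=1e3 * curve.stress)
        fit1 = fit_ogden(curve, order=2)
        fit2 = fit_ogden(scaled, order=2)
        lam = 1.0 + strain[1:]
        s1 = ogden_uniaxial_stress(lam, fit1.model, "nominal")
        s2 = ogden_uniaxial_stress(lam, fit2.model, "nominal")
        np.testing.assert_allclose(1e3 * s1, s2, rtol=1e-6)


class TestIsotropyCheck:
    def test_identical_curves_deviate_by_zero(self, balloon_material):
        c = gen_uniaxial(balloon_material, strain=np.linspace(0.0, 0.12, 100))
        assert check_isotropy(c, c, strain_max=0.10) == 0.0

    def test_constructed_uniform_deviation(self, balloon_material):
        c1 = gen_uniaxial(balloon_material, strain=np.linspace(0.0, 0.12, 400))
        c2 = StressStrainCurve(strain=c1.strain, stress=1.05 * c1.stress)
        # with the larger curve in the denominator: 0.05/1.05
        dev = check_isotropy(c1, c2, strain_max=0.10)
        assert dev == pytest.approx(0.05 / 1.05, abs=1e-3)

    def test_insufficient_strain_coverage_rejected(self, balloon_material):
        c = gen_uniaxial(balloon_material, strain=np.linspace(0.0, 0.05, 50))
        with pytest.raises(InvalidInputError):
            check_isotropy(c, c, strain_max=0.10)


class TestResidualStrain:
    def test_elastic_cycle_has_zero_residual(self, balloon_material):
        cycles = gen_uniaxial(
            balloon_material, cyclic=True, n_cycles=1, residual_offsets=[0.0]
        )
        assert residual_strain(cycles)[0] == pytest.approx(0.0, abs=1e-9)

    def test_constructed_offset_recovered(self, balloon_material):
        cycles = gen_uniaxial(
            balloon_material, cyclic=True, n_cycles=1, residual_offsets=[0.03]
        )
        assert residual_strain(cycles)[0] == pytest.approx(0.03, abs=1e-6)

    def test_ten_cycle_sequence_recovered(self, balloon_material):
        """Default ten-cycle offsets span the 3-5 % range typical of the film."""
        cycles = gen_uniaxial(balloon_material, cyclic=True, n_cycles=10)
        rec = np.asarray(residual_strain(cycles))
        np.testing.assert_allclose(rec, np.linspace(0.03, 0.05, 10), atol=1e-6)
        assert rec[0] >= 0.03 - 1e-9 and rec[-1] <= 0.05 + 1e-9

    def test_never_unloading_curve_rejected(self):
        curve = StressStrainCurve(
            strain=np.linspace(0.0, 0.1, 20), stress=np.linspace(0.0, 5.0, 20)
        )
        with pytest.raises(InvalidInputError):
            residual_strain([curve])
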