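import numpy as np
import pytest

import balloonmech as bm
from balloonmech.errors import InvalidInputError
from balloonmech.solver import (
    MembraneState,
    SolverOptions,
    cylindrical_membrane_pressure,
    enclosed_volume,
    equilibrium_residual,
    membrane_strain_energy,
    solve_constrained_inflation,
    solve_free_inflation,
)
from balloonmech.units import MPA_PER_MMHG


def _reference_state(mesh):
    n_el = mesh.n_elements
    return MembraneState(
        z_mm=mesh.z.copy(),
        r_mm=mesh.r.copy(),
        pressure_mmhg=0.0,
        volume_ml=mesh.reference_cavity_volume_ml(),
        lambda_m=np.ones(n_el),
        lambda_theta=np.ones(n_el),
        slack=np.zeros(n_el, dtype=bool),
        contact_pressure_mmhg=np.zeros(mesh.z.size),
    )


class TestEquilibriumResidual:
    def test_reference_configuration_is_exactly_balanced(
        self, default_design, balloon_material
    ):
        mesh = bm.build_profile_mesh(default_design, 60)
        res = equilibrium_residual(_reference_state(mesh), mesh, balloon_material)
        assert np.max(np.abs(res)) == 0.0

    def test_pressure_load_on_cylinder_equals_laplace_force(self, balloon_material):
        """Follower-load radial force on a straight cylinder = P * area."""
        design = bm.BalloonDesign(cylinder_length_mm=76.0, total_length_mm=80.0)
        mesh = bm.build_profile_mesh(design, 120)
        state = _reference_state(mesh)
        state.pressure_mmhg = 100.0
        res = equilibrium_residual(state, mesh, balloon_material)
        # interior cylinder node: radial residual = -P * (2 pi r dz)
        k = mesh.z.size // 2
        dz = 0.5 * (mesh.z[k + 1] - mesh.z[k - 1])
        p_mpa = 100.0 * MPA_PER_MMHG
        expected = -p_mpa * 2.0 * np.pi * mesh.r[k] * dz
        assert res[1, k] == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_stretch_reports_element(
        self, default_design, balloon_material
    ):
        mesh = bm.build_profile_mesh(default_design, 60)
        state = _reference_state(mesh)
        state.r_mm = state.r_mm.copy()
        state.r_mm[10] = -state.r_mm[10]
        with pytest.raises(InvalidInputError):
            equilibrium_residual(state, mesh, balloon_material)


class TestFreeInflation:
    def test_volume_constraint_at_every_step(self, free_inflation_run):
        for s in free_inflation_run.states:
            target = s.volume_ml
            assert abs(enclosed_volume(s) - target) / target <= 1e-6

    def test_pv_curve_strictly_increasing_in_taut_regime(self, free_inflation_run):
        curve = free_inflation_run.curve
        assert np.all(np.diff(curve.pressure_mmhg) > 0.0)

    def test_diameter_grows_with_volume(self, free_inflation_run):
        curve = free_inflation_run.curve
        assert np.all(np.diff(curve.diameter_mm) > 0.0)

    def test_long_cylinder_matches_closed_form(
        self, long_cylinder_design, balloon_material, mid_element_stretches
    ):
        """Mid-section P agrees with the analytic membrane cylinder to < 1 %."""
        mesh = bm.build_profile_mesh(long_cylinder_design, 120)
        v_ref = mesh.reference_cavity_volume_ml()
        targets = [v_ref * f for f in (1.06, 1.13, 1.20)]
        result = solve_free_inflation(
            long_cylinder_design, balloon_material,
            volume_targets_ml=targets, n_elements=120,
        )
        for s in result.states:
            lam_t, lam_z = mid_element_stretches(s, result.mesh)
            p_oracle = cylindrical_membrane_pressure(
                lam_t, lam_z, 11.5, 0.09, balloon_material
            )
            assert s.pressure_mmhg == pytest.approx(p_oracle, rel=0.01)

    def test_energy_consistency_with_injected_work(
        self, default_design, balloon_material
    ):
        """Work integral of P dV equals the stored-energy increase (taut)."""
        targets = list(np.arange(24.2, 25.4, 0.1))
        opts = SolverOptions(max_step_ml=0.1)
        result = solve_free_inflation(
            default_design, balloon_material,
            volume_targets_ml=targets, n_elements=80, options=opts,
        )
        states = [s for s in result.states if not s.slack.any()]
        assert len(states) >= 8
        p_mpa = np.array([s.pressure_mmhg * MPA_PER_MMHG for s in states])
        v_mm3 = np.array([s.volume_ml * 1000.0 for s in states])
        work = np.trapezoid(p_mpa, v_mm3)
        energies = [
            membrane_strain_energy(s, result.mesh, balloon_material) for s in states
        ]
        stored = energies[-1] - energies[0]
        assert work == pytest.approx(stored, rel=0.01)

    def test_mesh_convergence_of_pressure(self, default_design, balloon_material):
        p = {}
        for n in (100, 200):
            result = solve_free_inflation(
                default_design, balloon_material,
                volume_targets_ml=[25.0], n_elements=n,
            )
            p[n] = result.states[-1].pressure_mmhg
        assert abs(p[100] - p[200]) / p[200] < 0.005

    def test_reference_volume_target_gives_zero_pressure(
        self, default_design, balloon_material
    ):
        mesh = bm.build_profile_mesh(default_design, 60)
        v_ref = mesh.reference_cavity_volume_ml()
        result = solve_free_inflation(
            default_design, balloon_material, volume_targets_ml=[v_ref], n_elements=60
        )
        s = result.states[0]
        assert s.pressure_mmhg == pytest.approx(0.0, abs=1e-6)
        assert s.central_diameter_mm() == pytest.approx(23.0, abs=1e-9)

    def test_deterministic_bitwise_identical(self, default_design, balloon_material):
        runs = [
            solve_free_inflation(
                default_design, balloon_material,
                volume_targets_ml=[23.5, 24.5], n_elements=60,
            )
            for _ in range(2)
        ]
        a, b = runs
        assert np.array_equal(a.curve.pressure_mmhg, b.curve.pressure_mmhg)
        assert np.array_equal(a.states[-1].r_mm, b.states[-1].r_mm)


class TestConstrainedInflation:
    def test_inactive_contact_reproduces_free_inflation(
        self, default_design, balloon_material
    ):
        """A wide rigid phantom never touches the balloon."""
        wide = bm.CylinderPhantom(
            inner_diameter_mm=40.0, thickness_mm=1.2, length_mm=75.0
        )
        free = solve_free_inflation(
            default_design, balloon_material, volume_targets_ml=[24.5], n_elements=80
        )
        constrained = solve_constrained_inflation(
            default_design, balloon_material, wide, None,
            volume_targets_ml=[24.5], n_elements=80,
        )
        assert constrained.contact_report["max_contact_pressure_mmhg"] == 0.0
        assert constrained.states[-1].pressure_mmhg == pytest.approx(
            free.states[-1].pressure_mmhg, rel=1e-6
        )

    def test_rigid_phantom_caps_diameter(self, rigid_constrained_run):
        d_max = rigid_constrained_run.contact_report["max_diameter_mm"]
        assert d_max <= 22.0 + 1e-3 * 22.0
        assert d_max >= 22.0 - 0.05  # contact actually engaged

    def test_compliant_contact_pressure_equals_phantom_laplace_pressure(
        self, compliant_constrained_run, t50_phantom, t50_material
    ):
        result = compliant_constrained_run
        k = bm.cylinder_pv_response(
            t50_phantom, t50_material, 0.0
        ).radial_stiffness_mpa_per_mm
        r0 = t50_phantom.inner_radius_mm
        checked = 0
        for s in result.states:
            free_span = (s.z_mm > t50_phantom.end_band_mm) & (
                s.z_mm < t50_phantom.length_mm - t50_phantom.end_band_mm
            )
            active = s.contact_active & free_span
            for i in np.nonzero(active)[0]:
                p_c = s.contact_pressure_mmhg[i] * MPA_PER_MMHG
                p_laplace = k * (s.r_mm[i] - r0)
                assert p_c == pytest.approx(p_laplace, rel=0.01)
                checked += 1
        assert checked > 10

    def test_contact_complementarity(self, compliant_constrained_run, t50_phantom):
        """Nodes with an open gap carry exactly zero contact pressure."""
        for s in compliant_constrained_run.states:
            gap_open = s.r_mm < t50_phantom.inner_radius_mm - 1e-9
            assert np.all(s.contact_pressure_mmhg[gap_open] == 0.0)

    def test_compliant_phantom_dilates_beyond_its_bore(self, compliant_constrained_run):
        assert compliant_constrained_run.contact_report["max_diameter_mm"] > 22.0


class TestCylindricalMembranePressure:
    def test_reference_stretches_give_zero(self, balloon_material):
        assert cylindrical_membrane_pressure(1.0, 1.0, 11.5, 0.09, balloon_material) == 0.0

    def test_neo_hookean_cross_checked_by_energy_differentiation(self):
        """Closed form equals -dE/dV of a unit cylinder segment (numeric)."""
        mu = 0.5
        model = bm.OgdenModel(mu=(mu,), alpha=(2.0,))
        r0, t0, lam_z = 10.0, 0.1, 1.0

        def energy_per_length(lam_t):
            # membrane energy per unit reference length of cylinder
            l3 = 1.0 / (lam_t * lam_z)
            w = 2.0 * mu / 4.0 * (lam_t**2 + lam_z**2 + l3**2 - 3.0)
            return w * 2.0 * np.pi * r0 * t0

        def volume_per_length(lam_t):
            return np.pi * (r0 * lam_t) ** 2 * lam_z

        lam = 1.2
        h = 1e-6
        de = (energy_per_length(lam + h) - energy_per_length(lam - h)) / (2 * h)
        dv = (volume_per_length(lam + h) - volume_per_length(lam - h)) / (2 * h)
        p_fd = de / dv / MPA_PER_MMHG
        p_closed = cylindrical_membrane_pressure(lam, lam_z, r0, t0, model)
        assert p_closed == pytest.approx(p_fd, rel=1e-6)

    def test_monotone_increasing_near_reference(self, balloon_material):
        p1 = cylindrical_membrane_pressure(1.01, 1.0, 11.5, 0.09, balloon_material)
        p2 = cylindrical_membrane_pressure(1.02, 1.0, 11.5, 0.09, balloon_material)
        assert 0.0 < p1 < p2

    def test_invalid_stretches_rejected(self, balloon_material):
        with pytest.raises(InvalidInputError):
            cylindrical_membrane_pressure(-1.0, 1.0, 11.5, 0.09, balloon_material)
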