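import numpy as np
import pytest
from hypothesis import settings

import balloonmech as bm

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def balloon_material() -> bm.OgdenModel:
    """Third-order Ogden coefficients of the balloon membrane."""
    return bm.BALLOON_MEMBRANE_OGDEN


@pytest.fixture(scope="session")
def default_design() -> bm.BalloonDesign:
    return bm.BalloonDesign()


@pytest.fixture(scope="session")
def long_cylinder_design() -> bm.BalloonDesign:
    """Balloon variant with heads shortened to 5 % of the length.

    Its mid-section behaves as an infinite cylinder, the closed-form
    oracle geometry.  The shaft radius is close to the cylinder radius
    (shallow shoulders) so the whole membrane stays taut and the
    comparison is not polluted by wrinkled head elements.
    """
    return bm.BalloonDesign(
        cylinder_length_mm=76.0, total_length_mm=80.0, shaft_radius_mm=10.0
    )


@pytest.fixture(scope="session")
def t50_phantom() -> bm.CylinderPhantom:
    """22 mm implantation-site phantom, printed in the stiff composite."""
    return bm.CylinderPhantom(
        inner_diameter_mm=22.0, thickness_mm=1.2, length_mm=75.0, end_band_mm=10.6
    )


@pytest.fixture(scope="session")
def t50_material() -> bm.LinearElasticModel:
    return bm.LinearElasticModel(young_modulus=13.19, poisson=0.25)


@pytest.fixture(scope="session")
def free_inflation_run(default_design, balloon_material) -> bm.InflationResult:
    """One shared moderate-resolution free-inflation run (cached per session)."""
    return bm.solve_free_inflation(
        default_design,
        balloon_material,
        volume_targets_ml=[23.3, 23.8, 24.3, 24.8, 25.3, 25.8],
        n_elements=100,
    )


@pytest.fixture(scope="session")
def rigid_constrained_run(
    default_design, balloon_material, t50_phantom
) -> bm.InflationResult:
    """Inflation against a rigid 22 mm bore (shared across test modules)."""
    return bm.solve_constrained_inflation(
        default_design, balloon_material, t50_phantom, None,
        volume_targets_ml=[24.0, 25.0], n_elements=100,
    )


@pytest.fixture(scope="session")
def compliant_constrained_run(
    default_design, balloon_material, t50_phantom, t50_material
) -> bm.InflationResult:
    """Inflation inside the compliant implantation-site phantom."""
    return bm.solve_constrained_inflation(
        default_design, balloon_material, t50_phantom, t50_material,
        volume_targets_ml=[24.5, 25.5], n_elements=100,
    )


@pytest.fixture(scope="session")
def mid_element_stretches():
    """Helper extracting mid-element (lambda_theta, lambda_z) of a state."""

    def _get(state: bm.MembraneState, mesh: bm.MeridianMesh):
        k = mesh.z.size // 2
        lam_t = (0.5 * (state.r_mm[k - 1] + state.r_mm[k])) / (
            0.5 * (mesh.r[k - 1] + mesh.r[k])
        )
        length = np.hypot(
            state.z_mm[k] - state.z_mm[k - 1], state.r_mm[k] - state.r_mm[k - 1]
        )
        l0 = np.hypot(mesh.z[k] - mesh.z[k - 1], mesh.r[k] - mesh.r[k - 1])
        return lam_t, length / l0

    return _get
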