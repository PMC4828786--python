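"""Seeded generators emulating every bench experiment the pipelines consume.

Each generator is a pure function of its parameters and a seed, and
returns both a noisy "measured" output and the clean ground truth, so
every analysis routine in the package can be exercised as a round trip
without any external data.  The noise model is additive Gaussian plus
uniform quantisation: the defaults mirror the acquisition hardware of
the emulated bench (0.2 atm manometer resolution for pressure, 0.5 mm
fluoroscopy pixel for diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .geometry import BalloonDesign, InflationProtocol
from .imaging import CalibrationArch, ProjectionImage
from .materials import (
    LinearElasticModel,
    OgdenModel,
    StressStrainCurve,
    ogden_uniaxial_stress,
)
from .metrics import InflationCurve
from .solver import (
    InflationResult,
    MembraneState,
    SolverOptions,
    solve_constrained_inflation,
    solve_free_inflation,
)
from .units import MMHG_PER_ATM
from .vessel import ComplianceRecord, CylinderPhantom, cylinder_pv_response


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for the synthetic bench.

    Pressure: additive Gaussian (transducer noise) followed by uniform
    quantisation at the manometer resolution (0.2 atm = 152 mmHg).
    Diameter: quantised at the 0.5 mm isotropic fluoroscopy pixel.
    Tensile data: additive Gaussian on stress and strain.  The seed
    fixes all randomness.
    """

    pressure_std_mmhg: float = 10.0
    pressure_quantum_mmhg: float = 0.2 * MMHG_PER_ATM
    diameter_quantum_mm: float = 0.5
    stress_std: float = 0.0
    strain_std: float = 0.0
    volume_std_ml: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "pressure_std_mmhg", "pressure_quantum_mmhg", "diameter_quantum_mm",
            "stress_std", "strain_std", "volume_std_ml",
        ):
            if getattr(self, name) < 0.0:
                raise InvalidInputError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _quantize(x: np.ndarray, quantum: float) -> np.ndarray:
    if quantum <= 0.0:
        return x
    return np.round(x / quantum) * quantum


def _model_stress(model, strain: np.ndarray) -> np.ndarray:
    if isinstance(model, LinearElasticModel):
        return model.young_modulus * strain
    if isinstance(model, OgdenModel):
        return np.where(
            strain > -1.0,
            ogden_uniaxial_stress(np.maximum(1.0 + strain, 1e-9), model, "nominal"),
            np.nan,
        )
    raise InvalidInputError(f"unsupported material model {type(model).__name__}")


def gen_uniaxial(
    model,
    strain: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    *,
    cyclic: bool = False,
    n_cycles: int = 10,
    max_strain: float = 0.10,
    residual_offsets: np.ndarray | None = None,
    n_per_branch: int = 101,
    direction: str | None = None,
):
    """Synthetic uniaxial tensile data.

    Monotonic mode returns one virgin-loading curve on ``strain``
    (default 0..10 %).  Cyclic mode emulates a ten-cycle test to 10 %
    strain: cycle k loads from the previous residual strain to
    ``max_strain`` and unloads along a branch shifted by that cycle's
    residual offset, so the unloading branch crosses zero stress exactly
    at the offset.  Default offsets ramp from 3 % to 5 %, the range
    observed for this class of balloon film; the offsets are recoverable
    by :func:`balloonmech.materials.residual_strain`.
    """
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if not cyclic:
        if strain is None:
            strain = np.linspace(0.0, max_strain, n_per_branch)
        strain = np.asarray(strain, dtype=float)
        stress = _model_stress(model, strain)
        if noise.strain_std > 0.0:
            strain = np.sort(strain + rng.normal(0.0, noise.strain_std, strain.shape))
        if noise.stress_std > 0.0:
            stress = stress + rng.normal(0.0, noise.stress_std, stress.shape)
        # the virgin curve starts exactly at the unloaded reference
        strain = strain - strain[0]
        stress[0] = 0.0
        return StressStrainCurve(strain=strain, stress=stress, direction=direction, cycle=None)

    if residual_offsets is None:
        residual_offsets = np.linspace(0.03, 0.05, n_cycles)
    residual_offsets = np.asarray(residual_offsets, dtype=float)
    if residual_offsets.size != n_cycles:
        raise InvalidInputError("need one residual offset per cycle")
    cycles = []
    prev = 0.0
    for k in range(n_cycles):
        off = float(residual_offsets[k])
        e_load = np.linspace(prev, max_strain, n_per_branch)
        s_load = _model_stress(model, e_load - prev)
        e_unload = np.linspace(max_strain, off, n_per_branch)[1:]
        s_unload = _model_stress(model, e_unload - off)
        e = np.concatenate([e_load, e_unload])
        s = np.concatenate([s_load, s_unload])
        if noise.stress_std > 0.0:
            s = s + rng.normal(0.0, noise.stress_std, s.shape)
        cycles.append(StressStrainCurve(strain=e, stress=s, direction=direction, cycle=k))
        prev = off
    return cycles


def gen_compliance(
    phantom: CylinderPhantom,
    material: LinearElasticModel,
    pressures_mmhg: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> ComplianceRecord:
    """Synthetic compliance-test P-V record of a thin-walled cylinder.

    Volumes come from the thin-wall linear response of the vessel
    module; optional Gaussian volume noise emulates the metering
    uncertainty.  The first sample is the zero-gauge-pressure state.
    """
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if pressures_mmhg is None:
        pressures_mmhg = np.linspace(0.0, 20.0, 11)
    pressures_mmhg = np.asarray(pressures_mmhg, dtype=float)
    if pressures_mmhg[0] != 0.0:
        raise InvalidInputError("pressure grid must start at the zero-gauge state")
    vols = np.array(
        [cylinder_pv_response(phantom, material, p).volume_ml for p in pressures_mmhg]
    )
    v_in = float(vols[0])
    if noise.volume_std_ml > 0.0:
        vols = vols + rng.normal(0.0, noise.volume_std_ml, vols.shape)
        vols[0] = v_in
    return ComplianceRecord(
        pressure_mmhg=pressures_mmhg, volume_ml=vols, initial_volume_ml=v_in
    )


@dataclass
class SyntheticInflation:
    """A synthetic inflation bench run: noisy measurement plus ground truth."""

    experiment: InflationCurve     # with transducer/fluoroscopy noise
    truth: InflationCurve          # clean forward-model output
    result: InflationResult        # full solver output (states, mesh)


def gen_inflation_experiment(
    design: BalloonDesign,
    material: OgdenModel,
    protocol: InflationProtocol,
    phantom: CylinderPhantom | None = None,
    phantom_material: LinearElasticModel | None = None,
    noise: NoiseSpec | None = None,
    *,
    n_elements: int = 120,
    options: SolverOptions | None = None,
) -> SyntheticInflation:
    """Emulate a free or constrained inflation bench test.

    Runs the forward membrane model on the protocol schedule, then
    applies pressure noise + manometer quantisation and fluoroscopy
    diameter quantisation.  The clean curve is retained as ground truth.
    """
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if phantom is None:
        result = solve_free_inflation(
            design, material, protocol, n_elements=n_elements, options=options
        )
    else:
        result = solve_constrained_inflation(
            design, material, phantom, phantom_material, protocol,
            n_elements=n_elements, options=options,
        )
    clean = result.curve
    p = clean.pressure_mmhg.copy()
    if noise.pressure_std_mmhg > 0.0:
        p = p + rng.normal(0.0, noise.pressure_std_mmhg, p.shape)
    p = np.clip(_quantize(p, noise.pressure_quantum_mmhg), 0.0, None)
    d = _quantize(clean.diameter_mm.copy(), noise.diameter_quantum_mm)
    experiment = InflationCurve(
        time_s=clean.time_s,
        volume_ml=clean.volume_ml,
        pressure_mmhg=p,
        diameter_mm=d,
        provenance="experimental",
    )
    return SyntheticInflation(experiment=experiment, truth=clean, result=result)


@dataclass
class ProjectionSet:
    """Biplane synthetic projections with calibration arch and ground truth."""

    ap: ProjectionImage
    lat: ProjectionImage
    arch: CalibrationArch  # real distances only; image distances must be measured
    truth: dict


def _render_projection(
    z_mm: np.ndarray,
    r_mm: np.ndarray,
    w_true: float,
    b1_real_mm: float,
    b2_real_mm: float,
    projection: str,
    rng: np.random.Generator,
    intensity_noise_std: float,
    blur_sigma_px: float,
    silhouette_level: float = 0.6,
) -> ProjectionImage:
    margin = 24
    length_px = (z_mm[-1] - z_mm[0]) / w_true
    r_max_px = np.max(r_mm) / w_true
    nx = int(np.ceil(length_px)) + 2 * margin
    ny = int(np.ceil(2 * r_max_px)) + 2 * margin + 24
    img = np.zeros((ny, nx))
    y_c = ny / 2.0
    x0 = margin

    xs = np.arange(nx)
    z_of_x = (xs - x0) * w_true + z_mm[0]
    r_px = np.where(
        (z_of_x >= z_mm[0]) & (z_of_x <= z_mm[-1]),
        np.interp(z_of_x, z_mm, r_mm) / w_true,
        0.0,
    )
    ys = np.arange(ny)[:, None]
    coverage = np.clip(r_px[None, :] - np.abs(ys - y_c) + 0.5, 0.0, 1.0)
    img += silhouette_level * coverage * (r_px[None, :] > 0.0)

    # arch beads: pair 1 near the top edge, pair 2 near the bottom edge
    beads = []
    x_mid = nx / 2.0
    for y_row, b_real in ((6.0, b1_real_mm), (ny - 7.0, b2_real_mm)):
        half = b_real / (2.0 * w_true)
        beads.append((y_row, x_mid - half))
        beads.append((y_row, x_mid + half))
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    for (by, bx) in beads:
        disc = (yy - by) ** 2 + (xx - bx) ** 2 <= 3.0**2
        img = np.maximum(img, disc * 1.0)

    img = ndimage.gaussian_filter(img, blur_sigma_px)
    if intensity_noise_std > 0.0:
        img = img + rng.normal(0.0, intensity_noise_std, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ProjectionImage(
        pixels=img,
        pixel_size_mm=w_true,
        projection=projection,
        beads_px=[(round(by), round(bx)) for by, bx in beads],
    )


def gen_projections(
    state: MembraneState,
    *,
    w_true_ap: float = 0.5,
    w_true_lat: float | None = None,
    b1_real_mm: float = 60.0,
    b2_real_mm: float = 40.0,
    intensity_noise_std: float = 0.01,
    blur_sigma_px: float = 0.7,
    seed: int = 0,
) -> ProjectionSet:
    """Synthetic biplane projections of a membrane state.

    Renders anti-aliased silhouettes of the revolved balloon at the true
    scales ``w_true_ap`` / ``w_true_lat`` (mm per pixel), with the four
    calibration beads drawn as bright discs at known real spacings.
    Ground truth carries the true scales, cavity volume and central
    diameter for round-trip checks.
    """
    if w_true_lat is None:
        w_true_lat = w_true_ap
    rng = np.random.default_rng(seed)
    ap = _render_projection(
        state.z_mm, state.r_mm, w_true_ap, b1_real_mm, b2_real_mm, "AP",
        rng, intensity_noise_std, blur_sigma_px,
    )
    lat = _render_projection(
        state.z_mm, state.r_mm, w_true_lat, b1_real_mm, b2_real_mm, "LAT",
        rng, intensity_noise_std, blur_sigma_px,
    )
    arch = CalibrationArch(
        b1_real_mm=b1_real_mm, b2_real_mm=b2_real_mm, image_distances={}
    )
    truth = {
        "w_ap": w_true_ap,
        "w_lat": w_true_lat,
        "volume_ml": state.volume_ml,
        "central_diameter_mm": state.central_diameter_mm(),
    }
    return ProjectionSet(ap=ap, lat=lat, arch=arch, truth=truth)
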