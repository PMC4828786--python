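"""Thin-walled cylinder mechanics for implantation-site phantoms.

The 3D-printed phantoms are treated as thin-walled cylinders of linear,
elastic, isotropic material.  The analysis equations are the Laplace-law
block used in bench compliance testing:

    sigma_theta = P * r / t          (hoop stress)
    eps         = (r - r_in) / r_in  (hoop strain)
    r           = sqrt(V / (pi * l)) (radius from internal volume)
    D           = dV / (dP * V_in)   (distensibility)
    E           = sigma_theta / eps  (Young's modulus from the final state)

r is the inner radius throughout (the equations are taken literally, so
stress uses the same r as strain).  The module also supplies the radial
stiffness of the phantom used by the contact solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .materials import LinearElasticModel
from .units import MM3_PER_ML, MPA_PER_MMHG, mm3_to_ml, mmhg_to_mpa, per_mpa_to_per_mmhg


@dataclass(frozen=True)
class CylinderPhantom:
    """Cylindrical implantation-site / compliance-test phantom (mm)."""

    inner_diameter_mm: float
    thickness_mm: float
    length_mm: float
    end_band_mm: float = 0.0
    label: str | None = None

    def __post_init__(self):
        if min(self.inner_diameter_mm, self.thickness_mm, self.length_mm) <= 0.0:
            raise InvalidInputError("phantom dimensions must be positive")
        if self.end_band_mm < 0.0 or 2.0 * self.end_band_mm >= self.length_mm:
            raise InvalidInputError("end bands must satisfy 0 <= 2*band < length")

    @property
    def inner_radius_mm(self) -> float:
        return 0.5 * self.inner_diameter_mm

    def reference_volume_ml(self) -> float:
        return mm3_to_ml(np.pi * self.inner_radius_mm**2 * self.length_mm)


@dataclass(frozen=True)
class ComplianceRecord:
    """Paired (P, V) samples of a compliance test; first sample at zero gauge pressure."""

    pressure_mmhg: np.ndarray
    volume_ml: np.ndarray
    initial_volume_ml: float | None = None

    def __post_init__(self):
        p = np.asarray(self.pressure_mmhg, dtype=float)
        v = np.asarray(self.volume_ml, dtype=float)
        object.__setattr__(self, "pressure_mmhg", p)
        object.__setattr__(self, "volume_ml", v)
        if p.ndim != 1 or p.shape != v.shape or p.size < 2:
            raise InvalidInputError("record needs >= 2 paired (P, V) samples")
        if np.any(v <= 0.0):
            raise InvalidInputError("volumes must be positive")
        if self.initial_volume_ml is None:
            object.__setattr__(self, "initial_volume_ml", float(v[0]))
        elif self.initial_volume_ml <= 0.0:
            raise InvalidInputError("initial volume must be positive")


def radius_from_volume(volume_ml: float, length_mm: float) -> float:
    """Inner radius (mm) of a cylinder of given internal volume and length."""
    if volume_ml <= 0.0 or length_mm <= 0.0:
        raise InvalidInputError("volume and length must be positive")
    return float(np.sqrt(volume_ml * MM3_PER_ML / (np.pi * length_mm)))


def hoop_stress(pressure, radius_mm, thickness_mm):
    """Laplace hoop stress P*r/t (same pressure units in and out)."""
    if np.any(np.asarray(thickness_mm) <= 0.0):
        raise InvalidInputError("thickness must be positive")
    return pressure * radius_mm / thickness_mm


def hoop_strain(radius_mm, initial_radius_mm):
    """Engineering hoop strain (r - r_in)/r_in; negative for r < r_in."""
    if np.any(np.asarray(initial_radius_mm) <= 0.0):
        raise InvalidInputError("initial radius must be positive")
    return (radius_mm - initial_radius_mm) / initial_radius_mm


def distensibility(
    record: ComplianceRecord, window: tuple[int, int] | None = None
) -> float:
    """Distensibility D = dV / (dP * V_in) in mmHg^-1.

    By default the pressure window is the full record (first to last
    sample); a ``window`` of sample indices selects a sub-range.
    """
    i0, i1 = window if window is not None else (0, -1)
    dp = float(record.pressure_mmhg[i1] - record.pressure_mmhg[i0])
    dv = float(record.volume_ml[i1] - record.volume_ml[i0])
    if dp <= 0.0:
        raise InvalidInputError("record must span dP > 0")
    return dv / (dp * record.initial_volume_ml)


def young_modulus_from_compliance(
    record: ComplianceRecord,
    phantom: CylinderPhantom,
    pressure_unit: str = "mmHg",
) -> float:
    """Young's modulus (MPa) from the final state of a compliance record.

    E = sigma_theta / eps with r = sqrt(V/(pi l)), sigma_theta = P*r/t
    and eps = (r - r_in)/r_in, where r_in comes from the record's initial
    volume.  Valid for thin walls (t/r < 0.2 advisory) and small strains.
    """
    to_mpa = {"mmHg": MPA_PER_MMHG, "Pa": 1e-6, "kPa": 1e-3, "MPa": 1.0}
    if pressure_unit not in to_mpa:
        raise InvalidInputError(f"unknown pressure unit {pressure_unit!r}")
    p_mpa = float(record.pressure_mmhg[-1]) * to_mpa[pressure_unit]
    r = radius_from_volume(float(record.volume_ml[-1]), phantom.length_mm)
    r_in = radius_from_volume(record.initial_volume_ml, phantom.length_mm)
    eps = hoop_strain(r, r_in)
    if eps == 0.0:
        raise InvalidInputError("zero hoop strain: record shows no dilation")
    sig = hoop_stress(p_mpa, r, phantom.thickness_mm)
    return float(sig / eps)


def linearized_distensibility(e_mpa: float, radius_mm: float, thickness_mm: float) -> float:
    """Small-strain closed form D = 2r/(E t), returned in mmHg^-1.

    Combines the Laplace stress, hoop strain and distensibility
    definitions in the limit of small dilation of a uniform thin-walled
    cylinder.
    """
    if min(e_mpa, radius_mm, thickness_mm) <= 0.0:
        raise InvalidInputError("inputs must be positive")
    d_per_mpa = 2.0 * radius_mm / (e_mpa * thickness_mm)
    return per_mpa_to_per_mmhg(d_per_mpa)


@dataclass(frozen=True)
class CylinderResponse:
    """Pressurised-phantom state from :func:`cylinder_pv_response`."""

    volume_ml: float
    free_radius_mm: float
    radial_stiffness_mpa_per_mm: float
    hoop_strain: float
    thin_wall_linear_ok: bool


def cylinder_pv_response(
    phantom: CylinderPhantom, material: LinearElasticModel, pressure_mmhg: float
) -> CylinderResponse:
    """Small-strain thin-wall response of the phantom at internal pressure P.

    Over the free length the inner radius dilates to
    r(P) = r_in (1 + P r_in / (E t)); the end bands are held at r_in with
    a linear radius taper across each band (the simplest profile meeting
    both boundary conditions).  The returned radial stiffness
    dP/dr = E t / r_in^2 is the free-length limit used by the contact
    solver.  Strains above 10 % flag the linear thin-wall model as out of
    its validity range.
    """
    p_mpa = mmhg_to_mpa(pressure_mmhg)
    r_in = phantom.inner_radius_mm
    t = phantom.thickness_mm
    e = material.young_modulus
    strain = p_mpa * r_in / (e * t)
    r_free = r_in * (1.0 + strain)
    lb = phantom.end_band_mm
    l_free = phantom.length_mm - 2.0 * lb
    # frusta are exact for the linear tapers
    v = np.pi * (
        l_free * r_free**2
        + 2.0 * (lb / 3.0) * (r_in**2 + r_in * r_free + r_free**2)
    )
    return CylinderResponse(
        volume_ml=mm3_to_ml(float(v)),
        free_radius_mm=float(r_free),
        radial_stiffness_mpa_per_mm=e * t / r_in**2,
        hoop_strain=float(strain),
        thin_wall_linear_ok=bool(strain <= 0.10),
    )


def compare_final_volume(v_exp_ml: float, v_comp_ml: float) -> dict[str, float]:
    """Percent difference between experimental and computational volumes.

    The denominator convention is not unique, so all three obvious ones
    are reported: experimental, computational, and their mean.
    """
    if v_exp_ml <= 0.0 or v_comp_ml <= 0.0:
        raise InvalidInputError("volumes must be positive")
    diff = abs(v_exp_ml - v_comp_ml)
    return {
        "pct_of_experimental": 100.0 * diff / v_exp_ml,
        "pct_of_computational": 100.0 * diff / v_comp_ml,
        "pct_of_mean": 100.0 * diff / (0.5 * (v_exp_ml + v_comp_ml)),
    }


def load_composite_table() -> pd.DataFrame:
    """Measured properties of the TangoPlus/VeroWhite phantom composites.

    Columns: composite name, mix percentages, tested wall thickness,
    distensibility (mmHg^-1) and Young's modulus (MPa).  Rows tagged
    ``interpolated`` in the ``source`` column are synthetic interpolants
    between the measured endpoints, kept only so the monotone
    stiffness/distensibility trend across the blend series is
    represented; treat them as qualitative.
    """
    with resources.files("balloonmech").joinpath("data/composites.csv").open("r") as fh:
        return pd.read_csv(fh, comment="#")
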