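"""Balloon geometry, meridian meshing, solids of revolution, protocols.

Under the axisymmetry of the device the balloon is fully described by
its meridian: a planar curve (z, r) that, revolved about the z axis,
generates the membrane surface.  The parametric profile is a central
cylinder of nominal radius closed by two pseudo-conical heads that taper
down to the catheter shaft radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .units import mm3_to_ml


@dataclass(frozen=True)
class BalloonDesign:
    """Parametric valvuloplasty-balloon geometry (all lengths in mm).

    Defaults describe a 23 mm non-compliant balloon: 40 mm cylindrical
    region, 75 mm total length, 0.09 mm uniform membrane thickness.
    ``head_exponent`` shapes the pseudo-conical heads: 1 gives straight
    cones (frusta); larger values give fuller shoulders.
    """

    nominal_diameter_mm: float = 23.0
    cylinder_length_mm: float = 40.0
    total_length_mm: float = 75.0
    thickness_mm: float = 0.09
    shaft_radius_mm: float = 3.0
    head_exponent: float = 1.0

    def __post_init__(self):
        if self.cylinder_length_mm <= 0.0 or self.total_length_mm <= 0.0:
            raise InvalidInputError("lengths must be positive")
        if self.cylinder_length_mm >= self.total_length_mm:
            raise InvalidInputError("cylindrical length must be < total length")
        if self.thickness_mm <= 0.0:
            raise InvalidInputError("membrane thickness must be positive")
        if not (0.0 < self.shaft_radius_mm < self.nominal_radius_mm):
            raise InvalidInputError("shaft radius must lie in (0, nominal radius)")
        if self.head_exponent <= 0.0:
            raise InvalidInputError("head_exponent must be positive")

    @property
    def nominal_radius_mm(self) -> float:
        return 0.5 * self.nominal_diameter_mm

    @property
    def head_length_mm(self) -> float:
        return 0.5 * (self.total_length_mm - self.cylinder_length_mm)

    def radius_at(self, z: np.ndarray) -> np.ndarray:
        """Profile radius r(z) for z in [0, total_length]."""
        z = np.asarray(z, dtype=float)
        lh = self.head_length_mm
        lc = self.cylinder_length_mm
        rs = self.shaft_radius_mm
        rn = self.nominal_radius_mm
        p = self.head_exponent
        zt = self.total_length_mm
        xi_left = np.clip(z / lh, 0.0, 1.0)
        xi_right = np.clip((zt - z) / lh, 0.0, 1.0)
        r = np.where(
            z < lh,
            rs + (rn - rs) * xi_left**p,
            np.where(z > lh + lc, rs + (rn - rs) * xi_right**p, rn),
        )
        return r

    def analytic_volume_ml(self) -> float:
        """Volume of the revolved reference profile.

        Exact (cylinder + two frusta) for conical heads; high-resolution
        quadrature otherwise.
        """
        rn = self.nominal_radius_mm
        rs = self.shaft_radius_mm
        lc = self.cylinder_length_mm
        lh = self.head_length_mm
        if self.head_exponent == 1.0:
            v = np.pi * rn**2 * lc + 2.0 * (np.pi * lh / 3.0) * (rn**2 + rn * rs + rs**2)
            return mm3_to_ml(v)
        z = np.linspace(0.0, self.total_length_mm, 200001)
        r = self.radius_at(z)
        return mm3_to_ml(np.pi * np.trapezoid(r**2, z))


@dataclass(frozen=True)
class MeridianMesh:
    """Reference meridian discretisation: nodes (z, r) and element thickness."""

    z: np.ndarray
    r: np.ndarray
    thickness: np.ndarray  # per element

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.r, dtype=float)
        t = np.asarray(self.thickness, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "thickness", t)
        if z.ndim != 1 or z.shape != r.shape or z.size < 3:
            raise InvalidInputError("mesh needs >= 3 nodes with matching z and r")
        if t.shape != (z.size - 1,):
            raise InvalidInputError("thickness must have one entry per element")
        seg = np.hypot(np.diff(z), np.diff(r))
        if np.any(seg == 0.0):
            raise InvalidInputError("duplicate consecutive nodes in meridian")
        if np.any(r < 0.0):
            raise InvalidInputError("meridian radii must be >= 0")
        if np.any(t <= 0.0):
            raise InvalidInputError("element thickness must be positive")

    @property
    def n_elements(self) -> int:
        return self.z.size - 1

    @property
    def ref_length(self) -> np.ndarray:
        return np.hypot(np.diff(self.z), np.diff(self.r))

    @property
    def ref_mid_radius(self) -> np.ndarray:
        return 0.5 * (self.r[:-1] + self.r[1:])

    @property
    def ref_element_volume(self) -> np.ndarray:
        """Reference membrane volume per element: 2 pi R_mid L0 t0 (mm^3)."""
        return 2.0 * np.pi * self.ref_mid_radius * self.ref_length * self.thickness

    def reference_cavity_volume_ml(self) -> float:
        return mm3_to_ml(solid_of_revolution_volume(self.z, self.r))


def solid_of_revolution_volume(z: np.ndarray, r: np.ndarray) -> float:
    """Volume (mm^3) of the solid of revolution of a meridian about the z axis.

    Second-order conical-frusta quadrature:
    V = pi/3 * sum (r_a^2 + r_a r_b + r_b^2) (z_b - z_a),
    exact for piecewise-linear meridians.  The axial coordinate must be
    strictly increasing (a folded meridian would self-intersect when
    revolved).
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.ndim != 1 or z.shape != r.shape or z.size < 2:
        raise InvalidInputError("meridian needs >= 2 (z, r) points")
    dz = np.diff(z)
    if np.any(dz <= 0.0):
        raise InvalidInputError("self-intersecting meridian: z must be strictly increasing")
    ra, rb = r[:-1], r[1:]
    return float(np.pi / 3.0 * np.sum((ra**2 + ra * rb + rb**2) * dz))


def build_profile_mesh(design: BalloonDesign, n_elements: int) -> MeridianMesh:
    """Mesh the balloon meridian with ~equal arc-length elements.

    Elements are allocated to the three profile regions (head, cylinder,
    head) proportionally to their arc length (at least 2 per region), and
    placed at equal arc length within each region, so junction nodes fall
    exactly on the region boundaries.
    """
    if n_elements < 20:
        raise InvalidInputError("n_elements must be >= 20")
    lh = design.head_length_mm
    lc = design.cylinder_length_mm
    zt = design.total_length_mm
    bounds = [(0.0, lh), (lh, lh + lc), (lh + lc, zt)]

    # arc length of each region from dense sampling
    arcs = []
    dense = []
    for z0, z1 in bounds:
        zz = np.linspace(z0, z1, 2001)
        rr = design.radius_at(zz)
        s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(zz), np.diff(rr)))])
        arcs.append(s[-1])
        dense.append((zz, s))
    arcs = np.asarray(arcs)
    total_arc = arcs.sum()
    n_alloc = np.maximum(2, np.round(n_elements * arcs / total_arc).astype(int))
    # adjust to hit n_elements exactly, keeping >= 2 per region
    while n_alloc.sum() > n_elements:
        i = int(np.argmax(n_alloc))
        n_alloc[i] -= 1
    while n_alloc.sum() < n_elements:
        i = int(np.argmin(n_alloc / arcs * total_arc / n_elements))
        n_alloc[i] += 1

    z_nodes = [0.0]
    for (zz, s), n_reg in zip(dense, n_alloc):
        targets = np.linspace(0.0, s[-1], n_reg + 1)[1:]
        z_nodes.extend(np.interp(targets, s, zz))
    z_nodes = np.asarray(z_nodes)
    r_nodes = design.radius_at(z_nodes)
    # pin end nodes exactly at the shaft radius
    r_nodes[0] = design.shaft_radius_mm
    r_nodes[-1] = design.shaft_radius_mm
    thickness = np.full(z_nodes.size - 1, design.thickness_mm)
    return MeridianMesh(z=z_nodes, r=r_nodes, thickness=thickness)


@dataclass(frozen=True)
class InflationProtocol:
    """Volume-controlled inflation protocol of the bench experiment.

    A syringe pump injects at a constant ``flow_rate_ml_h`` (default
    40 ml/h) and the acquisition system samples one frame every
    ``sampling_interval_s`` (default 15 s), so the injected-volume
    timeline is V(t) = V0 + Vdot * t.  ``initial_volume_ml`` is the
    zero-pressure filling volume V0 (None = use the balloon's reference
    cavity volume).
    """

    flow_rate_ml_h: float = 40.0
    sampling_interval_s: float = 15.0
    initial_volume_ml: float | None = None
    injected_volume_ml: float = 3.0

    def __post_init__(self):
        if self.flow_rate_ml_h <= 0.0:
            raise InvalidInputError("flow rate must be positive")
        if self.sampling_interval_s <= 0.0:
            raise InvalidInputError("sampling interval must be positive")
        if self.injected_volume_ml <= 0.0:
            raise InvalidInputError("injected volume must be positive")
        if self.initial_volume_ml is not None and self.initial_volume_ml <= 0.0:
            raise InvalidInputError("initial volume must be positive")

    @property
    def flow_rate_ml_s(self) -> float:
        return self.flow_rate_ml_h / 3600.0

    @property
    def duration_s(self) -> float:
        return self.injected_volume_ml / self.flow_rate_ml_s


def volume_schedule(
    protocol: InflationProtocol, v0_ml: float | None = None
) -> list[tuple[float, float]]:
    """Sampling instants and target volumes (t_k, V0 + Vdot * t_k).

    Instants are spaced by the protocol sampling interval; the final
    instant (total injected volume reached) is always included.
    """
    v0 = protocol.initial_volume_ml if protocol.initial_volume_ml is not None else v0_ml
    if v0 is None:
        raise InvalidInputError("initial volume V0 is required (protocol or argument)")
    t_end = protocol.duration_s
    times = list(np.arange(0.0, t_end, protocol.sampling_interval_s))
    if not times or times[-1] < t_end - 1e-9:
        times.append(t_end)
    return [(float(t), float(v0 + protocol.flow_rate_ml_s * t)) for t in times]
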