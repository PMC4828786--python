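"""Axisymmetric nonlinear membrane solver for balloon inflation.

The balloon is an incompressible Ogden membrane in plane stress
(lambda_3 = 1/(lambda_m * lambda_theta)), discretised along its meridian
into conical-frustum elements with stretches

    lambda_m     = L / L0          (meridional, per element)
    lambda_theta = r_mid / R_mid   (circumferential, per element).

Loading is volume-controlled: the injected contrast is incompressible,
so the fluid-cavity condition reduces to the constraint
V(x) = V_target with the cavity pressure P as the associated Lagrange
multiplier.  Each load step solves the augmented system

    grad E(x) - P grad V(x) = 0,   V(x) = V_target

(E = membrane strain energy + contact penalty energy) by damped Newton
iteration with finite-difference Jacobian, continuing in V with
automatic step halving; steps that defeat Newton (the wrinkled
low-pressure toe) fall back to a trust-region SQP minimisation of the
same energy under the same constraint.  End nodes are constrained
radially (held at the shaft radius) and free axially; one axial dof is
anchored to remove the rigid translation.

Membranes cannot carry compression.  Elements whose trial stress would
be compressive use a tension-field relaxation: the slack direction
relaxes towards its natural (uniaxial-contraction) stretch and carries
no stress.  The hard relaxation has a C1 kink exactly where wrinkling
starts - and converged inflation states sit on that kink manifold - so
the branches are blended by a smooth partition of unity over a narrow
stretch band (width ``wrinkle_smoothing``), making the energy
C-infinity while staying exact on the branch boundaries; the band is a
fraction of a percent of stretch and its effect on taut states is
exponentially small.  Elements inside the relaxed regime are flagged
"slack".

Contact with a cylindrical implantation-site phantom is frictionless and
radial.  A compliant phantom responds as a thin-walled linear-elastic
cylinder (radial stiffness E*t/r^2 from the vessel module); a rigid
phantom, and the phantom's constrained end bands, use a penalty with
automatic escalation until penetration is below 1e-3 of the phantom
radius.  The contact force derives from a penalty potential with
reference tributary areas, so the whole residual is the exact gradient
of one scalar potential.

The solver contains no randomness: identical inputs produce bitwise
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ConvergenceError, InvalidInputError
from .geometry import (
    BalloonDesign,
    InflationProtocol,
    MeridianMesh,
    build_profile_mesh,
    volume_schedule,
)
from .materials import LinearElasticModel, OgdenModel
from .metrics import InflationCurve
from .units import MM3_PER_ML, mm3_to_ml, mmhg_to_mpa, mpa_to_mmhg
from .vessel import CylinderPhantom, cylinder_pv_response


@dataclass(frozen=True)
class SolverOptions:
    """Numerical parameters of the quasi-static membrane solver."""

    ftol: float = 1e-8          # force residual, relative to internal force scale
    vtol: float = 1e-9          # cavity-volume constraint, relative
    fallback_ftol: float = 0.2  # acceptance for minimisation-fallback steps
    max_newton_iter: int = 30
    max_step_ml: float = 0.25   # continuation step in cavity volume
    min_step_halvings: int = 10
    penalty_scale: float = 1e3  # rigid-contact penalty vs membrane radial stiffness
    max_penalty_escalations: int = 6
    penetration_tol_rel: float = 1e-3
    wrinkle_smoothing: float = 5e-4  # tension-field blend band (stretch units)
    regularization: float = 1e-8     # tiny stiffness stabilising slack zones


@dataclass
class MembraneState:
    """Deformed configuration at one converged volume step."""

    z_mm: np.ndarray
    r_mm: np.ndarray
    pressure_mmhg: float
    volume_ml: float
    lambda_m: np.ndarray       # per element
    lambda_theta: np.ndarray   # per element
    slack: np.ndarray          # per element bool (wrinkled / tension-field regime)
    contact_pressure_mmhg: np.ndarray  # per node, >= 0
    time_s: float = 0.0
    #: force-balance diagnostic: max nodal residual / characteristic force.
    #: 0 for Newton-converged steps; small but nonzero for steps accepted
    #: from the minimisation fallback in the wrinkled low-pressure toe.
    residual_rel: float = 0.0

    @property
    def contact_active(self) -> np.ndarray:
        return self.contact_pressure_mmhg > 0.0

    def central_diameter_mm(self) -> float:
        z_mid = 0.5 * (self.z_mm[0] + self.z_mm[-1])
        return 2.0 * float(np.interp(z_mid, self.z_mm, self.r_mm))

    def max_diameter_mm(self) -> float:
        return 2.0 * float(np.max(self.r_mm))


def enclosed_volume(state: MembraneState) -> float:
    """Cavity volume (ml) of the revolved deformed meridian.

    Uses the same signed conical-frusta quadrature as the solver's
    volume constraint, so it is defined also for wrinkled states whose
    slack (near-zero-stiffness) head regions carry micro-folds.
    """
    dz = np.diff(state.z_mm)
    ra, rb = state.r_mm[:-1], state.r_mm[1:]
    return mm3_to_ml(np.pi / 3.0 * float(np.sum((ra**2 + ra * rb + rb**2) * dz)))


# ----------------------------------------------------------------------
# material response with smoothed tension-field (wrinkling) relaxation


def _f(lam: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """dU/dlambda of the deviatoric Ogden sum at J = 1."""
    return (lam[:, None] ** (alpha - 1.0)) @ (2.0 * mu / alpha)


def _w_dev(l1, l2, l3, mu, alpha) -> np.ndarray:
    s = l1[:, None] ** alpha + l2[:, None] ** alpha + l3[:, None] ** alpha - 3.0
    return s @ (2.0 * mu / alpha**2)


def _gp(lam: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """d(lambda * f(lambda))/dlambda = sum 2 mu_i lambda^(alpha_i - 1)."""
    return (lam[:, None] ** (alpha - 1.0)) @ (2.0 * mu)


def _element_response(
    lam_m: np.ndarray, lam_t: np.ndarray, material: OgdenModel, opts: "SolverOptions"
):
    """Energy density W and partials (Wm, Wt) with smoothed wrinkling relaxation.

    The tension-field relaxed energy has four branches - taut,
    hoop-wrinkled (uniaxial along the meridian), meridionally wrinkled
    (uniaxial along the hoop) and fully slack - separated by the
    wrinkling boundaries lam_t = lam_m^(-1/2) (zero trial hoop stress)
    and lam_m = lam_t^(-1/2).  Here the branches are blended by a smooth
    partition of unity in the stretch-space distance from those
    boundaries,

        W = s_t s_m W_taut + (1-s_t) s_m W_uni(lam_m)
          + s_t (1-s_m) W_uni(lam_t) + 0,
        s_t = expit((lam_t - lam_m^(-1/2)) / delta),
        s_m = expit((lam_m - lam_t^(-1/2)) / delta),

    which is exact on the branch boundaries (where adjacent branch
    energies and gradients coincide, including the stress-free
    reference) and deviates from the hard relaxation only inside a
    stretch band of width ``wrinkle_smoothing``.  A tiny quadratic
    regularisation keeps the fully slack branch positive definite.

    Returns (W, Wm, Wt, slack, sigma_m, sigma_t); stresses are blended
    Cauchy stresses.
    """
    if np.any(lam_m <= 0.0) or np.any(lam_t <= 0.0):
        bad = np.nonzero((lam_m <= 0.0) | (lam_t <= 0.0))[0]
        raise InvalidInputError(f"non-positive stretch in elements {bad.tolist()}")
    mu = np.asarray(material.mu)
    alpha = np.asarray(material.alpha)
    delta = opts.wrinkle_smoothing

    # taut trial branch
    l3 = 1.0 / (lam_m * lam_t)
    f_m = _f(lam_m, mu, alpha)
    f_t = _f(lam_t, mu, alpha)
    f_3 = _f(l3, mu, alpha)
    w_taut = _w_dev(lam_m, lam_t, l3, mu, alpha)
    um = f_m - f_3 * l3 / lam_m     # dW_taut/dlam_m
    ut = f_t - f_3 * l3 / lam_t
    sig_m = lam_m * f_m - l3 * f_3  # trial Cauchy stresses
    sig_t = lam_t * f_t - l3 * f_3

    # uniaxial (wrinkled) branches: the slack direction at its natural stretch
    def uni(lam):
        w_u = (lam[:, None] ** alpha + 2.0 * lam[:, None] ** (-alpha / 2.0) - 3.0) @ (
            2.0 * mu / alpha**2
        )
        dw_u = (lam[:, None] ** (alpha - 1.0) - lam[:, None] ** (-alpha / 2.0 - 1.0)) @ (
            2.0 * mu / alpha
        )
        return w_u, dw_u

    wm_uni, dwm_uni = uni(lam_m)
    wt_uni, dwt_uni = uni(lam_t)

    # smooth branch switches on the stretch-space boundary distances
    gap_t = lam_t - lam_m ** -0.5
    gap_m = lam_m - lam_t ** -0.5
    s_t = expit(gap_t / delta)
    s_m = expit(gap_m / delta)
    ds_t = s_t * (1.0 - s_t) / delta
    ds_m = s_m * (1.0 - s_m) / delta
    dgap_t_dlt = 1.0
    dgap_t_dlm = 0.5 * lam_m ** -1.5
    dgap_m_dlm = 1.0
    dgap_m_dlt = 0.5 * lam_t ** -1.5

    a_w = s_t * s_m           # taut weight
    b_w = (1.0 - s_t) * s_m   # hoop-wrinkled weight
    c_w = s_t * (1.0 - s_m)   # meridionally wrinkled weight
    w = a_w * w_taut + b_w * wm_uni + c_w * wt_uni

    def dweights(dst, dsm):
        da = s_m * dst + s_t * dsm
        db = -dst * s_m + (1.0 - s_t) * dsm
        dc = dst * (1.0 - s_m) - s_t * dsm
        return da, db, dc

    da, db, dc = dweights(ds_t * dgap_t_dlm, ds_m * dgap_m_dlm)
    wm = da * w_taut + db * wm_uni + dc * wt_uni + a_w * um + b_w * dwm_uni
    da, db, dc = dweights(ds_t * dgap_t_dlt, ds_m * dgap_m_dlt)
    wt = da * w_taut + db * wm_uni + dc * wt_uni + a_w * ut + c_w * dwt_uni

    # tiny regularisation: stabilises the near-zero-stiffness slack zones
    k = opts.regularization * max(material.initial_shear_modulus, 1.0)
    w = w + k * ((lam_m - 1.0) ** 2 + (lam_t - 1.0) ** 2)
    wm = wm + 2.0 * k * (lam_m - 1.0)
    wt = wt + 2.0 * k * (lam_t - 1.0)

    sig_m_rep = a_w * sig_m + b_w * lam_m * dwm_uni
    sig_t_rep = a_w * sig_t + c_w * lam_t * dwt_uni
    slack = (s_t < 0.5) | (s_m < 0.5)
    return w, wm, wt, slack, sig_m_rep, sig_t_rep


# ----------------------------------------------------------------------
# assembly


def _internal_forces(z, r, mesh: MeridianMesh, material: OgdenModel, opts: SolverOptions):
    """Gradient of the total membrane strain energy wrt nodal (z, r)."""
    dz = np.diff(z)
    dr = np.diff(r)
    length = np.hypot(dz, dr)
    l0 = mesh.ref_length
    lam_m = length / l0
    r_mid = 0.5 * (r[:-1] + r[1:])
    lam_t = r_mid / mesh.ref_mid_radius
    w, wm, wt, slack, sig_m, sig_t = _element_response(lam_m, lam_t, material, opts)
    vol0 = mesh.ref_element_volume

    nn = z.size
    gz = np.zeros(nn)
    gr = np.zeros(nn)
    cm = vol0 * wm / (length * l0)
    gz[1:] += cm * dz
    gz[:-1] -= cm * dz
    gr[1:] += cm * dr
    gr[:-1] -= cm * dr
    ct = vol0 * wt / (2.0 * mesh.ref_mid_radius)
    gr[1:] += ct
    gr[:-1] += ct

    energy = float(np.sum(vol0 * w))
    return gz, gr, energy, lam_m, lam_t, slack, sig_m, sig_t


def _volume_and_grad(z, r):
    dz = np.diff(z)
    ra, rb = r[:-1], r[1:]
    q = ra**2 + ra * rb + rb**2
    v = np.pi / 3.0 * float(np.sum(q * dz))
    nn = z.size
    gvz = np.zeros(nn)
    gvr = np.zeros(nn)
    gvz[1:] += np.pi / 3.0 * q
    gvz[:-1] -= np.pi / 3.0 * q
    gvr[:-1] += np.pi / 3.0 * (2.0 * ra + rb) * dz
    gvr[1:] += np.pi / 3.0 * (2.0 * rb + ra) * dz
    return v, gvz, gvr


def _volume_hessian(z, r):
    """Analytic Hessian of the frusta cavity volume, dof order [z..., r...]."""
    n = z.size
    dz = np.diff(z)
    ra, rb = r[:-1], r[1:]
    c = np.pi / 3.0
    h = np.zeros((2 * n, 2 * n))
    a = np.arange(n - 1)
    b = a + 1
    np.add.at(h, (n + a, n + a), 2.0 * c * dz)
    np.add.at(h, (n + b, n + b), 2.0 * c * dz)
    np.add.at(h, (n + a, n + b), c * dz)
    np.add.at(h, (n + b, n + a), c * dz)
    dra = c * (2.0 * ra + rb)
    drb = c * (ra + 2.0 * rb)
    for rows, vals in ((n + a, dra), (n + b, drb)):
        np.add.at(h, (rows, a), -vals)
        np.add.at(h, (a, rows), -vals)
        np.add.at(h, (rows, b), vals)
        np.add.at(h, (b, rows), vals)
    return h


@dataclass
class _ContactModel:
    """Radial contact of the balloon against a coaxial cylindrical phantom."""

    r_inner_mm: float
    z_start_mm: float
    z_end_mm: float
    band_mm: float
    k_free: float | None   # MPa/mm: thin-wall phantom stiffness; None = rigid
    k_penalty: float       # MPa/mm: penalty for rigid phantom / end bands

    def pressures(self, z, r):
        """Nodal contact pressure (MPa), >= 0, zero outside the phantom span."""
        gap = r - self.r_inner_mm
        in_span = (z >= self.z_start_mm) & (z <= self.z_end_mm)
        in_band = in_span & (
            (z < self.z_start_mm + self.band_mm) | (z > self.z_end_mm - self.band_mm)
        )
        if self.k_free is None:
            k = np.where(in_span, self.k_penalty, 0.0)
        else:
            k = np.where(in_band, self.k_penalty, np.where(in_span, self.k_free, 0.0))
        return k * np.clip(gap, 0.0, None)

    def rigid_mask(self, z):
        in_span = (z >= self.z_start_mm) & (z <= self.z_end_mm)
        if self.k_free is None:
            return in_span
        return in_span & (
            (z < self.z_start_mm + self.band_mm) | (z > self.z_end_mm - self.band_mm)
        )


def _ref_tributary_area(mesh: MeridianMesh) -> np.ndarray:
    """Reference surface area attributed to each node (mm^2)."""
    seg_area = 2.0 * np.pi * mesh.ref_mid_radius * mesh.ref_length
    trib = np.zeros(mesh.z.size)
    trib[:-1] += 0.5 * seg_area
    trib[1:] += 0.5 * seg_area
    return trib


def _contact_forces(z, r, contact: _ContactModel, area_ref: np.ndarray):
    """Contact pressure, radial nodal force and stored penalty energy.

    The nodal force derives from the potential 0.5 * k * gap^2 * A_ref
    (reference tributary area), which keeps the full residual the exact
    gradient of one scalar potential.
    """
    p = contact.pressures(z, r)  # k * gap_+, MPa
    gap = np.clip(r - contact.r_inner_mm, 0.0, None)
    energy = 0.5 * float(np.sum(p * gap * area_ref))
    return p, p * area_ref, energy


# ----------------------------------------------------------------------
# per-target solution: damped Newton on the augmented system, with a
# trust-region SQP minimisation fallback for the wrinkled toe


class _StepFailure(Exception):
    pass


def _residual(z, r, p_mpa, v_target_mm3, mesh, material, contact, opts):
    gz, gr, energy, lam_m, lam_t, slack, sig_m, sig_t = _internal_forces(
        z, r, mesh, material, opts
    )
    v, gvz, gvr = _volume_and_grad(z, r)
    rz = gz - p_mpa * gvz
    rr = gr - p_mpa * gvr
    if contact is not None:
        pc, fc, e_c = _contact_forces(z, r, contact, _ref_tributary_area(mesh))
        rr = rr + fc
        energy += e_c
    else:
        pc = np.zeros(z.size)
    extras = dict(
        energy=energy, volume=v, lam_m=lam_m, lam_t=lam_t, slack=slack,
        contact_pressure=pc,
    )
    return rz, rr, v, extras


def equilibrium_residual(
    state: MembraneState, mesh: MeridianMesh, material: OgdenModel,
    options: SolverOptions | None = None,
) -> np.ndarray:
    """Nodal residual forces (N) of a state, shape (2, n_nodes): (z, r) rows.

    Virtual-work residual of the internal membrane forces minus the
    follower pressure load; exactly zero at the reference configuration
    with P = 0.
    """
    opts = options or SolverOptions()
    p_mpa = mmhg_to_mpa(state.pressure_mmhg)
    rz, rr, _, _ = _residual(
        state.z_mm, state.r_mm, p_mpa, 1.0, mesh, material, None, opts
    )
    return np.vstack([rz, rr])


def _force_scale(mesh: MeridianMesh, material: OgdenModel) -> float:
    return max(
        1.0,
        material.initial_young_modulus
        * float(np.mean(mesh.thickness))
        * float(np.mean(mesh.ref_length)),
    )


def _dof_layout(nn: int):
    """Free dofs: z of nodes 1..nn-1, r of nodes 1..nn-2 (ends pinned)."""
    iz = np.arange(1, nn)
    ir = np.arange(1, nn - 1)
    return iz, ir


def _color_groups(nn: int):
    """Stride-3 colouring of the free dofs for sparse finite differencing.

    A meridian dof at node j only influences force rows of nodes
    j-1..j+1, so dofs of the same family three nodes apart never share a
    row and can be differenced in one residual evaluation.  Yields
    (dof index array in u, node array) pairs; 6 groups total.
    """
    iz, ir = _dof_layout(nn)
    groups = []
    for c in range(3):
        sel = np.nonzero(iz % 3 == c)[0]
        groups.append((sel, iz[sel]))
    for c in range(3):
        sel = np.nonzero(ir % 3 == c)[0]
        groups.append((iz.size + sel, ir[sel]))
    return groups


def _force_rows(node: np.ndarray, nn: int):
    """Force-block rows of u affected by a dof at the given nodes."""
    iz_size = nn - 1
    rows = []
    for j in (node - 1, node, node + 1):
        zr = j[(j >= 1) & (j <= nn - 1)] - 1           # z rows
        rr = j[(j >= 1) & (j <= nn - 2)] - 1 + iz_size  # r rows
        rows.append(zr)
        rows.append(rr)
    return np.concatenate(rows)


_SPARSITY_CACHE: dict[int, tuple] = {}


def _sparsity(nn: int):
    """Cached colour groups and per-dof force-row lists for a mesh size."""
    if nn not in _SPARSITY_CACHE:
        groups = _color_groups(nn)
        rows_by_dof = {}
        for dofs, nodes in groups:
            for k, dof in enumerate(dofs):
                rows_by_dof[int(dof)] = _force_rows(np.array([nodes[k]]), nn)
        _SPARSITY_CACHE[nn] = (groups, rows_by_dof)
    return _SPARSITY_CACHE[nn]


def _fd_force_block(eval_vec, u, vec0, nn, n_extra: int):
    """Coloured finite-difference Jacobian of the force block.

    Differencing the full vector but scattering only the local force
    rows per dof; ``n_extra`` trailing rows/columns (e.g. the pressure /
    constraint border) are left zero for the caller to fill
    analytically.  6 evaluations regardless of mesh size.
    """
    groups, rows_by_dof = _sparsity(nn)
    m_tot = u.size
    jac = np.zeros((m_tot, m_tot))
    for dofs, _nodes in groups:
        h = 1e-7 * (1.0 + np.abs(u[dofs]))
        up = u.copy()
        up[dofs] += h
        dvec = eval_vec(up) - vec0
        for k, dof in enumerate(dofs):
            rows = rows_by_dof[int(dof)]
            jac[rows, dof] = dvec[rows] / h[k]
    return jac


def _newton_step(z, r, p_mpa, v_target_mm3, mesh, material, contact, opts):
    """Damped Newton on the augmented system at one fixed target volume."""
    nn = z.size
    iz = np.arange(1, nn)          # z of node 0 anchors the axial rigid mode
    ir = np.arange(1, nn - 1)      # end radii are pinned at the shaft radius
    m = iz.size + ir.size
    # fixed characteristic force: a state-dependent scale would break the
    # line-search continuity at t -> 0
    fs = _force_scale(mesh, material)

    def unpack(u):
        zz = z.copy()
        rr_ = r.copy()
        zz[iz] = u[: iz.size]
        rr_[ir] = u[iz.size : iz.size + ir.size]
        return zz, rr_, u[-1]

    def eval_res(u):
        zz, rr_, pp = unpack(u)
        rz, rr_res, v, extras = _residual(
            zz, rr_, pp, v_target_mm3, mesh, material, contact, opts
        )
        vec = np.concatenate(
            [rz[iz] / fs, rr_res[ir] / fs, [(v - v_target_mm3) / v_target_mm3]]
        )
        return vec, extras

    u = np.concatenate([z[iz], r[ir], [p_mpa]])
    vec, extras = eval_res(u)
    for _ in range(opts.max_newton_iter):
        fnorm = float(np.max(np.abs(vec[:-1])))
        vnorm = abs(vec[-1])
        if fnorm <= opts.ftol and vnorm <= opts.vtol:
            zz, rr_, pp = unpack(u)
            return zz, rr_, pp, extras
        # coloured FD for the force block; analytic bordered row/column
        jac = _fd_force_block(lambda uu: eval_res(uu)[0], u, vec, nn, 1)
        zz, rr_, pp = unpack(u)
        _, gvz, gvr = _volume_and_grad(zz, rr_)
        gv_free = np.concatenate([gvz[iz], gvr[ir]])
        jac[:m, m] = -gv_free / fs                 # dR/dP
        jac[m, :m] = gv_free / v_target_mm3        # dC/dx
        jac[m, m] = 0.0
        try:
            step = np.linalg.solve(jac, -vec)
        except np.linalg.LinAlgError as exc:
            raise _StepFailure(f"singular Jacobian: {exc}") from exc
        # backtracking line search on the scaled residual norm
        phi0 = float(np.linalg.norm(vec))
        t = 1.0
        for _ in range(30):
            u_try = u + t * step
            try:
                vec_try, extras_try = eval_res(u_try)
            except InvalidInputError:
                t *= 0.5
                continue
            if np.linalg.norm(vec_try) < phi0 * (1.0 - 1e-4 * t) or np.linalg.norm(
                vec_try
            ) < 1e-14:
                u, vec, extras = u_try, vec_try, extras_try
                break
            t *= 0.5
        else:
            raise _StepFailure("line search stalled")
    fnorm = float(np.max(np.abs(vec[:-1])))
    vnorm = abs(vec[-1])
    if fnorm <= opts.ftol and vnorm <= opts.vtol:
        zz, rr_, pp = unpack(u)
        return zz, rr_, pp, extras
    raise _StepFailure(
        f"Newton did not converge (|F|={fnorm:.2e}, |dV|/V={vnorm:.2e})"
    )


def _constrained_minimize(z, r, v_target_mm3, mesh, material, contact, opts):
    """Minimise the relaxed potential subject to V(x) = V_target.

    The (smoothed) tension-field energy is the convexified membrane
    energy, so the wrinkled low-pressure regime that defeats a pure
    Newton iteration is handled as a constrained minimisation:
    trust-region SQP with the exact finite-difference energy Hessian and
    analytic volume gradient/Hessian.  Returns (z, r, P) with P the
    constraint multiplier, i.e. the cavity pressure.
    """
    from scipy.optimize import NonlinearConstraint
    from scipy.optimize import minimize as _sp_minimize

    nn = z.size
    iz = np.arange(1, nn)
    ir = np.arange(1, nn - 1)
    m = iz.size + ir.size
    area_ref = _ref_tributary_area(mesh)
    idx = np.concatenate([iz, nn + ir])

    def unpack(x):
        zz = z.copy()
        rr = r.copy()
        zz[iz] = x[: iz.size]
        rr[ir] = x[iz.size :]
        return zz, rr

    def energy_grad(x):
        zz, rr = unpack(x)
        gz, gr, e, *_ = _internal_forces(zz, rr, mesh, material, opts)
        if contact is not None:
            _, fc, e_c = _contact_forces(zz, rr, contact, area_ref)
            gr = gr + fc
            e += e_c
        return e, np.concatenate([gz[iz], gr[ir]])

    def hess(x):
        _, g0 = energy_grad(x)
        h_mat = _fd_force_block(lambda xv: energy_grad(xv)[1], x, g0, nn, 0)
        return 0.5 * (h_mat + h_mat.T)

    def volval(x):
        zz, rr = unpack(x)
        return _volume_and_grad(zz, rr)[0]

    def voljac(x):
        zz, rr = unpack(x)
        _, gvz, gvr = _volume_and_grad(zz, rr)
        return np.concatenate([gvz[iz], gvr[ir]]).reshape(1, -1)

    def volhess(x, v):
        zz, rr = unpack(x)
        return v[0] * _volume_hessian(zz, rr)[np.ix_(idx, idx)]

    con = NonlinearConstraint(
        volval, v_target_mm3, v_target_mm3, jac=voljac, hess=volhess
    )
    x0 = np.concatenate([z[iz], r[ir]])
    res = _sp_minimize(
        energy_grad, x0, jac=True, hess=hess, method="trust-constr",
        constraints=[con], options=dict(gtol=1e-10, xtol=1e-14, maxiter=500),
    )
    lam = -float(np.atleast_1d(np.squeeze(res.v[0]))[0])
    zz, rr = unpack(res.x)
    return zz, rr, lam


def _solve_target(z, r, p_mpa, v_target_mm3, mesh, material, contact, opts):
    """One converged volume target.

    Tries the damped Newton first (fast in the taut regime); where it
    fails, falls back to the constrained minimisation, polishes with
    Newton from the minimiser's basin, and otherwise accepts the KKT
    point under a looser force-balance check, recording the residual in
    the step diagnostics.
    """
    try:
        return _newton_step(z, r, p_mpa, v_target_mm3, mesh, material, contact, opts)
    except _StepFailure:
        pass
    z2, r2, lam = _constrained_minimize(
        z, r, v_target_mm3, mesh, material, contact, opts
    )
    try:
        return _newton_step(z2, r2, lam, v_target_mm3, mesh, material, contact, opts)
    except _StepFailure:
        pass
    # exact-volume projection: a uniform scalar scaling of the interior
    # radii (scalar Newton) removes any residual constraint violation of
    # the minimiser without perceptibly disturbing equilibrium
    for _ in range(4):
        v_now, _, gvr = _volume_and_grad(z2, r2)
        c = v_now - v_target_mm3
        if abs(c) / v_target_mm3 <= 0.1 * opts.vtol:
            break
        dvds = float(np.dot(gvr[1:-1], r2[1:-1]))
        r2 = r2.copy()
        r2[1:-1] *= 1.0 - c / dvds
    rz, rr_res, v, extras = _residual(
        z2, r2, lam, v_target_mm3, mesh, material, contact, opts
    )
    fs = _force_scale(mesh, material)
    kkt_rel = float(max(np.max(np.abs(rz[1:])), np.max(np.abs(rr_res[1:-1]))) / fs)
    c_rel = abs(v - v_target_mm3) / v_target_mm3
    if c_rel > opts.vtol or kkt_rel > opts.fallback_ftol:
        raise _StepFailure(
            f"minimisation fallback not converged (|F|rel={kkt_rel:.2e}, "
            f"|dV|/V={c_rel:.2e})"
        )
    extras["kkt_rel"] = kkt_rel
    return z2, r2, lam, extras


# ----------------------------------------------------------------------
# continuation and run drivers


@dataclass
class InflationResult:
    """States and curve from a volume-controlled inflation run."""

    states: list[MembraneState]
    curve: InflationCurve
    mesh: MeridianMesh
    contact_report: dict | None = None


def _march(z, r, p_mpa, v_from, v_to, mesh, material, contact, opts):
    """Continuation from v_from to v_to (mm^3) with adaptive substeps."""
    v = v_from
    max_step = opts.max_step_ml * MM3_PER_ML
    dv = math.copysign(min(max_step, abs(v_to - v)), v_to - v) if v_to != v else 0.0
    min_dv = max_step / 2**opts.min_step_halvings
    last_extras = None
    while abs(v_to - v) > 1e-12 * max(v_to, 1.0):
        vt = v + dv if abs(v_to - v) > abs(dv) else v_to
        try:
            z2, r2, p2, extras = _solve_target(z, r, p_mpa, vt, mesh, material, contact, opts)
        except _StepFailure as exc:
            dv *= 0.5
            if abs(dv) < min_dv:
                raise ConvergenceError(
                    f"continuation stalled at V = {mm3_to_ml(v):.4f} ml: {exc}",
                    last_volume_ml=mm3_to_ml(v),
                ) from exc
            continue
        z, r, p_mpa, v = z2, r2, p2, vt
        dv = math.copysign(min(abs(dv) * 1.5, max_step), v_to - v) if v_to != v else dv
        last_extras = extras
    if last_extras is None:
        z, r, p_mpa, last_extras = _solve_target(z, r, p_mpa, v_to, mesh, material, contact, opts)
    return z, r, p_mpa, last_extras


def _make_state(z, r, p_mpa, extras, t_s) -> MembraneState:
    return MembraneState(
        z_mm=z.copy(),
        r_mm=r.copy(),
        pressure_mmhg=float(mpa_to_mmhg(p_mpa)),
        volume_ml=mm3_to_ml(extras["volume"]),
        lambda_m=extras["lam_m"].copy(),
        lambda_theta=extras["lam_t"].copy(),
        slack=extras["slack"].copy(),
        contact_pressure_mmhg=mpa_to_mmhg(extras["contact_pressure"]).copy(),
        time_s=float(t_s),
        residual_rel=float(extras.get("kkt_rel", 0.0)),
    )


def _max_rigid_penetration(z, r, contact: _ContactModel) -> float:
    mask = contact.rigid_mask(z)
    if not np.any(mask):
        return 0.0
    return float(np.max(np.clip(r[mask] - contact.r_inner_mm, 0.0, None), initial=0.0))


def _run_schedule(mesh, material, schedule, contact, opts, provenance):
    z = mesh.z.copy()
    r = mesh.r.copy()
    if contact is not None:
        # feasible starting guess: project penetrating nodes just inside the phantom
        in_span = (z >= contact.z_start_mm) & (z <= contact.z_end_mm)
        cap = contact.r_inner_mm * (1.0 - 1e-4)
        r = np.where(in_span & (r > cap), cap, r)
    p_mpa = 0.0
    v_now, _, _ = _volume_and_grad(z, r)
    states: list[MembraneState] = []
    for t_s, v_ml in schedule:
        v_target = v_ml * MM3_PER_ML
        while True:
            z2, r2, p2, extras = _march(z, r, p_mpa, v_now, v_target, mesh, material, contact, opts)
            if contact is not None:
                pen = _max_rigid_penetration(z2, r2, contact)
                if pen > opts.penetration_tol_rel * contact.r_inner_mm:
                    contact.k_penalty *= 10.0
                    if contact.k_penalty > 1e12:
                        raise ConvergenceError(
                            "contact penalty escalation failed",
                            last_volume_ml=mm3_to_ml(v_now),
                        )
                    continue
            break
        z, r, p_mpa, v_now = z2, r2, p2, v_target
        states.append(_make_state(z, r, p_mpa, extras, t_s))

    taut = [not bool(np.any(s.slack)) for s in states]
    first_taut = taut.index(True) if any(taut) else 0
    reported = states[first_taut:]
    curve = InflationCurve(
        time_s=np.array([s.time_s for s in reported]),
        volume_ml=np.array([s.volume_ml for s in reported]),
        pressure_mmhg=np.array([max(s.pressure_mmhg, 0.0) for s in reported]),
        diameter_mm=np.array([s.central_diameter_mm() for s in reported]),
        provenance=provenance,
    )
    return states, curve


def membrane_strain_energy(
    state: MembraneState, mesh: MeridianMesh, material: OgdenModel,
    options: SolverOptions | None = None,
) -> float:
    """Total stored membrane strain energy of a state (N mm = mJ).

    Along a quasi-static volume-controlled inflation, the increase of
    this energy equals the injected work integral of P dV (taut regime,
    no contact), which is the solver's energy-consistency check.
    """
    opts = options or SolverOptions()
    _gz, _gr, e, *_ = _internal_forces(state.z_mm, state.r_mm, mesh, material, opts)
    return float(e)


def cylindrical_membrane_pressure(
    lam_theta: float, lam_z: float, r0_mm: float, t0_mm: float, material: OgdenModel
) -> float:
    """Closed-form inflation pressure (mmHg) of an infinite cylindrical membrane.

    Thin-membrane equilibrium (Laplace, sigma_theta = P r / t) for an
    incompressible Ogden cylinder of reference radius r0 and thickness
    t0 at hoop stretch lambda_theta and axial stretch lambda_z:

        P = sigma_theta * t0 / (r0 * lam_theta^2 * lam_z),
        sigma_theta = sum_i (2 mu_i/alpha_i)(lam_theta^alpha_i
                                             - (lam_theta lam_z)^(-alpha_i)).

    This is the analytic oracle for the mid-section of a long balloon.
    """
    if lam_theta <= 0.0 or lam_z <= 0.0:
        raise InvalidInputError("stretches must be > 0")
    mu = np.asarray(material.mu)
    alpha = np.asarray(material.alpha)
    sig = float(np.sum(2.0 * mu / alpha * (lam_theta**alpha - (lam_theta * lam_z) ** -alpha)))
    p_mpa = sig * t0_mm / (r0_mm * lam_theta**2 * lam_z)
    return mpa_to_mmhg(p_mpa)


def solve_free_inflation(
    design: BalloonDesign,
    material: OgdenModel,
    protocol: InflationProtocol | None = None,
    *,
    volume_targets_ml: list[float] | None = None,
    n_elements: int = 200,
    options: SolverOptions | None = None,
) -> InflationResult:
    """Volume-controlled free inflation of the balloon.

    Targets come either from the protocol schedule (V(t) = V0 + Vdot t at
    the sampling instants) or from an explicit ``volume_targets_ml``
    list.  The curve reports pressure and the diameter of the central
    section at each target; states that are not fully taut are excluded
    from the curve (but kept in ``states``).
    """
    opts = options or SolverOptions()
    mesh = build_profile_mesh(design, n_elements)
    v_ref = mesh.reference_cavity_volume_ml()
    if volume_targets_ml is not None:
        schedule = [(float(i), float(v)) for i, v in enumerate(volume_targets_ml)]
    else:
        protocol = protocol or InflationProtocol()
        schedule = volume_schedule(protocol, v0_ml=v_ref)
    states, curve = _run_schedule(mesh, material, schedule, None, opts, "computational")
    return InflationResult(states=states, curve=curve, mesh=mesh)


def solve_constrained_inflation(
    design: BalloonDesign,
    material: OgdenModel,
    phantom: CylinderPhantom,
    phantom_material: LinearElasticModel | None,
    protocol: InflationProtocol | None = None,
    *,
    volume_targets_ml: list[float] | None = None,
    n_elements: int = 200,
    options: SolverOptions | None = None,
) -> InflationResult:
    """Inflation inside a coaxial cylindrical phantom.

    ``phantom_material = None`` makes the phantom rigid.  A compliant
    phantom dilates with the thin-wall radial stiffness E t / r^2; its
    constrained end bands are held at the reference radius.  The contact
    report summarises peak diameter, contact pressure and penetration.
    """
    opts = options or SolverOptions()
    mesh = build_profile_mesh(design, n_elements)
    v_ref = mesh.reference_cavity_volume_ml()
    if volume_targets_ml is not None:
        schedule = [(float(i), float(v)) for i, v in enumerate(volume_targets_ml)]
    else:
        protocol = protocol or InflationProtocol()
        schedule = volume_schedule(protocol, v0_ml=v_ref)

    k_pen = opts.penalty_scale * material.initial_young_modulus * float(
        np.mean(mesh.thickness)
    ) / phantom.inner_radius_mm**2
    if phantom_material is None:
        k_free = None
    else:
        k_free = cylinder_pv_response(phantom, phantom_material, 0.0).radial_stiffness_mpa_per_mm
    z_mid_balloon = 0.5 * (mesh.z[0] + mesh.z[-1])
    contact = _ContactModel(
        r_inner_mm=phantom.inner_radius_mm,
        z_start_mm=z_mid_balloon - 0.5 * phantom.length_mm,
        z_end_mm=z_mid_balloon + 0.5 * phantom.length_mm,
        band_mm=phantom.end_band_mm,
        k_free=k_free,
        k_penalty=k_pen,
    )
    states, curve = _run_schedule(mesh, material, schedule, contact, opts, "computational")
    pen = max(_max_rigid_penetration(s.z_mm, s.r_mm, contact) for s in states)
    report = {
        "max_diameter_mm": max(s.max_diameter_mm() for s in states),
        "max_contact_pressure_mmhg": max(
            float(np.max(s.contact_pressure_mmhg)) for s in states
        ),
        "max_rigid_penetration_mm": pen,
        "final_penalty_mpa_per_mm": contact.k_penalty,
        "rigid": phantom_material is None,
    }
    return InflationResult(states=states, curve=curve, mesh=mesh, contact_report=report)
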