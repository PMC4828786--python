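"""Constitutive models and tensile-test analysis for the balloon membrane.

The non-compliant balloon membrane (a PET/Nylon-class film) is modelled as
an isotropic hyperelastic solid with an Ogden strain-energy density in
principal stretches,

    U = sum_i 2*mu_i/alpha_i**2 * (l1^alpha_i + l2^alpha_i + l3^alpha_i - 3)
      + sum_i 1/delta_i * (J_el - 1)^(2i),

where the l_i are deviatoric principal stretches, J_el the elastic volume
ratio, and (mu_i, alpha_i, delta_i) the material triplets.  Terms with
delta_i = 0 carry no volumetric energy; the membrane solver treats the
film as fully incompressible and evaluates only the deviatoric part.

The module also provides uniaxial-test plumbing: the incompressible
uniaxial stress reduction, non-convex least-squares fitting of Ogden
coefficients to stress-strain data, an isotropy check between
longitudinal and circumferential specimens, and residual-strain
measurement from cyclic tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InvalidInputError

Convention = Literal["cauchy", "nominal"]


@dataclass(frozen=True)
class OgdenModel:
    """Ogden hyperelastic material of order N = len(mu).

    Parameters
    ----------
    mu, alpha, delta:
        Material triplets.  ``mu`` carries stress units (see ``units``),
        ``alpha`` is dimensionless, ``delta`` has inverse-stress units.
        Individual ``mu_i`` may be negative; the initial shear modulus
        ``sum(mu)`` must be positive.
    poisson:
        Poisson ratio, retained as metadata (the membrane theory used by
        the solver is fully incompressible).
    units:
        Stress unit tag for ``mu`` (and implicitly ``1/delta``).
    """

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    delta: tuple[float, ...] | None = None
    poisson: float = 0.5
    units: str = "MPa"

    def __post_init__(self):
        mu = tuple(float(m) for m in np.atleast_1d(self.mu))
        alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        delta = self.delta
        if delta is None:
            delta = (0.0,) * len(mu)
        delta = tuple(float(d) for d in np.atleast_1d(delta))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "delta", delta)
        if len(mu) < 1:
            raise InvalidInputError("Ogden order must be >= 1")
        if not (len(mu) == len(alpha) == len(delta)):
            raise InvalidInputError("mu, alpha, delta must have equal length")
        if any(a == 0.0 for a in alpha):
            raise InvalidInputError("alpha_i must be nonzero")
        if sum(mu) <= 0.0:
            raise InvalidInputError(
                f"initial shear modulus sum(mu) = {sum(mu):g} must be positive"
            )
        if any(d < 0.0 for d in delta):
            raise InvalidInputError("delta_i must be >= 0")
        if not (0.0 <= self.poisson <= 0.5):
            raise InvalidInputError("poisson ratio must lie in [0, 0.5]")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def initial_shear_modulus(self) -> float:
        return float(sum(self.mu))

    @property
    def initial_young_modulus(self) -> float:
        """Incompressible small-strain Young's modulus 3*sum(mu)."""
        return 3.0 * self.initial_shear_modulus


#: Third-order Ogden coefficients for the PET membrane of a 23 mm
#: non-compliant valvuloplasty balloon, obtained from uniaxial tensile
#: characterisation of the film.  Stress units are taken as MPa: with
#: these triplets the initial Young's modulus is 3*sum(mu) ~ 0.73 GPa,
#: the right magnitude for a thin PET/Nylon balloon film, and the
#: predicted inflation pressures fall in the bench range of a few
#: hundred kPa.  delta_2 = delta_3 = 0, so the volumetric energy reduces
#: to a single penalty term; the membrane solver ignores it and treats
#: the film as incompressible.
BALLOON_MEMBRANE_OGDEN = OgdenModel(
    mu=(-4715.57, 2480.94, 2479.35),
    alpha=(4.89, 6.90, 1.13),
    delta=(1.38, 0.0, 0.0),
    poisson=0.45,
    units="MPa",
)


@dataclass(frozen=True)
class LinearElasticModel:
    """Linear, elastic, isotropic material (used for phantom cylinders)."""

    young_modulus: float
    poisson: float = 0.25
    units: str = "MPa"

    def __post_init__(self):
        if self.young_modulus <= 0.0:
            raise InvalidInputError("young_modulus must be positive")
        if not (0.0 <= self.poisson < 0.5):
            raise InvalidInputError("poisson ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class StretchState:
    """Principal stretches (l1, l2, l3) of a material point."""

    stretches: tuple[float, float, float]

    def __post_init__(self):
        s = tuple(float(v) for v in self.stretches)
        object.__setattr__(self, "stretches", s)
        if any(v <= 0.0 for v in s):
            raise InvalidInputError(f"principal stretches must be > 0, got {s}")

    @property
    def volume_ratio(self) -> float:
        l1, l2, l3 = self.stretches
        return l1 * l2 * l3

    @property
    def deviatoric(self) -> tuple[float, float, float]:
        j = self.volume_ratio
        scale = j ** (-1.0 / 3.0)
        return tuple(scale * v for v in self.stretches)


@dataclass(frozen=True)
class StressStrainCurve:
    """Ordered (engineering strain, engineering stress) samples.

    The nominal (engineering) convention is assumed for tensile output,
    as is standard for dumb-bell specimens.
    """

    strain: np.ndarray
    stress: np.ndarray
    direction: str | None = None
    cycle: int | None = None
    stress_units: str = "MPa"

    def __post_init__(self):
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.shape != stress.shape or strain.ndim != 1:
            raise InvalidInputError("strain and stress must be 1-D arrays of equal length")
        if strain.size < 2:
            raise InvalidInputError("a curve needs at least 2 samples")
        if not np.all(np.isfinite(strain)) or not np.all(np.isfinite(stress)):
            raise InvalidInputError("strain/stress must be finite")

    @property
    def max_strain(self) -> float:
        return float(np.max(self.strain))

    def interp(self, strain_grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of stress on a monotonic branch."""
        order = np.argsort(self.strain, kind="stable")
        return np.interp(strain_grid, self.strain[order], self.stress[order])


def _dU_dlambda(lam: np.ndarray, model: OgdenModel) -> np.ndarray:
    """f(l) = dU/dl along one principal direction at J = 1 (per stretch)."""
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(model.mu)
    alpha = np.asarray(model.alpha)
    return (lam[..., None] ** (alpha - 1.0)) @ (2.0 * mu / alpha)


def ogden_energy(state: StretchState, model: OgdenModel) -> float:
    """Strain-energy density U at the given stretch state.

    The deviatoric sum uses the deviatoric stretches; each volumetric
    term (1/delta_i)(J_el - 1)^(2i) is included only where delta_i > 0
    (delta_i = 0 marks an incompressible-penalty term that is omitted).
    """
    if not isinstance(state, StretchState):
        state = StretchState(tuple(state))
    lbar = np.asarray(state.deviatoric)
    mu = np.asarray(model.mu)
    alpha = np.asarray(model.alpha)
    u_dev = float(np.sum(2.0 * mu / alpha**2 * (np.sum(lbar[:, None] ** alpha, axis=0) - 3.0)))
    j = state.volume_ratio
    u_vol = 0.0
    for i, d in enumerate(model.delta, start=1):
        if d > 0.0:
            u_vol += (j - 1.0) ** (2 * i) / d
    return u_dev + u_vol


def ogden_uniaxial_stress(
    lam: float | np.ndarray, model: OgdenModel, convention: Convention = "cauchy"
) -> float | np.ndarray:
    """Uniaxial stress at stretch ``lam`` for an incompressible Ogden solid.

    With transverse stretches lam**(-1/2) the Cauchy stress is
    sigma = sum_i (2 mu_i / alpha_i) (lam^alpha_i - lam^(-alpha_i/2));
    the nominal (engineering) stress is sigma / lam.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0.0):
        raise InvalidInputError("stretch must be > 0")
    mu = np.asarray(model.mu)
    alpha = np.asarray(model.alpha)
    terms = lam_arr[..., None] ** alpha - lam_arr[..., None] ** (-alpha / 2.0)
    sigma = terms @ (2.0 * mu / alpha)
    if convention == "nominal":
        sigma = sigma / lam_arr
    elif convention != "cauchy":
        raise InvalidInputError(f"unknown stress convention {convention!r}")
    if np.ndim(lam) == 0:
        return float(sigma)
    return sigma


def _uniaxial_stress_basis(lam: np.ndarray, alpha: np.ndarray, convention: Convention) -> np.ndarray:
    """Design matrix Phi with sigma = Phi @ mu (the model is linear in mu)."""
    phi = (2.0 / alpha) * (lam[:, None] ** alpha - lam[:, None] ** (-alpha / 2.0))
    if convention == "nominal":
        phi = phi / lam[:, None]
    return phi


def _drucker_stable(mu: np.ndarray, alpha: np.ndarray, lam_grid: np.ndarray) -> bool:
    """Monotone Cauchy stress over the fitted stretch range (Drucker-type filter)."""
    dsig = (
        lam_grid[:, None] ** (alpha - 1.0) + 0.5 * lam_grid[:, None] ** (-alpha / 2.0 - 1.0)
    ) @ (2.0 * mu)
    return bool(np.all(dsig > 0.0))


_ALPHA_SEED_BASES = (
    (2.0, 4.0, 6.0, 8.0, 10.0),
    (1.0, 3.0, 5.0, 7.0, 9.0),
    (-2.0, 2.0, 4.0, 6.0, 8.0),
    (1.5, 3.5, 5.5, 7.5, 9.5),
    (0.5, 1.25, 2.5, 5.0, 7.0),
)


@dataclass(frozen=True)
class OgdenFit:
    """Result of :func:`fit_ogden` (fitted model plus fit diagnostics)."""

    model: OgdenModel
    residual_norm: float
    rel_residual: float
    convention: Convention
    n_starts_stable: int


def fit_ogden(
    curve: StressStrainCurve,
    order: int,
    convention: Convention = "nominal",
    n_starts: int = 5,
) -> OgdenFit:
    """Least-squares fit of an incompressible Ogden model to uniaxial data.

    Ogden fits are non-convex and non-unique, so the fit runs a
    trust-region solver from several deterministic alpha seeds, solving
    the (linear) mu sub-problem exactly at each step (variable
    projection), and keeps the best fit that passes a Drucker-type
    stability filter (sum(mu) > 0 and monotone uniaxial Cauchy stress on
    the data range).
    """
    if order < 1:
        raise InvalidInputError("order must be >= 1")
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    pos = strain > 0.0
    if int(np.count_nonzero(pos)) < 2 * order + 1:
        raise InvalidInputError(
            f"need at least {2 * order + 1} samples with strain > 0 for order {order}, "
            f"got {int(np.count_nonzero(pos))}"
        )
    lam = 1.0 + strain[pos]
    sig = stress[pos]
    lam_grid = np.linspace(lam.min(), lam.max(), 64)
    sig_scale = float(np.max(np.abs(sig)))

    def mu_for(alpha: np.ndarray) -> np.ndarray:
        phi = _uniaxial_stress_basis(lam, alpha, convention)
        mu, *_ = np.linalg.lstsq(phi, sig, rcond=None)
        return mu

    def residual(alpha: np.ndarray) -> np.ndarray:
        if np.any(np.abs(alpha) < 1e-6):
            return np.full(lam.shape, 1e6)
        phi = _uniaxial_stress_basis(lam, alpha, convention)
        mu, *_ = np.linalg.lstsq(phi, sig, rcond=None)
        return phi @ mu - sig

    best = None
    n_stable = 0
    diagnostics: dict = {"starts": []}
    for base in _ALPHA_SEED_BASES[:n_starts]:
        x0 = np.asarray(base[:order], dtype=float)
        sol = least_squares(
            residual, x0, method="trf", ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=4000
        )
        alpha = sol.x
        mu = mu_for(alpha)
        rnorm = float(np.linalg.norm(residual(alpha)))
        stable = float(np.sum(mu)) > 0.0 and _drucker_stable(mu, alpha, lam_grid)
        diagnostics["starts"].append(
            {"alpha0": list(x0), "alpha": list(alpha), "sum_mu": float(np.sum(mu)),
             "residual_norm": rnorm, "stable": stable}
        )
        if stable:
            n_stable += 1
            if best is None or rnorm < best[0]:
                best = (rnorm, mu, alpha)
    if best is None:
        raise FitError(
            "no stable Ogden fit found (sum(mu) <= 0 or non-monotone stress in all starts)",
            diagnostics=diagnostics,
        )
    rnorm, mu, alpha = best
    model = OgdenModel(
        mu=tuple(mu), alpha=tuple(alpha), delta=(0.0,) * order,
        poisson=0.5, units=curve.stress_units,
    )
    return OgdenFit(
        model=model,
        residual_norm=rnorm,
        rel_residual=rnorm / max(np.linalg.norm(sig), 1e-300) if sig_scale else rnorm,
        convention=convention,
        n_starts_stable=n_stable,
    )


def check_isotropy(
    longitudinal: StressStrainCurve,
    circumferential: StressStrainCurve,
    strain_max: float = 0.10,
    n_grid: int = 200,
) -> float:
    """Maximum relative stress deviation between the two test directions.

    Both curves are interpolated on a common strain grid over
    (0, strain_max]; the deviation at each grid point is
    |sigma_long - sigma_circ| / max(sigma_long, sigma_circ).  A value
    well below ~0.1 over strains < 10 % supports treating the membrane
    as isotropic in the working range of the balloon.
    """
    if strain_max <= 0.0:
        raise InvalidInputError("strain_max must be positive")
    for name, c in (("longitudinal", longitudinal), ("circumferential", circumferential)):
        if c.max_strain < strain_max:
            raise InvalidInputError(
                f"{name} curve covers strain up to {c.max_strain:g} < strain_max {strain_max:g}"
            )
    grid = np.linspace(strain_max / n_grid, strain_max, n_grid)
    s_long = longitudinal.interp(grid)
    s_circ = circumferential.interp(grid)
    denom = np.maximum(np.maximum(s_long, s_circ), 1e-300)
    dev = np.abs(s_long - s_circ) / denom
    return float(np.max(dev))


def residual_strain(
    cycles: Sequence[StressStrainCurve], zero_stress_frac: float = 1e-3
) -> list[float]:
    """Residual strain of each load/unload cycle.

    Each cycle is a curve sampled in time (strain rising to the cycle
    peak, then falling on unloading).  The residual strain is where the
    unloading branch crosses zero stress, located by linear interpolation
    between the bracketing samples.  To avoid noise-induced early
    crossings, "zero" is taken as ``zero_stress_frac`` of the cycle peak
    stress (default 0.1 %).
    """
    if len(cycles) < 1:
        raise InvalidInputError("need at least one cycle")
    out = []
    for k, cyc in enumerate(cycles):
        strain = cyc.strain
        stress = cyc.stress
        i_peak = int(np.argmax(strain))
        un_strain = strain[i_peak:]
        un_stress = stress[i_peak:]
        if un_strain.size < 2:
            raise InvalidInputError(f"cycle {k} has no unloading branch")
        threshold = zero_stress_frac * float(np.max(stress))
        below = np.nonzero(un_stress <= threshold)[0]
        if below.size == 0:
            raise InvalidInputError(
                f"cycle {k}: unloading branch never reaches the zero-stress threshold "
                f"({threshold:g})"
            )
        # the threshold only guards against noise-induced early crossings;
        # the residual strain itself is the zero-stress crossing
        zero = np.nonzero(un_stress <= 0.0)[0]
        target = 0.0
        j = int(zero[0]) if zero.size else int(below[0])
        if not zero.size:
            target = threshold
        if j == 0:
            out.append(float(un_strain[0]))
            continue
        s0, s1 = un_stress[j - 1], un_stress[j]
        e0, e1 = un_strain[j - 1], un_strain[j]
        t = (target - s0) / (s1 - s0) if s1 != s0 else 1.0
        out.append(float(e0 + t * (e1 - e0)))
    return out
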