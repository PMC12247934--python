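"""Forward constitutive model of the vessel wall.

The wall is an incompressible hyperelastic membrane described by a
four-fiber-family (4FF) strain-energy function: an isotropic neo-Hookean
ground matrix (elastin and amorphous constituents) plus four exponentially
strain-stiffening collagen fiber families oriented axially (0 deg),
circumferentially (90 deg) and along a symmetric diagonal pair (+/- alpha0
from the axis). The diagonal pair shares one modulus and one exponent.

Per unit reference volume, with circumferential stretch lth, axial stretch
lz and radial stretch lr = 1/(lth*lz) from incompressibility::

    W = (c/2) (lth^2 + lz^2 + lr^2 - 3)
        + sum_k  c1_k / (4 c2_k) * [exp(c2_k (lk^2 - 1)^2) - 1]

    lk^2 = lth^2 sin^2(a_k) + lz^2 cos^2(a_k),   a_k in {0, 90, +a0, -a0}

The circumferential Cauchy stress follows from the reduced (incompressible)
energy ``sth = lth * dW/dlth``, and the luminal pressure from the thin-wall
(Laplace) equilibrium ``P = sth * h / a`` with deformed inner radius ``a``
and thickness ``h`` mapped from the unloaded geometry by exact
incompressible cylinder kinematics at mid-wall.

A fiber family with ``c2 = 0`` degenerates continuously to the quadratic
energy ``(c1/4) (lk^2 - 1)^2``; the stress expression is continuous in
``c2`` without special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, ParameterError
from .units import kpa_to_mmhg

__all__ = [
    "VesselGeometry",
    "FourFiberParams",
    "LoadedState",
    "deformed_geometry",
    "strain_energy",
    "circ_stress",
    "equilibrium_pressure",
    "pressure_diameter_curve",
    "rupture_check",
    "PRESETS",
]

_C2_QUADRATIC_LIMIT = 1e-12


@dataclass(frozen=True)
class VesselGeometry:
    """Unloaded reference configuration of a cylindrical vessel segment.

    Attributes
    ----------
    inner_radius : float
        Unloaded inner radius ``A`` in um.
    thickness : float
        Unloaded wall thickness ``H`` in um.
    axial_stretch : float
        In-situ axial stretch ``lz`` held constant during inflation.
    """

    inner_radius: float
    thickness: float
    axial_stretch: float = 1.0

    def __post_init__(self) -> None:
        if not self.inner_radius > 0:
            raise ParameterError("inner_radius must be > 0")
        if not self.thickness > 0:
            raise ParameterError("thickness must be > 0")
        if not self.axial_stretch > 0:
            raise ParameterError("axial_stretch must be > 0")

    @property
    def outer_radius(self) -> float:
        """Unloaded outer radius ``B = A + H`` (um)."""
        return self.inner_radius + self.thickness

    @property
    def midwall_radius(self) -> float:
        """Unloaded mid-wall radius ``R_m = A + H/2`` (um)."""
        return self.inner_radius + 0.5 * self.thickness


@dataclass(frozen=True)
class FourFiberParams:
    """Material parameters of the four-fiber-family strain energy.

    ``c`` (kPa) is the isotropic matrix modulus; ``c1_axial``,
    ``c1_circ``, ``c1_diag`` (kPa) and ``c2_axial``, ``c2_circ``,
    ``c2_diag`` (dimensionless) are the fiber moduli and exponential
    stiffening factors (the diagonal +/- pair shares one value of each);
    ``alpha0_deg`` is the diagonal fiber angle from the axial direction.
    """

    c: float
    c1_axial: float
    c1_circ: float
    c1_diag: float
    c2_axial: float
    c2_circ: float
    c2_diag: float
    alpha0_deg: float = 45.0

    def __post_init__(self) -> None:
        for name in ("c", "c1_axial", "c1_circ", "c1_diag",
                     "c2_axial", "c2_circ", "c2_diag"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 < self.alpha0_deg < 90.0:
            raise ParameterError("alpha0_deg must lie in (0, 90)")

    def _families(self) -> list[tuple[float, float, float]]:
        """(c1, c2, angle_rad) for the four families."""
        a0 = np.deg2rad(self.alpha0_deg)
        return [
            (self.c1_axial, self.c2_axial, 0.0),
            (self.c1_circ, self.c2_circ, np.pi / 2.0),
            (self.c1_diag, self.c2_diag, a0),
            (self.c1_diag, self.c2_diag, -a0),
        ]


@dataclass(frozen=True)
class LoadedState:
    """One pressurized equilibrium state of the vessel."""

    pressure: float        # mmHg
    inner_radius: float    # um
    thickness: float       # um
    circ_stretch: float    # mid-wall
    circ_stress: float     # kPa

    @property
    def outer_diameter(self) -> float:
        return 2.0 * (self.inner_radius + self.thickness)

    @property
    def inner_diameter(self) -> float:
        return 2.0 * self.inner_radius


def deformed_geometry(geom: VesselGeometry, circ_stretch: float) -> tuple[float, float]:
    """Map the unloaded wall through incompressible cylinder kinematics.

    The mid-wall radius deforms as ``r_m = lth * R_m``; inner and outer radii
    follow from exact conservation of wall cross-section under axial stretch:
    ``(b^2 - a^2) * lz = B^2 - A^2``.

    Returns
    -------
    (a, h) : deformed inner radius and wall thickness in um.
    """
    A, H, lz = geom.inner_radius, geom.thickness, geom.axial_stretch
    Rm = geom.midwall_radius
    B = geom.outer_radius
    rm = circ_stretch * Rm
    a_sq = rm * rm - (Rm * Rm - A * A) / lz
    if a_sq <= 0.0:
        raise DomainError(
            f"circ_stretch {circ_stretch} too small for a real inner radius "
            f"(a^2 = {a_sq:.3g} um^2)"
        )
    a = np.sqrt(a_sq)
    b = np.sqrt(a_sq + (B * B - A * A) / lz)
    return float(a), float(b - a)


def strain_energy(params: FourFiberParams, circ_stretch: float,
                  axial_stretch: float = 1.0) -> float:
    """Stored energy density W (kPa) at the given biaxial stretch state."""
    lth, lz = float(circ_stretch), float(axial_stretch)
    if lth <= 0 or lz <= 0:
        raise DomainError("stretches must be positive")
    lr = 1.0 / (lth * lz)
    W = 0.5 * params.c * (lth * lth + lz * lz + lr * lr - 3.0)
    for c1, c2, ang in params._families():
        if c1 == 0.0:
            continue
        lk2 = lth * lth * np.sin(ang) ** 2 + lz * lz * np.cos(ang) ** 2
        e = lk2 - 1.0
        if c2 < _C2_QUADRATIC_LIMIT:
            W += 0.25 * c1 * e * e
        else:
            W += c1 / (4.0 * c2) * np.expm1(c2 * e * e)
    return float(W)


def circ_stress(params: FourFiberParams, circ_stretch: float,
                axial_stretch: float = 1.0) -> float:
    """Circumferential Cauchy stress sth (kPa), analytic.

    Derived from the reduced energy with the radial stretch eliminated by
    incompressibility: ``sth = lth * dW_hat/dlth``. Vanishes at the
    reference state.
    """
    lth, lz = float(circ_stretch), float(axial_stretch)
    if lth <= 0 or lz <= 0:
        raise DomainError("stretches must be positive")
    # Matrix: lth * c * (lth - lth^-3 lz^-2)
    s = params.c * (lth * lth - 1.0 / (lth * lth * lz * lz))
    for c1, c2, ang in params._families():
        if c1 == 0.0:
            continue
        sin2 = np.sin(ang) ** 2
        if sin2 == 0.0:
            continue  # axial family carries no circumferential load
        lk2 = lth * lth * sin2 + lz * lz * (1.0 - sin2)
        e = lk2 - 1.0
        s += c1 * e * np.exp(c2 * e * e) * lth * lth * sin2
    return float(s)


def _circ_stress_dlth(params: FourFiberParams, lth: float, lz: float) -> float:
    """Analytic d(sth)/d(lth) at fixed lz (kPa per unit stretch)."""
    s = params.c * (2.0 * lth + 2.0 / (lth ** 3 * lz * lz))
    for c1, c2, ang in params._families():
        if c1 == 0.0:
            continue
        sin2 = np.sin(ang) ** 2
        if sin2 == 0.0:
            continue
        lk2 = lth * lth * sin2 + lz * lz * (1.0 - sin2)
        e = lk2 - 1.0
        ee = np.exp(c2 * e * e)
        # d/dlth [ c1 e exp(c2 e^2) lth^2 sin2 ]
        de = 2.0 * lth * sin2
        s += c1 * sin2 * (
            de * ee * lth * lth * (1.0 + 2.0 * c2 * e * e)
            + 2.0 * lth * e * ee
        )
    return float(s)


def equilibrium_pressure(params: FourFiberParams, geom: VesselGeometry,
                         circ_stretch: float) -> float:
    """Luminal pressure (mmHg) balancing the wall at the given stretch.

    Thin-wall (Laplace) closure: ``P = sth * h / a`` with the deformed
    geometry from :func:`deformed_geometry`.
    """
    a, h = deformed_geometry(geom, circ_stretch)
    sth = circ_stress(params, circ_stretch, geom.axial_stretch)
    return kpa_to_mmhg(sth * h / a)


def _loaded_state(params: FourFiberParams, geom: VesselGeometry,
                  lth: float, pressure: float) -> LoadedState:
    a, h = deformed_geometry(geom, lth)
    sth = circ_stress(params, lth, geom.axial_stretch)
    return LoadedState(pressure=float(pressure), inner_radius=a, thickness=h,
                       circ_stretch=float(lth), circ_stress=sth)


def solve_stretch(params: FourFiberParams, geom: VesselGeometry,
                  pressure: float, lth_max: float = 2.5,
                  xtol: float = 1e-10) -> float:
    """Invert the equilibrium curve: the stretch at which the wall carries
    ``pressure`` (mmHg). Bracketed root-find on ``lth``.
    """
    lz = geom.axial_stretch
    Rm, A = geom.midwall_radius, geom.inner_radius
    # kinematic lower bound: a^2 > 0
    lth_kin = np.sqrt(max(Rm * Rm - A * A, 0.0) / lz) / Rm
    lo = max(lth_kin * (1.0 + 1e-9), 0.25)
    f = lambda l: equilibrium_pressure(params, geom, l) - pressure

    flo, fhi = f(lo), f(lth_max)
    if flo > 0.0:
        raise ConvergenceError(
            f"pressure {pressure} mmHg below the curve's range on "
            f"[{lo:.4g}, {lth_max:.4g}]"
        )
    if fhi < 0.0:
        raise ConvergenceError(
            f"pressure {pressure} mmHg above the curve's reachable range on "
            f"[{lo:.4g}, {lth_max:.4g}] (max {pressure + fhi:.4g} mmHg)"
        )
    return float(brentq(f, lo, lth_max, xtol=xtol))


def pressure_diameter_curve(params: FourFiberParams, geom: VesselGeometry,
                            pressures, lth_max: float = 2.5) -> list[LoadedState]:
    """Equilibrium states at each prescribed pressure (mmHg, ascending).

    For each pressure the circumferential stretch is found by bracketed
    root-finding; the returned outer diameter is non-decreasing in pressure.
    """
    pressures = np.asarray(pressures, dtype=float)
    if np.any(pressures < 0):
        raise ParameterError("pressures must be >= 0")
    states = []
    for P in pressures:
        lth = solve_stretch(params, geom, float(P), lth_max=lth_max)
        states.append(_loaded_state(params, geom, lth, float(P)))
    return states


def rupture_check(state: LoadedState, failure_stress: float) -> bool:
    """True iff the wall stress has reached the failure stress (boundary
    inclusive)."""
    if not failure_stress > 0:
        raise ParameterError("failure_stress must be > 0")
    return bool(state.circ_stress >= failure_stress)


# ---------------------------------------------------------------------------
# Presets
#
# Two documented calibration presets bracket the physiological range seen in
# small-artery myography: "compliant" has a soft elastin-dominated toe region
# with collagen engaging late, so its pressure-diameter curve keeps rising to
# a plateau near 200 mmHg; "stiff" engages its collagen early (large c2) and
# plateaus near 125 mmHg with much smaller pulse distension. The numbers are
# package calibration choices, not measured tissue values.
# ---------------------------------------------------------------------------

PRESET_GEOMETRY = VesselGeometry(inner_radius=200.0, thickness=30.0, axial_stretch=1.0)
"""Carotid-like reference geometry used by the shipped presets
(unloaded outer diameter 460 um, wall 30 um)."""

PRESETS: dict[str, FourFiberParams] = {
    "compliant": FourFiberParams(
        c=30.0, c1_axial=20.0, c1_circ=20.0, c1_diag=14.0,
        c2_axial=0.8, c2_circ=0.8, c2_diag=0.8, alpha0_deg=45.0,
    ),
    "stiff": FourFiberParams(
        c=30.0, c1_axial=60.0, c1_circ=60.0, c1_diag=42.0,
        c2_axial=16.0, c2_circ=16.0, c2_diag=16.0, alpha0_deg=45.0,
    ),
}


def preset(name: str) -> FourFiberParams:
    """Look up a shipped parameter preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
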