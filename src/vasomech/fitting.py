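"""Inverse problem: constitutive parameters from pressure-diameter data.

Given a static inflation sweep (pressure, loaded outer diameter) and the
unloaded geometry, this module

* converts measured states to experimental circumferential stress-stretch
  pairs (Laplace stress ``P a / h``, mid-wall stretch from exact
  incompressible kinematics),
* fits the four-fiber-family parameters by seeded multistart nonlinear
  least squares on the outer-diameter residuals, and
* evaluates the linearized (incremental) material stiffness
  ``d(sigma_theta)/d(lambda_theta)`` at loaded equilibrium states, by
  default at 20, 90 and 120 mmHg.

The 4FF parameters are notoriously non-identifiable from a single inflation
protocol: distinct parameter vectors can produce near-identical curves. The
meaningful outputs are therefore the fitted *curve* and the stiffness
evaluated on it, not the raw parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DomainError, ParameterError
from .mechanics import (
    FourFiberParams,
    VesselGeometry,
    _circ_stress_dlth,
    circ_stress,
    deformed_geometry,
    solve_stretch,
)
from .units import mmhg_to_kpa

__all__ = [
    "FitResult",
    "StiffnessResult",
    "stress_stretch_curve",
    "fit_4ff",
    "linearized_stiffness",
    "DEFAULT_BOUNDS",
    "DEFAULT_STIFFNESS_PRESSURES",
]

DEFAULT_STIFFNESS_PRESSURES = (20.0, 90.0, 120.0)

# (lower, upper) bounds: moduli c, c1 in kPa; exponents c2 dimensionless
DEFAULT_BOUNDS = {
    "c": (1e-3, 1e3),
    "c1": (1e-3, 1e3),
    "c2": (1e-3, 50.0),
}

_FIT_FIELDS = ("c", "c1_axial", "c1_circ", "c1_diag",
               "c2_axial", "c2_circ", "c2_diag")


@dataclass
class FitResult:
    """Outcome of a multistart 4FF fit."""

    params: FourFiberParams
    residual_rms: float      # um, RMS outer-diameter residual
    cost: float              # 0.5 * sum of squared residuals (um^2)
    n_iterations: int
    converged: bool
    multistart_best_of: int
    seed: int


@dataclass(frozen=True)
class StiffnessResult:
    """Linearized material stiffness at one loaded pressure state."""

    pressure: float              # mmHg
    stiffness: float             # kPa (d sigma / d lambda at fixed lz)
    stretch_at_pressure: float
    stress_at_pressure: float    # kPa


def stress_stretch_curve(pressures, outer_diameters,
                         geom: VesselGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Experimental circumferential stress-stretch pairs from (P, OD) data.

    The measured outer diameter is inverted through the incompressible
    kinematics to the mid-wall stretch, and the stress is the Laplace
    estimate ``sigma = P a / h`` (kPa) from the *measured* state — no
    constitutive assumption enters.
    """
    P = np.asarray(pressures, dtype=float)
    OD = np.asarray(outer_diameters, dtype=float)
    if P.shape != OD.shape:
        raise ParameterError("pressures and outer_diameters must match")
    if np.any(OD <= 0):
        raise ParameterError("outer diameters must be > 0")
    A, lz = geom.inner_radius, geom.axial_stretch
    B, Rm = geom.outer_radius, geom.midwall_radius
    wall = (B * B - A * A) / lz    # conserved b^2 - a^2
    b = OD / 2.0
    a_sq = b * b - wall
    if np.any(a_sq <= 0):
        bad = np.nonzero(a_sq <= 0)[0][0]
        raise DomainError(
            f"outer diameter {OD[bad]:.4g} um at point {bad} below the "
            "unloaded-compatible minimum"
        )
    a = np.sqrt(a_sq)
    h = b - a
    rm_sq = a_sq + (Rm * Rm - A * A) / lz
    lth = np.sqrt(rm_sq) / Rm
    sigma = mmhg_to_kpa(P) * a / h
    return lth, sigma


def _params_to_vector(p: FourFiberParams) -> np.ndarray:
    return np.log10([getattr(p, f) for f in _FIT_FIELDS])


def _vector_to_params(x: np.ndarray, alpha0_deg: float) -> FourFiberParams:
    vals = 10.0 ** np.asarray(x, dtype=float)
    return FourFiberParams(*vals, alpha0_deg=alpha0_deg)


def _predict_od(params: FourFiberParams, geom: VesselGeometry,
                pressures: np.ndarray, lth_max: float) -> np.ndarray:
    """Model OD at each pressure; pressures beyond the curve's reach map to
    the diameter at the stretch bracket edge (a smooth penalty that keeps
    the optimizer's residuals finite)."""
    od = np.empty(pressures.size)
    for i, P in enumerate(pressures):
        try:
            lth = solve_stretch(params, geom, float(P), lth_max=lth_max)
        except ConvergenceError:
            lth = lth_max
        a, h = deformed_geometry(geom, lth)
        od[i] = 2.0 * (a + h)
    return od


def fit_4ff(pressures, outer_diameters, geom: VesselGeometry,
            init: FourFiberParams | None = None,
            bounds: dict | None = None,
            n_multistart: int = 8, seed: int = 0,
            perturbation_decades: float = 0.5,
            lth_max: float = 2.5) -> FitResult:
    """Fit 4FF parameters to a static pressure-outer-diameter sweep.

    Least squares on the OD residuals (um) in log-parameter space, with the
    diagonal fiber pair sharing one (c1, c2) and the fiber angle fixed at
    ``init.alpha0_deg``. ``n_multistart`` seeded log-uniform perturbations
    of the initial guess (within ``perturbation_decades`` decades) are run
    and the best kept.

    Requires >= 6 points spanning >= 50 mmHg.
    """
    P = np.asarray(pressures, dtype=float)
    OD = np.asarray(outer_diameters, dtype=float)
    if P.size < 6:
        raise ParameterError("need at least 6 data points")
    if np.ptp(P) < 50.0:
        raise ParameterError("data must span at least 50 mmHg")
    if init is None:
        init = FourFiberParams(10.0, 5.0, 5.0, 5.0, 1.0, 1.0, 1.0)
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.log10([b["c"][0]] + [b["c1"][0]] * 3 + [b["c2"][0]] * 3)
    hi = np.log10([b["c"][1]] + [b["c1"][1]] * 3 + [b["c2"][1]] * 3)

    def residuals(x):
        p = _vector_to_params(x, init.alpha0_deg)
        return _predict_od(p, geom, P, lth_max) - OD

    x0 = np.clip(_params_to_vector(init), lo, hi)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_multistart - 1)):
        starts.append(np.clip(
            x0 + rng.uniform(-perturbation_decades, perturbation_decades, x0.size),
            lo, hi,
        ))

    best = None
    n_ok = 0
    for xs in starts:
        try:
            res = least_squares(residuals, xs, bounds=(lo, hi),
                                ftol=1e-8, xtol=1e-10, gtol=1e-10)
        except Exception:
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError(
            f"all {len(starts)} optimisation starts failed"
        )
    params = _vector_to_params(best.x, init.alpha0_deg)
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return FitResult(
        params=params, residual_rms=rms, cost=float(best.cost),
        n_iterations=int(best.nfev), converged=bool(best.status > 0),
        multistart_best_of=n_ok, seed=seed,
    )


def linearized_stiffness(params: FourFiberParams, geom: VesselGeometry,
                         pressures=DEFAULT_STIFFNESS_PRESSURES,
                         lth_max: float = 2.5) -> list[StiffnessResult]:
    """Incremental material stiffness at loaded equilibrium states.

    For each pressure the equilibrium stretch is solved and the stiffness
    ``d(sigma_theta)/d(lambda_theta)`` evaluated analytically at that state
    with the axial stretch held fixed. Unreachable pressures yield a NaN
    entry rather than aborting the rest.
    """
    out = []
    for P in np.asarray(pressures, dtype=float):
        try:
            lth = solve_stretch(params, geom, float(P), lth_max=lth_max)
        except ConvergenceError:
            out.append(StiffnessResult(pressure=float(P), stiffness=np.nan,
                                       stretch_at_pressure=np.nan,
                                       stress_at_pressure=np.nan))
            continue
        out.append(StiffnessResult(
            pressure=float(P),
            stiffness=_circ_stress_dlth(params, lth, geom.axial_stretch),
            stretch_at_pressure=float(lth),
            stress_at_pressure=circ_stress(params, lth, geom.axial_stretch),
        ))
    return out
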