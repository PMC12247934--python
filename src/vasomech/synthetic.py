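"""Synthetic myography experiments from the digital vessel.

Everything the analysis chain consumes can be generated here with known
ground truth: pulsatile and stepwise recordings driven through the forward
constitutive model, burst experiments with a stress-based rupture criterion,
pharmacological dose-response series, and rendered grayscale frames of a
cannulated vessel for the tracking stage.

Noise model: measurement noise is Gaussian, independent across samples and
channels, homoscedastic (no temporal autocorrelation). With all noise SDs at
zero the whole chain is deterministic and seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ParameterError
from .mechanics import (
    FourFiberParams,
    VesselGeometry,
    circ_stress,
    deformed_geometry,
    solve_stretch,
)
from .waveform import PressureTrace, StepSpec, generate_step_protocol

__all__ = [
    "NoiseSpec",
    "MyographyRecording",
    "DoseResponse",
    "simulate_recording",
    "simulate_burst_experiment",
    "simulate_dose_response",
    "render_vessel_frame",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise levels (SDs) for a simulated recording."""

    diameter_sd: float = 0.0   # um, applied independently to OD and ID
    pressure_sd: float = 0.0   # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_sd < 0 or self.pressure_sd < 0:
            raise ParameterError("noise SDs must be >= 0")


NO_NOISE = NoiseSpec(0.0, 0.0, 0)


@dataclass
class MyographyRecording:
    """Paired pressure and diameter traces on one uniform time grid.

    ``rupture_time`` is ``None`` unless the simulated vessel burst; after
    rupture the recorded pressure is 0 and diameters are NaN (absent).
    """

    time: np.ndarray              # s
    pressure: np.ndarray          # mmHg, recorded (noisy) trace
    outer_diameter: np.ndarray    # um
    inner_diameter: np.ndarray    # um
    condition_label: str = ""
    rupture_time: float | None = None
    seed: int = 0
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.outer_diameter = np.asarray(self.outer_diameter, dtype=float)
        self.inner_diameter = np.asarray(self.inner_diameter, dtype=float)
        n = self.time.size
        for name in ("pressure", "outer_diameter", "inner_diameter"):
            if getattr(self, name).size != n:
                raise ParameterError(f"{name} must share the time grid ({n} samples)")
        if self.sample_rate is None and n >= 2:
            self.sample_rate = float(1.0 / (self.time[1] - self.time[0]))


@dataclass(frozen=True)
class DoseResponse:
    """Diameter response to cumulative doses of a vasoactive agent."""

    concentrations: np.ndarray    # mol/L, ascending
    diameters: np.ndarray         # um
    baseline_diameter: float      # um, pre-dose
    agent_type: str               # "constrictor" | "dilator"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "diameters", d)
        if c.size < 2 or np.any(np.diff(c) <= 0) or np.any(c <= 0):
            raise ParameterError("need >= 2 strictly ascending positive concentrations")
        if d.shape != c.shape:
            raise ParameterError("diameters must match concentrations")
        if self.agent_type not in ("constrictor", "dilator"):
            raise ParameterError("agent_type must be 'constrictor' or 'dilator'")


def _diameters_for_pressures(params: FourFiberParams, geom: VesselGeometry,
                             pressures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless OD/ID (um) at each drive pressure, via the forward model.

    Repeated pressure values (staircase holds, repeated pulse shapes) are
    solved once and broadcast.
    """
    uniq, inv = np.unique(np.round(pressures, 9), return_inverse=True)
    od_u = np.empty_like(uniq)
    id_u = np.empty_like(uniq)
    for i, P in enumerate(uniq):
        try:
            lth = solve_stretch(params, geom, float(P))
        except ConvergenceError as exc:
            first = int(np.nonzero(inv == i)[0][0])
            raise ConvergenceError(
                f"drive pressure {P:.4g} mmHg at sample {first} "
                f"outside the model's range: {exc}"
            ) from exc
        a, h = deformed_geometry(geom, lth)
        od_u[i] = 2.0 * (a + h)
        id_u[i] = 2.0 * a
    return od_u[inv], id_u[inv]


def simulate_recording(params: FourFiberParams, geom: VesselGeometry,
                       drive: PressureTrace, noise: NoiseSpec = NO_NOISE,
                       condition_label: str = "") -> MyographyRecording:
    """Record the digital vessel's diameter response to a pressure drive.

    Per sample the quasi-static equilibrium diameter at the driving pressure
    is computed from the forward model, then independent Gaussian noise is
    added to the recorded OD, ID and pressure channels. Deterministic given
    the seed; with zero SDs the output is seed-independent.
    """
    od, idm = _diameters_for_pressures(params, geom, drive.pressure)
    p = drive.pressure.astype(float).copy()
    if noise.diameter_sd > 0 or noise.pressure_sd > 0:
        rng = np.random.default_rng(noise.seed)
        od = od + rng.normal(0.0, noise.diameter_sd, od.size)
        idm = idm + rng.normal(0.0, noise.diameter_sd, idm.size)
        p = np.clip(p + rng.normal(0.0, noise.pressure_sd, p.size), 0.0, None)
    return MyographyRecording(
        time=drive.time.copy(), pressure=p, outer_diameter=od,
        inner_diameter=idm, condition_label=condition_label, seed=noise.seed,
    )


def simulate_burst_experiment(params: FourFiberParams, geom: VesselGeometry,
                              step: StepSpec, failure_stress: float,
                              noise: NoiseSpec = NO_NOISE,
                              condition_label: str = "") -> MyographyRecording:
    """Stepwise inflation until rupture or protocol completion.

    The staircase drive is applied sample by sample; at the first sample
    whose noiseless wall stress reaches ``failure_stress`` (kPa) the wall is
    deemed to have failed, and the rupture manifests at the *next* sample:
    recorded pressure collapses to 0 and diameters become NaN from there on.
    The triggering hold level is therefore momentarily recorded, so the burst
    pressure recovered by the analysis is that level's pressure. If the
    protocol completes without reaching the failure stress, ``rupture_time``
    stays ``None``.
    """
    if not failure_stress > 0:
        raise ParameterError("failure_stress must be > 0")
    drive = generate_step_protocol(step)
    # Noiseless stress per unique level; rupture index from first exceedance.
    uniq, inv = np.unique(drive.pressure, return_inverse=True)
    stress_u = np.empty_like(uniq)
    for i, P in enumerate(uniq):
        lth = solve_stretch(params, geom, float(P))
        stress_u[i] = circ_stress(params, lth, geom.axial_stretch)
    stress = stress_u[inv]
    exceed = np.nonzero(stress >= failure_stress)[0]
    rec = simulate_recording(params, geom, drive, noise,
                             condition_label=condition_label)
    if exceed.size and exceed[0] + 1 < drive.time.size:
        k = int(exceed[0]) + 1
        rec.rupture_time = float(drive.time[k])
        rec.pressure[k:] = 0.0
        rec.outer_diameter[k:] = np.nan
        rec.inner_diameter[k:] = np.nan
    return rec


def simulate_dose_response(baseline_diameter: float, emax_fraction: float,
                           ec50: float, hill: float, concentrations,
                           agent_type: str, noise_sd: float = 0.0,
                           seed: int = 0) -> DoseResponse:
    """Hill-curve diameter response to cumulative agonist doses.

    The diameter change at concentration ``c`` is
    ``+/- baseline * emax_fraction * c^h / (c^h + ec50^h)`` — negative for a
    constrictor, positive for a dilator — plus Gaussian noise.
    """
    if not ec50 > 0:
        raise ParameterError("ec50 must be > 0")
    if not 0.0 < emax_fraction < 1.0:
        raise ParameterError("emax_fraction must lie in (0, 1)")
    if not hill > 0:
        raise ParameterError("hill must be > 0")
    if not baseline_diameter > 0:
        raise ParameterError("baseline_diameter must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    sign = -1.0 if agent_type == "constrictor" else +1.0
    ch = conc ** hill
    delta = sign * baseline_diameter * emax_fraction * ch / (ch + ec50 ** hill)
    d = baseline_diameter + delta
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, d.size)
    return DoseResponse(concentrations=conc, diameters=d,
                        baseline_diameter=baseline_diameter,
                        agent_type=agent_type)


def render_vessel_frame(outer_diameter: float, inner_diameter: float,
                        um_per_px: float, image_size: tuple[int, int] = (256, 320),
                        wall_intensity: float = 0.2,
                        background_intensity: float = 0.9,
                        noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render one grayscale frame of a horizontal cannulated vessel.

    The vessel is centered vertically: two dark wall bands of width
    ``(OD - ID) / 2`` separated by a lumen band of width ``ID`` at background
    brightness, on a bright background. Intensities are floats in [0, 1]
    after clipping; additive Gaussian pixel noise is seeded.
    """
    if not outer_diameter > inner_diameter > 0:
        raise ParameterError("need outer_diameter > inner_diameter > 0")
    if not um_per_px > 0:
        raise ParameterError("um_per_px must be > 0")
    h, w = image_size
    od_px = outer_diameter / um_per_px
    id_px = inner_diameter / um_per_px
    if od_px >= h:
        raise ParameterError(
            f"vessel ({od_px:.0f} px) does not fit the frame height ({h} px)"
        )
    img = np.full((h, w), background_intensity, dtype=float)
    cy = h / 2.0
    rows = np.arange(h)
    # A row belongs to the vessel if its center lies inside the band.
    dist = np.abs(rows + 0.5 - cy)
    wall = (dist <= od_px / 2.0) & (dist > id_px / 2.0)
    img[wall, :] = wall_intensity
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)
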