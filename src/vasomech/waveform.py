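"""Pressure protocols applied to a cannulated vessel.

Two drive shapes are produced: a pulsatile waveform mimicking an occlusion-arm
pulse generator (smoothed rectangular pulses riding on a diastolic baseline,
the digital twin of a cyclic 80/120 mmHg drive), and a stepwise staircase
mimicking a click-quantized manual syringe ratchet (constant holds, one fixed
pressure increment per click, up to a burst/stop ceiling).

Conventions
-----------
* Traces start at ``t = 0`` on a uniform grid of ``n = round(duration *
  sample_rate)`` samples covering ``[0, duration)``.
* A pulsatile cycle begins at the diastolic baseline; the systolic window
  occupies the *end* of each cycle, so a trailing partial cycle never contains
  a complete pulse and the number of complete pulses in a record of length
  ``T`` is ``floor(T * beat_rate / 60)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "PulseSpec",
    "StepSpec",
    "PressureTrace",
    "generate_pulsatile_pressure",
    "generate_step_protocol",
]


@dataclass(frozen=True)
class PulseSpec:
    """Setpoints for a pulsatile pressure drive.

    Parameters
    ----------
    diastolic_pressure, systolic_pressure : float
        Baseline and peak pressure in mmHg.
    beat_rate : float
        Pulses per minute.
    duration : float
        Record length in seconds.
    sample_rate : float
        Samples per second; must resolve the pulse (>= 10 samples per beat).
    systolic_fraction : float
        Fraction of each cycle spent above baseline, in (0, 1).
    rise_fraction : float
        Fraction of the systolic window used by the raised-cosine rise and
        fall combined (Tukey taper parameter); 1.0 gives a pure cosine bump,
        smaller values a flatter top.
    """

    diastolic_pressure: float
    systolic_pressure: float
    beat_rate: float
    duration: float
    sample_rate: float
    systolic_fraction: float = 0.35
    rise_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.diastolic_pressure >= 0:
            raise ParameterError("diastolic_pressure must be >= 0")
        if not self.systolic_pressure > self.diastolic_pressure:
            raise ParameterError(
                "systolic_pressure must exceed diastolic_pressure "
                f"({self.systolic_pressure} <= {self.diastolic_pressure})"
            )
        if not self.beat_rate > 0:
            raise ParameterError("beat_rate must be > 0")
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")
        if not self.sample_rate >= 10.0 * self.beat_rate / 60.0:
            raise ParameterError(
                "sample_rate must be at least 10 x beat_rate/60 to resolve pulses"
            )
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ParameterError("systolic_fraction must lie in (0, 1)")
        if not 0.0 < self.rise_fraction <= 1.0:
            raise ParameterError("rise_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class StepSpec:
    """Setpoints for a click-quantized stepwise pressure ramp."""

    start_pressure: float
    increment: float
    hold_time: float
    max_pressure: float
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        if not self.increment > 0:
            raise ParameterError("increment must be > 0")
        if not self.hold_time > 0:
            raise ParameterError("hold_time must be > 0")
        if not self.max_pressure > self.start_pressure:
            raise ParameterError("max_pressure must exceed start_pressure")
        if not self.start_pressure >= 0:
            raise ParameterError("start_pressure must be >= 0")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be > 0")


@dataclass(frozen=True)
class PressureTrace:
    """Uniformly sampled pressure time series (time in s, pressure in mmHg)."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)
        if t.ndim != 1 or p.shape != t.shape:
            raise ParameterError("time and pressure must be 1-D and equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ParameterError("time must increase with a constant step")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ParameterError("pressures must be finite and >= 0")

    @property
    def sample_rate(self) -> float:
        if self.time.size < 2:
            raise ParameterError("sample_rate undefined for a single sample")
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time.size / self.sample_rate)


def _pulse_profile(phase: np.ndarray, spec: PulseSpec) -> np.ndarray:
    """Normalized pulse height in [0, 1] as a function of cycle phase [0, 1).

    The systolic window occupies ``[1 - systolic_fraction, 1)`` of the cycle
    (cycle starts at baseline); within it the shape is a Tukey (tapered
    cosine) window: raised-cosine rise/fall with an optional flat top.
    """
    sf = spec.systolic_fraction
    onset = 1.0 - sf
    out = np.zeros_like(phase)
    inside = phase >= onset
    # Normalized position in the systolic window, u in [0, 1).
    u = (phase[inside] - onset) / sf
    alpha = spec.rise_fraction
    v = np.ones_like(u)
    rising = u < alpha / 2.0
    falling = u > 1.0 - alpha / 2.0
    v[rising] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[rising] / alpha))
    v[falling] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (1.0 - u[falling]) / alpha))
    out[inside] = v
    return out


def generate_pulsatile_pressure(spec: PulseSpec) -> PressureTrace:
    """Generate a periodic smoothed-rectangular pulsatile pressure trace.

    The trace is periodic with period ``60 / beat_rate`` s, ranges from the
    diastolic to the systolic setpoint (to within one sample of the grid), and
    carries one local maximum per complete cycle. The first cycle begins at
    ``t = 0`` on the diastolic baseline.
    """
    n = int(round(spec.duration * spec.sample_rate))
    if n < 2:
        raise ParameterError("duration x sample_rate must give at least 2 samples")
    t = np.arange(n) / spec.sample_rate
    period = 60.0 / spec.beat_rate
    phase = (t / period) % 1.0
    amp = spec.systolic_pressure - spec.diastolic_pressure
    p = spec.diastolic_pressure + amp * _pulse_profile(phase, spec)
    return PressureTrace(time=t, pressure=p)


def generate_step_protocol(spec: StepSpec) -> PressureTrace:
    """Generate a click-quantized staircase pressure trace.

    Level ``k`` holds ``start_pressure + k * increment`` for ``hold_time``
    seconds; the staircase ends with the first level at or above
    ``max_pressure``. The step function is right-continuous: each hold starts
    exactly at its level-change time.
    """
    n_clicks = int(np.ceil((spec.max_pressure - spec.start_pressure) / spec.increment))
    levels = spec.start_pressure + spec.increment * np.arange(n_clicks + 1)
    samples_per_level = int(round(spec.hold_time * spec.sample_rate))
    if samples_per_level < 1:
        raise ParameterError("hold_time x sample_rate must give at least 1 sample")
    p = np.repeat(levels, samples_per_level)
    t = np.arange(p.size) / spec.sample_rate
    return PressureTrace(time=t, pressure=p)


def step_levels(spec: StepSpec) -> np.ndarray:
    """The sequence of hold pressures of a staircase protocol (mmHg)."""
    n_clicks = int(np.ceil((spec.max_pressure - spec.start_pressure) / spec.increment))
    return spec.start_pressure + spec.increment * np.arange(n_clicks + 1)
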