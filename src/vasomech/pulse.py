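"""Trace analysis: pulses, frequency, compliance, burst and vasoreactivity.

These operations reproduce the standard post-processing chain of a
pulsatile-pressure myography experiment:

* peak filtering of the diameter trace and per-pulse diameter change,
* FFT-based pulse-frequency estimation with a fundamental-frequency rule,
* dynamic compliance ``Dc = ((Dmax - Dmin) / Dmin) / (Pmax - Pmin)`` in
  1/mmHg, computed from the outer diameter,
* burst pressure of a stepwise inflation (maximum recorded pressure before
  rupture),
* plateau pressure of a static pressure-diameter sweep,
* min-max percentage normalization of constriction / relaxation
  dose-response series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError, ParameterError
from .synthetic import DoseResponse, MyographyRecording

__all__ = [
    "PulseSummary",
    "ComplianceResult",
    "BurstResult",
    "detect_pulses",
    "pulse_frequency",
    "dynamic_compliance",
    "recording_compliance",
    "burst_pressure",
    "plateau_pressure",
    "percent_constriction",
    "percent_relaxation",
]


@dataclass
class PulseSummary:
    """Detected pulses of a diameter (or pressure) trace.

    ``baseline`` is a single global baseline: the median of the inter-peak
    minima. Per-pulse deltas are peak height minus that baseline.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    baseline: float
    per_pulse_delta: np.ndarray
    mean_delta: float
    sd_delta: float

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass
class ComplianceResult:
    """Per-pulse dynamic compliance of a recording (1/mmHg)."""

    per_pulse_dc: np.ndarray
    mean: float
    sd: float
    p_max: float
    p_min: float
    d_min: float

    @property
    def n_pulses(self) -> int:
        return int(self.per_pulse_dc.size)


@dataclass(frozen=True)
class BurstResult:
    """Outcome of a stepwise inflation to failure.

    ``ruptured`` distinguishes a true burst from a protocol that completed
    without rupture; ``pressure`` is the burst pressure in the former case
    and the maximum pressure reached in the latter.
    """

    pressure: float
    ruptured: bool


def _empty_summary() -> PulseSummary:
    return PulseSummary(
        peak_times=np.empty(0), peak_values=np.empty(0), baseline=np.nan,
        per_pulse_delta=np.empty(0), mean_delta=np.nan, sd_delta=np.nan,
    )


def default_prominence(values: np.ndarray) -> float:
    """Default peak prominence from the trace's own statistics.

    Based on 3 x scaled MAD of the median-subtracted trace, floored at 10%
    of the peak-to-peak range (a clean pulse train sitting mostly at
    baseline has near-zero MAD) and capped at 50% of it (a pure sinusoid
    spends so much time away from its median that 3 x MAD exceeds the peak
    prominence itself)."""
    v = values[np.isfinite(values)]
    if v.size == 0 or np.ptp(v) == 0:
        return np.inf
    mad = np.median(np.abs(v - np.median(v)))
    ptp = np.ptp(v)
    return float(min(max(3.0 * 1.4826 * mad, 0.1 * ptp), 0.5 * ptp))


def detect_pulses(time: np.ndarray, values: np.ndarray,
                  min_prominence: float | None = None,
                  min_separation: float = 0.3) -> PulseSummary:
    """Detect complete pulses in a uniformly sampled trace.

    Peaks are local maxima with prominence >= ``min_prominence`` (default:
    :func:`default_prominence`) separated by >= ``min_separation`` s (default
    0.3 s, supporting rates up to 200/min). Only *complete* pulses are
    counted: each peak must descend toward a trough on both sides within the
    record (the flanking segment must reach at least half the prominence
    below the peak), so pulses truncated by the record edges are excluded.

    An all-flat or peak-free trace yields an empty summary, not an error.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ParameterError("time and values must have equal length")
    if t.size < 3:
        raise ParameterError("need at least 3 samples")
    if not min_separation > 0:
        raise ParameterError("min_separation must be > 0")
    finite = np.isfinite(v)
    if not finite.all():
        # analyse the finite prefix (post-rupture tails are NaN)
        stop = int(np.nonzero(~finite)[0][0])
        t, v = t[:stop], v[:stop]
        if t.size < 3:
            return _empty_summary()
    if np.ptp(v) == 0:
        return _empty_summary()
    prom = default_prominence(v) if min_prominence is None else float(min_prominence)
    dt = t[1] - t[0]
    distance = max(1, int(round(min_separation / dt)))
    idx, props = find_peaks(v, prominence=prom, distance=distance)
    if idx.size == 0:
        return _empty_summary()

    # completeness: both flanks must drop at least prom/2 below the peak
    keep = []
    bounds = np.concatenate(([0], idx, [v.size - 1]))
    for j, i in enumerate(idx):
        left = v[bounds[j]: i + 1]
        right = v[i: bounds[j + 2] + 1]
        if left.min() <= v[i] - 0.5 * prom and right.min() <= v[i] - 0.5 * prom:
            keep.append(j)
    idx = idx[keep]
    if idx.size == 0:
        return _empty_summary()

    # global baseline: median of inter-peak minima (troughs between peaks,
    # plus the flanking segments)
    troughs = []
    bounds = np.concatenate(([0], idx, [v.size - 1]))
    for j in range(len(idx) + 1):
        seg = v[bounds[j]: bounds[j + 1] + 1]
        if seg.size:
            troughs.append(seg.min())
    baseline = float(np.median(troughs))
    deltas = v[idx] - baseline
    return PulseSummary(
        peak_times=t[idx], peak_values=v[idx], baseline=baseline,
        per_pulse_delta=deltas, mean_delta=float(deltas.mean()),
        sd_delta=float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
    )


def pulse_frequency(time: np.ndarray, values: np.ndarray,
                    harmonic_tolerance_db: float = 6.0) -> float:
    """Dominant pulse frequency (Hz) of a uniformly sampled trace by FFT.

    The mean-subtracted signal's amplitude spectrum is searched for its
    maximum; among all spectral peaks within ``harmonic_tolerance_db`` of
    that maximum the *lowest-frequency* one is returned (fundamental rule:
    square-ish pulse shapes put strong energy in harmonics). Resolution is
    one FFT bin, 1/duration Hz.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if t.size < 4:
        raise AnalysisError("trace too short for a frequency estimate")
    if np.ptp(v) == 0:
        raise AnalysisError("constant signal has no defined pulse frequency")
    dt = t[1] - t[0]
    x = v - v.mean()
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=dt)
    mag[0] = 0.0
    peak = mag.max()
    floor = peak * 10.0 ** (-harmonic_tolerance_db / 20.0)
    # local spectral maxima above the -6 dB floor
    cand = [
        k for k in range(1, mag.size - 1)
        if mag[k] >= floor and mag[k] >= mag[k - 1] and mag[k] >= mag[k + 1]
    ]
    if not cand:
        cand = [int(np.argmax(mag))]
    return float(freqs[min(cand)])


def dynamic_compliance(d_max: float, d_min: float,
                       p_max: float, p_min: float) -> float:
    """Dynamic compliance Dc (1/mmHg) of one pulse.

    ``Dc = ((d_max - d_min) / d_min) / (p_max - p_min)`` — the fractional
    diameter excursion per unit pulse pressure. Scale-invariant in the
    diameters.
    """
    if not d_min > 0:
        raise ParameterError("d_min must be > 0")
    if not p_max > p_min:
        raise ParameterError("p_max must exceed p_min")
    return ((d_max - d_min) / d_min) / (p_max - p_min)


def recording_compliance(rec: MyographyRecording,
                         min_prominence: float | None = None,
                         min_separation: float = 0.3) -> ComplianceResult:
    """Per-pulse dynamic compliance of a pulsatile recording.

    Pulses are detected on the *outer diameter*; the pulse-pressure pair
    (Pmax, Pmin) is matched from the pressure trace by the same peak
    detector and summarized as the median peak pressure and the pressure
    baseline. One Dc per diameter pulse, using the global diameter baseline.
    """
    dsum = detect_pulses(rec.time, rec.outer_diameter,
                         min_prominence=min_prominence,
                         min_separation=min_separation)
    psum = detect_pulses(rec.time, rec.pressure,
                         min_separation=min_separation)
    if dsum.n_peaks == 0 or psum.n_peaks == 0:
        return ComplianceResult(per_pulse_dc=np.empty(0), mean=np.nan,
                                sd=np.nan, p_max=np.nan, p_min=np.nan,
                                d_min=np.nan)
    p_max = float(np.median(psum.peak_values))
    p_min = float(psum.baseline)
    dcs = np.array([
        dynamic_compliance(dmax, dsum.baseline, p_max, p_min)
        for dmax in dsum.peak_values
    ])
    return ComplianceResult(
        per_pulse_dc=dcs, mean=float(dcs.mean()),
        sd=float(dcs.std(ddof=1)) if dcs.size > 1 else 0.0,
        p_max=p_max, p_min=p_min, d_min=float(dsum.baseline),
    )


def burst_pressure(rec: MyographyRecording) -> BurstResult:
    """Burst pressure of a stepwise inflation recording.

    If the recording contains a rupture event, the burst pressure is the
    maximum recorded pressure strictly before the rupture time. Otherwise
    the protocol completed intact and the maximum pressure reached is
    reported with ``ruptured=False``.
    """
    if rec.time.size == 0:
        raise AnalysisError("empty recording")
    if rec.rupture_time is not None:
        before = rec.time < rec.rupture_time
        if not before.any():
            raise AnalysisError("rupture precedes all samples")
        return BurstResult(pressure=float(np.max(rec.pressure[before])),
                           ruptured=True)
    return BurstResult(pressure=float(np.max(rec.pressure)), ruptured=False)


def plateau_pressure(pressures: np.ndarray, outer_diameters: np.ndarray,
                     slope_fraction: float = 0.1) -> float | None:
    """Pressure at which a pressure-diameter sweep flattens out.

    The local slope dOD/dP (central differences) is compared with its
    maximum over the sweep; the plateau is the lowest pressure from which
    the slope stays below ``slope_fraction`` times that maximum for all
    higher pressures. Returns ``None`` if the curve never plateaus (or is
    degenerate / flat, where no slope scale exists).
    """
    P = np.asarray(pressures, dtype=float)
    OD = np.asarray(outer_diameters, dtype=float)
    if P.size < 4:
        raise ParameterError("need at least 4 points")
    if np.any(np.diff(P) <= 0):
        raise ParameterError("pressures must be strictly ascending")
    if not 0.0 < slope_fraction < 1.0:
        raise ParameterError("slope_fraction must lie in (0, 1)")
    slope = np.gradient(OD, P)
    smax = slope.max()
    if smax <= 0:
        return None
    below = slope < slope_fraction * smax
    # lowest index from which 'below' holds through the end
    idx = None
    run = True
    for i in range(P.size - 1, -1, -1):
        run = run and below[i]
        if run:
            idx = i
        else:
            break
    if idx is None or idx == 0:
        # idx == 0 would mean the whole curve is "plateau" — no rise at all
        return None if idx is None else float(P[0])
    return float(P[idx])


def percent_constriction(dr: DoseResponse) -> np.ndarray:
    """Min-max normalized constriction percentages.

    100% is the most-constricted (smallest) diameter observed in the series
    and 0% the least; shift-invariant in the diameters.
    """
    if dr.agent_type != "constrictor":
        raise ParameterError("percent_constriction requires a constrictor series")
    d = dr.diameters
    d_ref, d_min = d.max(), d.min()
    if d_ref == d_min:
        raise AnalysisError("all diameters equal: normalization undefined")
    return 100.0 * (d_ref - d) / (d_ref - d_min)


def percent_relaxation(dr: DoseResponse) -> np.ndarray:
    """Relaxation percentages relative to the pre-dose diameter.

    0% is the starting (first) diameter and 100% the largest diameter
    reached in the series.
    """
    if dr.agent_type != "dilator":
        raise ParameterError("percent_relaxation requires a dilator series")
    d = dr.diameters
    d_start, d_largest = d[0], d.max()
    if d_largest == d_start:
        raise AnalysisError("no dilation beyond the starting diameter")
    return 100.0 * (d - d_start) / (d_largest - d_start)
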