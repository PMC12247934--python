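"""Recording table dialect and run configuration.

Recordings travel as delimited text with a fixed header row::

    time_s,pressure_in_mmHg,pressure_out_mmHg,outer_diameter_um,inner_diameter_um

preceded by ``# key=value`` comment lines carrying metadata (condition,
seed, sample_rate_hz, rupture_time_s). Missing values (e.g. diameters after
rupture) are empty fields. Two pressure columns mirror the dual in-line
sensor layout of a myography rig; the analysis consumes their mean by
default. Numeric fields round-trip at 6 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ParseError
from .synthetic import MyographyRecording

__all__ = ["COLUMNS", "read_recording", "write_recording",
           "load_config", "DEFAULT_CONFIG"]

COLUMNS = ("time_s", "pressure_in_mmHg", "pressure_out_mmHg",
           "outer_diameter_um", "inner_diameter_um")


def _fmt(x: float) -> str:
    return "" if not np.isfinite(x) else f"{x:.6g}"


def write_recording(rec: MyographyRecording, path) -> None:
    """Serialize a recording to the table dialect (lossless to 6 s.d.)."""
    path = Path(path)
    lines = [f"# condition={rec.condition_label}", f"# seed={rec.seed}"]
    if rec.sample_rate is not None:
        lines.append(f"# sample_rate_hz={rec.sample_rate:.6g}")
    if rec.rupture_time is not None:
        lines.append(f"# rupture_time_s={rec.rupture_time:.6g}")
    lines.append(",".join(COLUMNS))
    for t, p, od, idm in zip(rec.time, rec.pressure,
                             rec.outer_diameter, rec.inner_diameter):
        lines.append(",".join([_fmt(t), _fmt(p), _fmt(p), _fmt(od), _fmt(idm)]))
    path.write_text("\n".join(lines) + "\n")


def read_recording(path) -> MyographyRecording:
    """Parse a recording table; metadata and missing values preserved.

    The recorded pressure is the mean of the inlet and outlet columns
    (they are identical for simulated recordings).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = None
    data_start = 0
    raw = path.read_text().splitlines()
    for i, line in enumerate(raw):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        header_line = line.strip()
        data_start = i + 1
        break
    if header_line is None:
        raise ParseError(f"{path}: no header row found")
    if tuple(header_line.split(",")) != COLUMNS:
        raise ParseError(
            f"{path}: malformed header {header_line!r}; expected "
            + ",".join(COLUMNS)
        )
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(raw[data_start:])),
            names=COLUMNS, dtype=float, skip_blank_lines=True,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field ({exc})") from exc
    t = df["time_s"].to_numpy()
    if np.any(~np.isfinite(t)):
        bad = int(np.nonzero(~np.isfinite(t))[0][0])
        raise ParseError(f"{path}: missing time at line {data_start + bad + 1}")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.nonzero(dt <= 0)[0][0]) + 1
            raise ParseError(
                f"{path}: time not strictly increasing at line "
                f"{data_start + bad + 1}"
            )
    p = np.nanmean(
        np.column_stack([df["pressure_in_mmHg"], df["pressure_out_mmHg"]]),
        axis=1,
    )
    rupture = meta.get("rupture_time_s")
    rate = meta.get("sample_rate_hz")
    return MyographyRecording(
        time=t, pressure=p,
        outer_diameter=df["outer_diameter_um"].to_numpy(),
        inner_diameter=df["inner_diameter_um"].to_numpy(),
        condition_label=meta.get("condition", ""),
        rupture_time=float(rupture) if rupture else None,
        seed=int(meta["seed"]) if "seed" in meta else 0,
        sample_rate=float(rate) if rate else None,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "preset": "compliant",
    "geometry": {"inner_radius_um": 200.0, "thickness_um": 30.0,
                 "axial_stretch": 1.0},
    "noise": {"diameter_sd_um": 0.0, "pressure_sd_mmhg": 0.0},
    "pulse": {"diastolic_mmhg": 80.0, "systolic_mmhg": 120.0,
              "beat_rate_bpm": 65.0, "duration_s": 60.0,
              "sample_rate_hz": 100.0, "systolic_fraction": 0.35},
    "steps": {"start_mmhg": 0.0, "increment_mmhg": 64.37, "hold_s": 20.0,
              "max_mmhg": 500.0, "sample_rate_hz": 10.0},
    "tracking": {"n_scanlines": 15, "smoothing_window": 5,
                 "gradient_threshold": 0.3, "outlier_mad_factor": 3.5},
    "analysis": {"min_separation_s": 0.3},
    "fit": {"n_multistart": 8, "alpha0_deg": 45.0},
}


def _check_keys(given: dict, reference: dict, prefix: str = "") -> None:
    for k, v in given.items():
        if k not in reference:
            raise ParameterError(f"unknown config key {prefix + k!r}")
        if isinstance(reference[k], dict):
            if not isinstance(v, dict):
                raise ParameterError(f"config key {prefix + k!r} must be a mapping")
            _check_keys(v, reference[k], prefix=f"{prefix}{k}.")


def load_config(path=None) -> dict:
    """Load a YAML run configuration merged over the defaults.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ParameterError("config file must hold a mapping")
    _check_keys(user, DEFAULT_CONFIG)
    for k, v in user.items():
        if isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg
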