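"""Reference measurements of the open-hardware myography rig.

Published bench characterization numbers for the rig the synthetic twin
emulates, kept here so summary statistics about the hardware can be
recomputed rather than hard-coded: per-axis linear travel of the 3-axis
micromanipulator leadscrews (mean over n=10 repeats per axis, mm) and the
per-click pressure increments of the incremental syringe ratchet (mmHg).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MICROMANIPULATOR_FULL_TURN_MM",
    "MICROMANIPULATOR_QUARTER_TURN_MM",
    "RATCHET_INCREMENT_MMHG",
    "mean_axis_travel",
]

#: Mean linear travel per full leadscrew turn, per axis (mm).
MICROMANIPULATOR_FULL_TURN_MM = {"x": 0.985, "y": 0.996, "z": 0.982}

#: Mean linear travel per quarter turn, per axis (mm).
MICROMANIPULATOR_QUARTER_TURN_MM = {"x": 0.247, "y": 0.250, "z": 0.244}

#: Pressure increase per ratchet click by syringe size (mmHg).
RATCHET_INCREMENT_MMHG = {"3mL": 64.37, "1mL": 7.62}


def mean_axis_travel(travel_by_axis: dict[str, float]) -> float:
    """Mean linear travel across the manipulator axes (mm)."""
    return float(np.mean(list(travel_by_axis.values())))
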