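"""Unit conventions.

Pressures cross every public interface in mmHg (the unit myography rigs
display); stresses and moduli are kPa internally. One conversion constant is
defined here so the factor cannot drift between modules.
"""

KPA_PER_MMHG: float = 0.133322
"""1 mmHg expressed in kPa."""


def mmhg_to_kpa(p_mmhg):
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa):
    return p_kpa / KPA_PER_MMHG
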