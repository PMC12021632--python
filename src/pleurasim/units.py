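"""Unit conversions at the package boundary.

Internally everything is kPa / L / s; clinical instruments report mmHg and
cmH2O, so the converters live here and nowhere else.
"""

KPA_PER_MMHG = 0.133322
KPA_PER_CMH2O = 0.0980665


def mmhg_to_kpa(p: float) -> float:
    return p * KPA_PER_MMHG


def kpa_to_mmhg(p: float) -> float:
    return p / KPA_PER_MMHG


def cmh2o_to_kpa(p: float) -> float:
    return p * KPA_PER_CMH2O


def kpa_to_cmh2o(p: float) -> float:
    return p / KPA_PER_CMH2O
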