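"""Unit conventions and conversion constants.

Geometry lives in millimetres, flows in mL/s, lesion pressure-flow
coefficients in mmHg and mL/s; everything is converted to SI at the solver
boundary and back when results are reported.
"""

MM = 1e-3               # mm -> m
ML_S = 1e-6             # mL/s -> m^3/s
MMHG = 133.322          # mmHg -> Pa
WH = 3600.0             # Wh -> J at 1 W


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG
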