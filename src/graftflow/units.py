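"""Unit conversion constants.

All internal computation is SI (m, s, kg, Pa). User-facing quantities follow
clinical convention: flows in L/min, pressures in mmHg, areas in mm², TKE in mJ.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

LPM_TO_M3S = 1.0 / 60000.0
M3S_TO_LPM = 60000.0

MM2_TO_M2 = 1e-6
M2_TO_MM2 = 1e6

MM_TO_M = 1e-3
M_TO_MM = 1e3

J_TO_MJ = 1e3


def mmhg(pa: float) -> float:
    """Pascals to millimetres of mercury."""
    return pa * PA_TO_MMHG


def pa(mmhg_value: float) -> float:
    """Millimetres of mercury to pascals."""
    return mmhg_value * MMHG_TO_PA


def m3s(lpm: float) -> float:
    """Litres per minute to cubic metres per second."""
    return lpm * LPM_TO_M3S
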