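"""Unit conventions and converters.

All solver-internal quantities are SI (m, s, kg, Pa, m^3/s).  Geometry
I/O (skeletons, centerlines, meshes) is in millimetres; flow rates are
reported in ml/s and pressures in mmHg at the user-facing surface.
"""

MM = 1e-3               # m per mm
MM2 = 1e-6              # m^2 per mm^2
ML_S = 1e-6             # m^3/s per ml/s
MMHG = 133.322387415    # Pa per mmHg


def mm_to_m(x):
    return x * MM


def m_to_mm(x):
    return x / MM


def mlps_to_m3ps(q):
    return q * ML_S


def m3ps_to_mlps(q):
    return q / ML_S


def mmhg_to_pa(p):
    return p * MMHG


def pa_to_mmhg(p):
    return p / MMHG
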