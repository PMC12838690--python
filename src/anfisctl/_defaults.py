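"""Default input partitions for the 8-input stimulation controller.

Each entry: (name, lo, hi, wrap, [(mf_name, center, width), ...]).
Bearing-error centers/widths are stored on the degree scale (the published
initialization uses the [-1, 1] normalized scale; multiply by 180).
"""

_B = 180.0  # bearing scale

INPUT_TABLE = (
    ("prox_f", 0.0, 1.0, False, (
        ("PF_Far", 0.15, 0.10),
        ("PF_Medium", 0.40, 0.10),
        ("PF_Near", 0.65, 0.10),
        ("PF_VeryNear", 0.90, 0.10),
    )),
    ("prox_b", 0.0, 1.0, False, (
        ("PB_Far", 0.15, 0.10),
        ("PB_Medium", 0.40, 0.10),
        ("PB_Near", 0.65, 0.10),
        ("PB_VeryNear", 0.90, 0.10),
    )),
    ("vel_lin", 0.0, 1.0, False, (
        ("VL_Stop", 0.05, 0.05),
        ("VL_Slow", 0.30, 0.15),
        ("VL_Medium", 0.60, 0.15),
        ("VL_Fast", 0.90, 0.10),
    )),
    ("vel_ang", -1.0, 1.0, False, (
        ("VA_FastLeft", -0.80, 0.20),
        ("VA_SlowLeft", -0.30, 0.20),
        ("VA_Straight", 0.00, 0.15),
        ("VA_SlowRight", 0.30, 0.20),
        ("VA_FastRight", 0.80, 0.20),
    )),
    ("dist_targ", 0.0, 1.0, False, (
        ("DT_VeryClose", 0.10, 0.10),
        ("DT_Close", 0.30, 0.15),
        ("DT_Medium", 0.60, 0.20),
        ("DT_Far", 0.90, 0.10),
    )),
    ("err_bear", -180.0, 180.0, True, (
        ("EB_HardLeft", -0.80 * _B, 0.20 * _B),
        ("EB_Left", -0.40 * _B, 0.20 * _B),
        ("EB_Ahead", 0.00 * _B, 0.20 * _B),
        ("EB_Right", 0.40 * _B, 0.20 * _B),
        ("EB_HardRight", 0.80 * _B, 0.20 * _B),
    )),
    ("accel_ang", -1.0, 1.0, False, (
        ("AA_Decel", -0.50, 0.25),
        ("AA_Steady", 0.00, 0.20),
        ("AA_Accel", 0.50, 0.25),
    )),
    ("hab_lvl", 0.0, 1.0, False, (
        ("HL_Low", 0.20, 0.15),
        ("HL_Medium", 0.50, 0.15),
        ("HL_High", 0.80, 0.15),
    )),
)

MF_NAMES = {name: tuple(m[0] for m in mfs) for name, _, _, _, mfs in INPUT_TABLE}
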