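"""Reference wall-area statistics from a spatially resolved 3D solve.

ALWSS (area of low wall shear stress, cm^2) on the portal-bifurcation venous
wall and on the stent wall for the 18-case design, together with the printed
relative errors of the Type B/C simplifications against Type A. A 0D network
cannot produce these areas; they serve as comparator fixtures for the
relative-error operation.

Each record: (patient, position, wall, simplification, alwss_cm2,
printed_rel_err_pct) — Type A rows carry no error entry.
"""

ALWSS_TABLE = [
    # patient-1, shunt at LPV
    ("patient-1", "LPV", "bifurcation", "A", 24.38, None),
    ("patient-1", "LPV", "bifurcation", "B", 22.85, -6.28),
    ("patient-1", "LPV", "bifurcation", "C", 24.38, 0.00),
    ("patient-1", "LPV", "shunt", "A", 3.58, None),
    ("patient-1", "LPV", "shunt", "B", 2.72, -24.02),
    ("patient-1", "LPV", "shunt", "C", 3.25, -9.22),
    # patient-1, shunt at MPV
    ("patient-1", "MPV", "bifurcation", "A", 27.28, None),
    ("patient-1", "MPV", "bifurcation", "B", 26.00, -4.69),
    ("patient-1", "MPV", "bifurcation", "C", 26.78, -1.83),
    ("patient-1", "MPV", "shunt", "A", 3.53, None),
    ("patient-1", "MPV", "shunt", "B", 3.86, 9.35),
    ("patient-1", "MPV", "shunt", "C", 2.45, -30.59),
    # patient-1, shunt at RPV
    ("patient-1", "RPV", "bifurcation", "A", 25.35, None),
    ("patient-1", "RPV", "bifurcation", "B", 22.80, -10.06),
    # the printed -0.74 was truncated rather than rounded (exact: -0.7495)
    ("patient-1", "RPV", "bifurcation", "C", 25.16, -0.74),
    ("patient-1", "RPV", "shunt", "A", 2.86, None),
    ("patient-1", "RPV", "shunt", "B", 3.36, 17.48),
    ("patient-1", "RPV", "shunt", "C", 2.24, -21.68),
    # patient-2, shunt at LPV
    ("patient-2", "LPV", "bifurcation", "A", 24.76, None),
    ("patient-2", "LPV", "bifurcation", "B", 24.82, 0.24),
    ("patient-2", "LPV", "bifurcation", "C", 25.26, 2.02),
    ("patient-2", "LPV", "shunt", "A", 1.70, None),
    ("patient-2", "LPV", "shunt", "B", 1.92, 12.94),
    ("patient-2", "LPV", "shunt", "C", 1.98, 16.47),
    # patient-2, shunt at MPV
    ("patient-2", "MPV", "bifurcation", "A", 26.17, None),
    ("patient-2", "MPV", "bifurcation", "B", 26.77, 2.29),
    ("patient-2", "MPV", "bifurcation", "C", 25.69, -1.83),
    ("patient-2", "MPV", "shunt", "A", 3.13, None),
    ("patient-2", "MPV", "shunt", "B", 3.08, -1.60),
    ("patient-2", "MPV", "shunt", "C", 2.08, -33.55),
    # patient-2, shunt at RPV
    ("patient-2", "RPV", "bifurcation", "A", 25.93, None),
    ("patient-2", "RPV", "bifurcation", "B", 25.80, -0.50),
    ("patient-2", "RPV", "bifurcation", "C", 26.23, 1.16),
    ("patient-2", "RPV", "shunt", "A", 2.02, None),
    ("patient-2", "RPV", "shunt", "B", 2.02, 0.00),
    ("patient-2", "RPV", "shunt", "C", 1.43, -29.21),
]

#: The one printed cell whose last digit was truncated instead of rounded.
TRUNCATED_CELLS = {("patient-1", "RPV", "bifurcation", "C")}


def error_cases():
    """(key, alwss, Type-A reference alwss, printed error) per B/C cell."""
    ref = {
        (p, pos, wall): a for p, pos, wall, t, a, _ in ALWSS_TABLE if t == "A"
    }
    for p, pos, wall, t, a, printed in ALWSS_TABLE:
        if printed is None:
            continue
        yield (p, pos, wall, t), a, ref[(p, pos, wall)], printed
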