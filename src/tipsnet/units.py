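"""Unit constants and conversions used throughout the package.

Pressures are carried in pascal internally; clinical quantities (portal
pressure, portal pressure gradient) are printed in mmHg. Vessel diameters are
recorded in millimetres, as clinicians report them, and converted to metres
when a network is built.
"""

#: Pascal per millimetre of mercury (standard value).
MMHG_TO_PA: float = 133.322

#: Metres per millimetre.
MM_TO_M: float = 1e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA


def mm_to_m(x_mm: float) -> float:
    """Convert a length from millimetres to metres."""
    return x_mm * MM_TO_M
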