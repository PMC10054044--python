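"""Unit conversions between bench units (uL/h, um, ms, mL^-1) and SI.

All internal computation is SI; conversion happens once at the API boundary.
"""

from __future__ import annotations

#: m^3/s per uL/h
UL_PER_H = 1e-9 / 3600.0
#: m^-3 per mL^-1
PER_ML = 1e6
#: metres per micrometre
UM = 1e-6
#: seconds per millisecond
MS = 1e-3


def ul_per_h_to_m3s(q: float) -> float:
    """Convert a flow rate in microlitres per hour to m^3/s."""
    return q * UL_PER_H


def m3s_to_ul_per_h(q: float) -> float:
    """Convert a flow rate in m^3/s to microlitres per hour."""
    return q / UL_PER_H


def per_ml_to_per_m3(c: float) -> float:
    """Convert a number concentration in mL^-1 to m^-3."""
    return c * PER_ML


def per_m3_to_per_ml(c: float) -> float:
    """Convert a number concentration in m^-3 to mL^-1."""
    return c / PER_ML
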