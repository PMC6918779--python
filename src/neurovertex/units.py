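"""Nondimensionalisation constants.

Lengths and areas are measured in units of a reference apical cell area of
23 um^2 (so one nondimensional area unit is one "typical" apical cross
section and one length unit is sqrt(23) um ~ 4.8 um).  Time is measured in
units of 460 s, so one biological hour is 3600/460 ~ 7.826 time units and a
13 h cell cycle is ~101.7 time units.
"""

TIME_UNIT_S = 460.0
AREA_UNIT_UM2 = 23.0

#: nondimensional time units per biological hour
PER_HOUR = 3600.0 / TIME_UNIT_S


def hours(h: float) -> float:
    """Convert biological hours to nondimensional time."""
    return h * PER_HOUR


def to_hours(t: float) -> float:
    """Convert nondimensional time to biological hours."""
    return t / PER_HOUR


def per_hour_rate(rate: float) -> float:
    """Convert a per-hour rate (e.g. a differentiation hazard) to a
    per-nondimensional-time rate."""
    return rate / PER_HOUR
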