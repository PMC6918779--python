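"""Cell-cycle state and interkinetic nuclear movement (IKNM).

In a pseudostratified epithelium the nucleus translocates along the
apicobasal axis in synchrony with the cell cycle: basally during G1, basal
in S, returning apically in G2, and apical during mitosis.  The apical
cross-section of the cell tracks this movement, so the 2D model encodes
IKNM as a time-dependent *target* apical area

    A^0(t~) = (1 + g * t~) * f(rho(t~)),

the product of linear volume growth at per-cell rate ``g`` and an
interpolant ``f`` of the apicobasal nuclear position ``rho`` (1 apical, 0
basal), with ``f(0) = 1/2``, ``f(1) = 1``, rising faster as the nucleus
approaches the apical surface.  The default interpolant is
``f(rho) = (1 + rho^2) / 2``; alternatives can be passed explicitly.

``rho`` is piecewise linear over the cycle phases:

    G1: 1 - t~/t_G1      S: 0      G2: (t~ - t_G1 - t_S)/t_G2      M: 1

Cells that have exhausted M but not yet met the division criterion simply
wait apically (rho = 1) and keep growing.  Differentiating cells have their
target area set to zero, shrink, and are eventually extruded by the
topology layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .units import PER_HOUR, hours

__all__ = [
    "CellCyclePhases",
    "CellCycleState",
    "DivisionRule",
    "apicobasal_position",
    "target_area",
    "default_interpolant",
    "sample_growth_rate",
    "division_ready",
    "mark_differentiating",
    "GROWTH_RATE_MEAN_PER_MIN",
]

#: mean growth rate: inverse of a 780 min (13 h) cell lifespan
GROWTH_RATE_MEAN_PER_MIN = 1.0 / 780.0

#: same rate in nondimensional time (460 s units)
GROWTH_RATE_MEAN = GROWTH_RATE_MEAN_PER_MIN * (460.0 / 60.0)


@dataclass(frozen=True)
class CellCyclePhases:
    """Durations of the G1, S, G2 and M phases (nondimensional time)."""

    t_G1: float
    t_S: float
    t_G2: float
    t_M: float

    def __post_init__(self) -> None:
        for name in ("t_G1", "t_S", "t_G2", "t_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def t_T(self) -> float:
        return self.t_G1 + self.t_S + self.t_G2 + self.t_M

    @property
    def m_onset(self) -> float:
        """Time since birth at which M phase begins."""
        return self.t_G1 + self.t_S + self.t_G2

    @classmethod
    def from_proportions(
        cls,
        t_T_hours: float = 13.0,
        g1_fraction: float = 0.55,
        sg2_fraction: float = 0.40,
        m_fraction: float = 0.05,
    ) -> "CellCyclePhases":
        """Build phases from a total cycle time (hours) and proportions.

        Within the S+G2 block, S takes 1/3 and G2 takes 2/3 of the time.
        """
        if not np.isclose(g1_fraction + sg2_fraction + m_fraction, 1.0):
            raise ValueError("phase proportions must sum to 1")
        t_T = hours(t_T_hours)
        return cls(
            t_G1=g1_fraction * t_T,
            t_S=sg2_fraction * t_T / 3.0,
            t_G2=2.0 * sg2_fraction * t_T / 3.0,
            t_M=m_fraction * t_T,
        )


@dataclass
class CellCycleState:
    """Per-cell lineage and cycle bookkeeping."""

    t_0: float
    g: float
    differentiating: bool = False
    clone_id: int = -1
    domain: str = "pD"

    def age(self, t: float) -> float:
        return t - self.t_0


@dataclass(frozen=True)
class DivisionRule:
    """Critical size above which an M-phase cell divides.

    ``criterion="volume"`` (default) compares the cell's volume proxy —
    the linear growth factor ``1 + g t~`` of the target-area model, since
    cell volume is assumed to grow linearly over the cycle — against
    ``A_c``; with ``A_c = 2`` a cell divides once it has doubled its
    volume, which happens at ``t~ = 1/g``, i.e. after one nominal cycle.
    ``criterion="apical_area"`` compares the instantaneous apical area
    instead, which couples division timing to mechanical compression.
    """

    A_c: float = 2.0
    criterion: str = "volume"

    def __post_init__(self) -> None:
        if self.A_c <= 0:
            raise ValueError("A_c must be positive")
        if self.criterion not in ("volume", "apical_area"):
            raise ValueError("criterion must be 'volume' or 'apical_area'")


def default_interpolant(rho):
    """Apical-area interpolant f(rho) = (1 + rho^2)/2: f(0)=1/2, f(1)=1,
    increasing and steepest near the apical surface."""
    rho = np.asarray(rho, dtype=float)
    return 0.5 * (1.0 + rho * rho)


def apicobasal_position(t_tilde, phases: CellCyclePhases):
    """Apicobasal nuclear position rho in [0, 1] at time-since-birth t~.

    Piecewise linear: apical (1) at birth, basal (0) through S, back to
    apical through G2, and apical for M and any overtime beyond t_T.
    Accepts scalars or arrays; negative ages raise.
    """
    t = np.asarray(t_tilde, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since birth must be non-negative")
    g1, s, g2 = phases.t_G1, phases.t_S, phases.t_G2
    rho = np.ones_like(t)
    in_g1 = t < g1
    rho = np.where(in_g1, 1.0 - np.divide(t, g1, out=np.zeros_like(t), where=g1 > 0), rho)
    in_s = (t >= g1) & (t < g1 + s)
    rho = np.where(in_s, 0.0, rho)
    in_g2 = (t >= g1 + s) & (t < g1 + s + g2)
    frac = np.divide(t - g1 - s, g2, out=np.ones_like(t), where=g2 > 0)
    rho = np.where(in_g2, frac, rho)
    out = np.clip(rho, 0.0, 1.0)
    return float(out) if np.isscalar(t_tilde) else out


def target_area(
    t_tilde,
    g,
    phases: CellCyclePhases,
    interpolant: Callable = default_interpolant,
):
    """Time-dependent target apical area A^0 = (1 + g t~) f(rho(t~))."""
    t = np.asarray(t_tilde, dtype=float)
    rho = apicobasal_position(t, phases)
    out = (1.0 + np.asarray(g, dtype=float) * t) * interpolant(rho)
    return float(out) if np.isscalar(t_tilde) else out


def sample_growth_rate(
    rng: np.random.Generator,
    size=None,
    mean: float = GROWTH_RATE_MEAN,
    sd_fraction: float = 0.2,
):
    """Draw per-cell growth rates from Normal(mean, (sd_fraction*mean)^2),
    redrawing any non-positive values.

    The spread is 20% of the mean growth rate of 1/780 per minute
    (converted to nondimensional time), interpreted as a standard
    deviation.
    """
    n = 1 if size is None else int(size)
    out = rng.normal(mean, sd_fraction * mean, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd_fraction * mean, size=int(bad.sum()))
        bad = out <= 0
    return float(out[0]) if size is None else out


def division_ready(
    state: CellCycleState,
    area: float,
    phases: CellCyclePhases,
    rule: DivisionRule,
    t: float,
) -> bool:
    """True iff the cell is in M phase (t~ > t_G1+t_S+t_G2), its size
    measure exceeds the critical value, and it is not differentiating."""
    if state.differentiating:
        return False
    age = state.age(t)
    if age <= phases.m_onset:
        return False
    size = 1.0 + state.g * age if rule.criterion == "volume" else area
    return size > rule.A_c


def mark_differentiating(
    differentiating: np.ndarray,
    rate_per_hour,
    dt: float,
    eligible_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flip eligible cells to differentiating with first-order hazard
    ``rate * dt`` per step (rates in per-hour, dt in nondimensional time).

    Returns the updated boolean array (modified in place).  Warns when
    ``rate * dt`` exceeds 0.1, where the first-order approximation of the
    exponential hazard degrades.
    """
    rate = np.asarray(rate_per_hour, dtype=float) / PER_HOUR
    if np.any(rate < 0):
        raise ValueError("differentiation rate must be non-negative")
    p = rate * dt
    if np.any(p > 0.1):
        import warnings

        warnings.warn(
            "rate*dt > 0.1: first-order hazard approximation degraded",
            RuntimeWarning,
            stacklevel=2,
        )
    can_flip = eligible_mask & ~differentiating
    flips = can_flip & (rng.random(len(differentiating)) < p)
    differentiating |= flips
    return differentiating
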