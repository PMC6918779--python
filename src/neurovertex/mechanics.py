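"""Vertex-model energy, forces and overdamped dynamics.

The tissue energy is

    E = sum_a K/2 (A_a - A_a^0)^2  +  sum_<ij> Lambda l_ij
        + sum_a Gamma/2 L_a^2

with uniform area elasticity ``K``, junction tension ``Lambda`` and
perimeter contractility ``Gamma`` (each junction counted once).  Combining
the last two terms per cell gives an effective target perimeter
``L0 = -Lambda / (2 Gamma)``.  Vertices follow overdamped first-order
dynamics ``mu dr_i/dt = F_i`` with ``F_i = -dE/dr_i``, integrated with an
explicit Euler step.

Ground states are classified in the plane of the dimensionless parameters

    lambda_bar = Lambda / (K A0^{3/2}),   gamma_bar = Gamma / (K A0),

where ``A0`` is the cycle-averaged target area.  The boundaries follow the
hexagonal-ground-state analysis of the standard model: a tissue is "soft"
when the preferred perimeter exceeds that of the unit-area regular hexagon
(shape index ~3.722), solid ("epithelial") below it, and collapsed when
shrinking cells to zero area is energetically favourable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .mesh import Mesh

__all__ = [
    "MechanicalParams",
    "NondimensionalParams",
    "PRESETS",
    "energy",
    "vertex_forces",
    "step_vertices",
    "normalise_parameters",
    "denormalise_parameters",
    "classify_phase_region",
    "is_epithelial",
    "HEX_SHAPE_INDEX",
]

#: perimeter of the regular hexagon of unit area, p = 6 s with (3 sqrt3/2) s^2 = 1
HEX_SHAPE_INDEX = float(6.0 * np.sqrt(2.0 / (3.0 * np.sqrt(3.0))))

#: the six (lambda_bar, gamma_bar) working points used throughout
PRESETS: dict[str, tuple[float, float]] = {
    "I": (-0.4, 0.14),
    "II": (-0.2, 0.12),
    "III": (-0.3, 0.1),
    "IV": (-0.05, 0.065),
    "V": (0.075, 0.04),
    "VI": (0.15, 0.02),
}


@dataclass
class MechanicalParams:
    """Dimensional mechanical parameters (uniform across cells/junctions).

    ``K`` area elasticity, ``Lambda`` junction tension, ``Gamma`` perimeter
    contractility, ``mu`` vertex drag, ``dt`` Euler step (nondimensional
    time; the reference discretisation is 1.017e-3, i.e. 1e5 steps per 13 h
    cycle — coarser steps are routinely used for desk-scale runs, see
    docs/methods.md).
    """

    K: float = 1.0
    Lambda: float = 0.0
    Gamma: float = 0.0
    mu: float = 1.0
    dt: float = 1.017e-3

    def __post_init__(self) -> None:
        if self.K <= 0 or self.mu <= 0 or self.dt <= 0:
            raise ValueError("K, mu and dt must be positive")

    @property
    def target_perimeter(self) -> float:
        """Effective target perimeter L0 = -Lambda/(2 Gamma) (Gamma != 0)."""
        if self.Gamma == 0:
            raise ValueError("target perimeter undefined for Gamma = 0")
        return -self.Lambda / (2.0 * self.Gamma)


@dataclass
class NondimensionalParams:
    """Dimensionless tension/contractility with the reference target area."""

    lambda_bar: float
    gamma_bar: float
    A0: float = 1.25

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("reference area A0 must be positive")


def normalise_parameters(params: MechanicalParams, A0: float) -> NondimensionalParams:
    """Map (K, Lambda, Gamma) to (lambda_bar, gamma_bar) at reference area A0."""
    if params.K <= 0 or A0 <= 0:
        raise ValueError("K and A0 must be positive")
    return NondimensionalParams(
        lambda_bar=params.Lambda / (params.K * A0 ** 1.5),
        gamma_bar=params.Gamma / (params.K * A0),
        A0=A0,
    )


def denormalise_parameters(
    nd: NondimensionalParams, K: float = 1.0, mu: float = 1.0, dt: float = 1.017e-3
) -> MechanicalParams:
    """Inverse of :func:`normalise_parameters` (K chosen freely, default 1)."""
    return MechanicalParams(
        K=K,
        Lambda=nd.lambda_bar * K * nd.A0 ** 1.5,
        Gamma=nd.gamma_bar * K * nd.A0,
        mu=mu,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# energy and forces


def _check_targets(mesh: Mesh, targets: np.ndarray) -> np.ndarray:
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (mesh.n_cells,):
        raise ValueError(
            f"need one target area per cell ({mesh.n_cells}), got shape {targets.shape}"
        )
    return targets


def energy(mesh: Mesh, params: MechanicalParams, targets) -> float:
    """Total tissue energy for the given per-cell target areas."""
    targets = _check_targets(mesh, targets)
    _, lens, _, areas, perims = mesh.edge_geometry()
    e_area = 0.5 * params.K * np.sum((areas - targets) ** 2)
    # each junction appears twice in the slot arrays
    e_tension = 0.5 * params.Lambda * np.sum(lens)
    e_contract = 0.5 * params.Gamma * np.sum(perims**2)
    return float(e_area + e_tension + e_contract)


def vertex_forces(mesh: Mesh, params: MechanicalParams, targets) -> np.ndarray:
    """Analytic force ``F_i = -dE/dr_i`` on every vertex, (N_v, 2).

    Gradients are taken on minimum-image unwrapped loops, so the forces are
    exact for cells straddling the periodic seam, and their sum over the
    tissue vanishes (translation invariance).
    """
    targets = _check_targets(mesh, targets)
    f = mesh.flat()
    e, lens, _, areas, perims = mesh.edge_geometry()
    if np.any(lens == 0.0):
        raise ValueError("zero-length junction encountered; topology update required")

    # area term: dA/dr_k = 0.5 * perp(r_{k+1} - r_{k-1})
    d = e + e[f.prv]
    coeff_a = (params.K * (areas - targets))[f.cell_id]
    fa = np.empty_like(e)
    fa[:, 0] = -coeff_a * 0.5 * d[:, 1]
    fa[:, 1] = coeff_a * 0.5 * d[:, 0]

    # junction tension (Lambda/2 per slot; each junction appears twice) and
    # perimeter contractility (Gamma * L per cell), both along edge directions
    u = e / lens[:, None]
    coeff_e = 0.5 * params.Lambda + (params.Gamma * perims)[f.cell_id]
    fe = coeff_e[:, None] * u

    n = mesh.n_vertices
    fx = np.bincount(f.loop, weights=fa[:, 0] + fe[:, 0], minlength=n)
    fy = np.bincount(f.loop, weights=fa[:, 1] + fe[:, 1], minlength=n)
    nxt_ids = f.loop[f.nxt]
    fx -= np.bincount(nxt_ids, weights=fe[:, 0], minlength=n)
    fy -= np.bincount(nxt_ids, weights=fe[:, 1], minlength=n)
    return np.stack([fx, fy], axis=1)


def step_vertices(mesh: Mesh, forces: np.ndarray, params: MechanicalParams) -> Mesh:
    """Explicit Euler step ``r_i <- r_i + (dt/mu) F_i``, wrapped into the box.

    Aborts with a diagnostic if any displacement exceeds a quarter box
    length (the step size is then too large for the current forces).
    """
    disp = (params.dt / params.mu) * forces
    max_disp = np.max(np.abs(disp), axis=0)
    if np.any(max_disp > mesh.box / 4.0):
        raise RuntimeError(
            f"vertex displacement {max_disp} exceeds box/4 {mesh.box / 4.0}; "
            f"reduce dt (currently {params.dt:g})"
        )
    mesh.vertices += disp
    mesh.wrap()
    return mesh


# ---------------------------------------------------------------------------
# phase-diagram classification


def _hexagon_energy_profile(lambda_bar: float, gamma_bar: float):
    """Per-cell energy of a regular hexagonal tiling as a function of cell
    area (nondimensional, unit target area).  Junction tension is halved
    because edges are shared between neighbours."""
    c = HEX_SHAPE_INDEX

    def e(a: float) -> float:
        return (
            0.5 * (a - 1.0) ** 2
            + 0.5 * lambda_bar * c * np.sqrt(a)
            + 0.5 * gamma_bar * c * c * a
        )

    return e


def classify_phase_region(nd: NondimensionalParams) -> str:
    """Classify a parameter point into one of four ground-state regions.

    Returns one of ``"I"`` (soft network: degenerate ground state, zero
    shear modulus), ``"II"`` (hexagonal solid at negative tension),
    ``"III"`` (hexagonal solid at positive tension) or ``"IV"``
    (collapsed: cells shrink to zero area).  Regions II and III have
    epithelial (solid, confluent) behaviour.
    """
    lb, gb = nd.lambda_bar, nd.gamma_bar
    if gb < 0:
        raise ValueError("gamma_bar must be non-negative")
    # soft network: preferred perimeter reaches the regular-hexagon perimeter
    if gb == 0.0:
        if lb <= 0.0:
            return "I"
    else:
        p0 = -lb / (2.0 * gb)
        if lb <= 0.0 and p0 >= HEX_SHAPE_INDEX:
            return "I"
    if lb <= 0.0:
        return "II"
    # positive tension: solid unless collapse (area -> 0) is favourable
    e = _hexagon_energy_profile(lb, gb)
    res = minimize_scalar(e, bounds=(1e-9, 4.0), method="bounded")
    if e(1e-12) <= res.fun + 1e-12:
        return "IV"
    return "III"


def is_epithelial(nd: NondimensionalParams) -> bool:
    """True in the solid, confluent regions (II and III)."""
    return classify_phase_region(nd) in ("II", "III")
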