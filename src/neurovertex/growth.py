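"""Global growth of the torus against anisotropic drag.

The neural tube is modelled as a torus with DV radius ``R``
(circumference ``L_DV = 2 pi R``) and AP radius ``H`` (``L_AP = 2 pi H``).
Writing the DV coordinate of vertex ``i`` as ``x_i = R theta_i``, expansion
of each radius is resisted by a drag of magnitude ``2 mu' dR/dt`` (DV) or
``2 mu'' dH/dt`` (AP) per cell, balancing the potential force:

    2 mu'  N_c dR/dt = F_R = -dE/dR |_theta,
    2 mu'' N_c dH/dt = F_H = -dE/dH.

The generalised forces are exact derivatives of the vertex-model energy
under affine dilation of the respective axis at fixed angular coordinates.
After each radius update all vertex positions are rescaled affinely.  The
default drags (mu' = 0.02, mu'' = 1) make DV expansion fifty times easier
than AP expansion, which drives the anisotropic tissue growth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh
from .mechanics import MechanicalParams, _check_targets

__all__ = ["TorusScale", "scale_forces", "step_scales", "tissue_aspect_ratio"]

TWO_PI = 2.0 * np.pi


@dataclass
class TorusScale:
    """Torus radii and the two drag coefficients."""

    R: float
    H: float
    mu_dv: float = 0.02
    mu_ap: float = 1.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.H <= 0:
            raise ValueError("radii must be positive")
        if self.mu_dv <= 0 or self.mu_ap <= 0:
            raise ValueError("drag coefficients must be positive")

    @classmethod
    def from_box(cls, box, mu_dv: float = 0.02, mu_ap: float = 1.0) -> "TorusScale":
        return cls(R=box[0] / TWO_PI, H=box[1] / TWO_PI, mu_dv=mu_dv, mu_ap=mu_ap)

    @property
    def box(self) -> np.ndarray:
        return np.array([TWO_PI * self.R, TWO_PI * self.H])


def scale_forces(mesh: Mesh, params: MechanicalParams, targets) -> tuple[float, float]:
    """Generalised forces (F_R, F_H) = (-dE/dR, -dE/dH) at fixed angles.

    Under an affine x-dilation every cell area scales linearly and every
    edge x-component scales linearly, so the chain rule gives

        dE/d(ln R) = sum_a K (A_a - A_a^0) A_a
                     + sum_slots (Lambda/2 + Gamma L_a) e_x^2 / |e|

    and similarly for H with the y-components.
    """
    targets = _check_targets(mesh, targets)
    f = mesh.flat()
    e, lens, _, areas, perims = mesh.edge_geometry()
    press = params.K * (areas - targets)
    darea = float(np.sum(press * areas))
    coeff = 0.5 * params.Lambda + (params.Gamma * perims)[f.cell_id]
    ex2 = e[:, 0] ** 2 / lens
    ey2 = e[:, 1] ** 2 / lens
    dlnx = darea + float(np.sum(coeff * ex2))
    dlny = darea + float(np.sum(coeff * ey2))
    R = mesh.box[0] / TWO_PI
    H = mesh.box[1] / TWO_PI
    return -dlnx / R, -dlny / H


def step_scales(
    mesh: Mesh,
    scale: TorusScale,
    F_R: float,
    F_H: float,
    n_cells: int,
    dt: float,
    max_rel_step: float = 0.005,
) -> TorusScale:
    """Euler-update the torus radii against per-cell drag and rescale the
    mesh affinely.

        dR/dt = F_R / (2 mu'  N_c),   dH/dt = F_H / (2 mu'' N_c)

    The relative change of each radius is capped at ``max_rel_step`` per
    step; the cap only engages during strong initial transients, where it
    turns a possibly unstable explicit step into a slower relaxation
    towards the same balance point.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    dR = dt * F_R / (2.0 * scale.mu_dv * n_cells)
    dH = dt * F_H / (2.0 * scale.mu_ap * n_cells)
    cap_r = max_rel_step * scale.R
    cap_h = max_rel_step * scale.H
    dR = float(np.clip(dR, -cap_r, cap_r))
    dH = float(np.clip(dH, -cap_h, cap_h))
    new_R = scale.R + dR
    new_H = scale.H + dH
    if new_R <= 0 or new_H <= 0:
        raise RuntimeError("torus radius driven non-positive; reduce dt")
    mesh.vertices[:, 0] *= new_R / scale.R
    mesh.vertices[:, 1] *= new_H / scale.H
    mesh.box = np.array([TWO_PI * new_R, TWO_PI * new_H])
    mesh.invalidate()
    return TorusScale(new_R, new_H, scale.mu_dv, scale.mu_ap)


def tissue_aspect_ratio(scale: TorusScale) -> float:
    """Whole-tissue AP/DV aspect ratio, L_AP / L_DV = H / R."""
    return scale.H / scale.R
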