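"""Simulation engine: initialisation, equilibration and the main loop.

Each Euler step applies, in a fixed order chosen for determinism:

1. per-cell IKNM target areas from the cycle state,
2. vertex forces and the overdamped Euler vertex update,
3. the torus-scale (box growth) update against anisotropic drag,
4. stochastic differentiation marking,
5. division checks (M phase and the critical-area criterion),
6. short-edge T1 transitions and two-sided-cell extrusions.

A run consists of an equilibration phase (default 30 h of biological time,
no differentiation, no clone tracking) after which the clock is reset, each
cell becomes the founder of a clone and, optionally, a contiguous DV band
is designated as the pMN domain.  pMN identity is a lineage label: it is
assigned once from the initial band and inherited by daughters rather than
re-evaluated positionally, matching the biological identity semantics (the
band's DV extent then shrinks as progenitors are lost to differentiation).

All randomness flows from a single master seed through named child streams
(initial ages, growth rates, division edge choice, differentiation), so
runs are reproducible and subsystems are independently replayable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import mesh as meshmod
from .cycle import DivisionRule, sample_growth_rate
from .growth import TorusScale, scale_forces, step_scales
from .mechanics import (
    MechanicalParams,
    NondimensionalParams,
    PRESETS,
    denormalise_parameters,
    vertex_forces,
    step_vertices,
)
from .mesh import IncidenceMap, Mesh, TopologyParams, build_hexagonal_tissue
from .units import PER_HOUR, hours

__all__ = [
    "SimulationConfig",
    "CellState",
    "EventLog",
    "SimulationResult",
    "run_simulation",
    "designate_pmn",
    "track_clones",
    "circular_extent",
]

PD, PMN = 0, 1
DOMAIN_NAMES = {PD: "pD", PMN: "pMN"}


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run.

    Mechanical parameters are given either as a named preset ("I".."VI")
    or as explicit (lambda_bar, gamma_bar); both are interpreted at the
    reference target area ``A0_ref`` with K = mu = 1.

    Durations are biological hours.  ``dt`` is the Euler step in
    nondimensional time; the reference discretisation is 1.017e-3 (1e5
    steps per 13 h cycle) and coarser desk-scale steps are standard (see
    docs/methods.md for the step-size study).
    """

    preset: str | None = "V"
    lambda_bar: float | None = None
    gamma_bar: float | None = None
    A0_ref: float = 1.25
    K: float = 1.0
    mu: float = 1.0
    dt: float = 1.017e-3

    n_rows: int = 10
    n_cols: int = 10
    equilibration_hours: float = 30.0
    run_hours: float = 48.0
    seed: int = 0

    topology: TopologyParams = field(default_factory=TopologyParams)
    division: DivisionRule = field(default_factory=DivisionRule)
    t_T_hours_pd: float = 13.0
    t_T_hours_pmn: float = 11.7
    g1_fraction: float = 0.55
    sg2_fraction: float = 0.40
    m_fraction: float = 0.05
    g_sd_fraction: float = 0.2

    pmn_fraction: float = 0.0
    diff_rate_pmn: float = 0.1  # per hour, applies to the pMN lineage
    diff_rate_pd: float = 0.0   # per hour, usually 0 (uniform-differentiation runs set it)

    mu_dv: float = 0.02
    mu_ap: float = 1.0

    record_every_hours: float = 0.5
    audit_every_steps: int = 2000

    def __post_init__(self) -> None:
        if self.equilibration_hours < 0 or self.run_hours < 0:
            raise ValueError("durations must be non-negative")
        if not 0.0 <= self.pmn_fraction <= 1.0:
            raise ValueError("pmn_fraction must lie in [0, 1]")

    def nondimensional(self) -> NondimensionalParams:
        if self.lambda_bar is not None and self.gamma_bar is not None:
            return NondimensionalParams(self.lambda_bar, self.gamma_bar, self.A0_ref)
        if self.preset is None:
            raise ValueError("give a preset or explicit (lambda_bar, gamma_bar)")
        lb, gb = PRESETS[self.preset]
        return NondimensionalParams(lb, gb, self.A0_ref)

    def mechanical(self) -> MechanicalParams:
        return denormalise_parameters(self.nondimensional(), K=self.K, mu=self.mu, dt=self.dt)


class CellState:
    """Per-cell arrays, kept index-aligned with ``mesh.cells``."""

    def __init__(self, n: int):
        self.t0 = np.zeros(n)
        self.g = np.zeros(n)
        self.t_T = np.zeros(n)
        self.differentiating = np.zeros(n, dtype=bool)
        self.clone = np.full(n, -1, dtype=np.int64)
        self.domain = np.zeros(n, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.t0)

    _FIELDS = ("t0", "g", "t_T", "differentiating", "clone", "domain")

    def append(self, **kw: Any) -> None:
        for name in self._FIELDS:
            arr = getattr(self, name)
            setattr(self, name, np.append(arr, np.asarray(kw[name], dtype=arr.dtype)))

    def delete(self, idx: int) -> None:
        for name in self._FIELDS:
            setattr(self, name, np.delete(getattr(self, name), idx))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t0": self.t0,
                "g": self.g,
                "t_T": self.t_T,
                "differentiating": self.differentiating,
                "clone_id": self.clone,
                "domain": [DOMAIN_NAMES[d] for d in self.domain],
            }
        )


@dataclass
class EventLog:
    """Append-only record of topological and fate events.

    Angles are radians in [0, pi) measured from the DV axis.  Times are
    nondimensional, counted from the post-equilibration reset.
    """

    divisions: list = field(default_factory=list)  # (t, cell, clone, domain, new_edge_angle)
    t1s: list = field(default_factory=list)        # (t, old_angle, new_angle, domain)
    differentiations: list = field(default_factory=list)  # (t, cell, clone, domain)
    extrusions: list = field(default_factory=list)  # (t, clone, domain)

    def divisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.divisions, columns=["t", "cell", "clone_id", "domain", "new_edge_angle"]
        )

    def t1_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.t1s, columns=["t", "old_angle", "new_angle", "domain"])

    def differentiations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.differentiations, columns=["t", "cell", "clone_id", "domain"])

    def extrusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.extrusions, columns=["t", "clone_id", "domain"])


@dataclass
class SimulationResult:
    mesh: Mesh
    state: CellState
    scale: TorusScale
    events: EventLog
    series: pd.DataFrame
    clones: pd.DataFrame
    config: SimulationConfig

    @property
    def aspect_ratio(self) -> float:
        return float(self.mesh.box[1] / self.mesh.box[0])


# ---------------------------------------------------------------------------
# helpers


def circular_extent(coords: np.ndarray, length: float) -> float:
    """Extent (max - min after optimal unwrapping) of points on a circle of
    circumference ``length``: the circle length minus the largest empty arc.
    Handles point sets straddling the periodic seam without unwrapping
    choices; equals the plain bounding interval for compact sets.
    """
    xs = np.sort(np.mod(np.asarray(coords, dtype=float), length))
    if xs.size == 0:
        return 0.0
    if xs.size == 1:
        return 0.0
    gaps = np.diff(xs)
    wrap_gap = length - xs[-1] + xs[0]
    return float(length - max(gaps.max(), wrap_gap))


def designate_pmn(mesh: Mesh, fraction: float) -> np.ndarray:
    """Label the cells whose centroid DV coordinate falls in a contiguous
    band of width ``fraction * L_DV`` starting at x = 0.  Returns a boolean
    mask (True = pMN)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return np.zeros(mesh.n_cells, dtype=bool)
    if fraction == 1.0:
        return np.ones(mesh.n_cells, dtype=bool)
    cx = _centroids(mesh)[:, 0]
    return cx < fraction * mesh.box[0]


def _centroids(mesh: Mesh) -> np.ndarray:
    f = mesh.flat()
    _, _, u, _, _ = mesh.edge_geometry()
    anchors = mesh.vertices[f.loop[f.starts[:-1]]]
    sums = np.add.reduceat(u, f.starts[:-1], axis=0)
    return np.mod(anchors + sums / f.nsides[:, None], mesh.box)


def track_clones(mesh: Mesh, state: CellState, method: str = "centroids") -> pd.DataFrame:
    """Per-founder clone records: member count and AP/DV extents.

    ``method="centroids"`` (default) measures extents over the member
    cells' centroid coordinates, mirroring the experimental clone analysis
    in which each labelled cell contributes one point; ``"vertices"``
    measures the bounding range of the member cells' vertex loops instead
    (one cell size larger in each axis).  Both use the circular-range rule,
    so clones straddling the periodic seam measure the same as their
    translated copies.  Clones wider than half the box are flagged (their
    extent is ambiguous under periodicity).
    """
    if method not in ("centroids", "vertices"):
        raise ValueError("method must be 'centroids' or 'vertices'")
    f = mesh.flat()
    records = []
    clone_ids = np.unique(state.clone)
    if method == "centroids":
        pts = _centroids(mesh)
    vx = mesh.vertices[:, 0]
    vy = mesh.vertices[:, 1]
    for cid in clone_ids:
        members = np.flatnonzero(state.clone == cid)
        if method == "centroids":
            xs, ys = pts[members, 0], pts[members, 1]
        else:
            sel = np.isin(f.cell_id, members)
            vids = np.unique(f.loop[sel])
            xs, ys = vx[vids], vy[vids]
        dv = circular_extent(xs, mesh.box[0])
        ap = circular_extent(ys, mesh.box[1])
        records.append(
            {
                "clone_id": int(cid),
                "n_cells": len(members),
                "dv_extent": dv,
                "ap_extent": ap,
                "domain": DOMAIN_NAMES[int(state.domain[members[0]])],
                "flagged": bool(dv > mesh.box[0] / 2 or ap > mesh.box[1] / 2),
            }
        )
    return pd.DataFrame(records)


def _pmn_dv_fraction(mesh: Mesh, state: CellState) -> float:
    """DV extent of the surviving pMN cells as a fraction of L_DV, measured
    over cell centroids — the same coordinates that define band membership,
    so a freshly designated 30% band measures 0.30."""
    members = np.flatnonzero(state.domain == PMN)
    if members.size == 0:
        return 0.0
    cx = _centroids(mesh)[members, 0]
    return circular_extent(cx, mesh.box[0]) / mesh.box[0]


# ---------------------------------------------------------------------------
# the engine


class _Engine:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        ss = np.random.SeedSequence(config.seed)
        kids = ss.spawn(4)
        self.rng_init = np.random.default_rng(kids[0])
        self.rng_growth = np.random.default_rng(kids[1])
        self.rng_division = np.random.default_rng(kids[2])
        self.rng_diff = np.random.default_rng(kids[3])

        self.params = config.mechanical()
        self.mesh = build_hexagonal_tissue(config.n_rows, config.n_cols)
        # break the symmetry of the fresh lattice so relaxation can proceed
        jitter = 0.01 * self.rng_init.standard_normal(self.mesh.vertices.shape)
        self.mesh.vertices += jitter
        self.mesh.wrap()
        self.mesh.invalidate()
        self.scale = TorusScale.from_box(self.mesh.box, config.mu_dv, config.mu_ap)

        n = self.mesh.n_cells
        self.state = CellState(n)
        t_T = hours(config.t_T_hours_pd)
        self.state.t_T[:] = t_T
        self.state.t0[:] = -self.rng_init.uniform(0.0, t_T, size=n)
        self.state.g[:] = sample_growth_rate(
            self.rng_growth, size=n, mean=1.0 / t_T, sd_fraction=config.g_sd_fraction
        )
        self.t = 0.0
        self.events = EventLog()
        self.series_rows: list[dict] = []
        self._recording = False

        fr = config.g1_fraction, config.sg2_fraction, config.m_fraction
        if not math.isclose(sum(fr), 1.0):
            raise ValueError("phase fractions must sum to 1")
        self.f_g1, self.f_sg2, self.f_m = fr
        self.f_m_onset = self.f_g1 + self.f_sg2

    # -- per-cell cycle quantities ----------------------------------------

    def _rho(self, t_tilde: np.ndarray) -> np.ndarray:
        u = t_tilde / self.state.t_T
        f_g1 = self.f_g1
        f_s_end = self.f_g1 + self.f_sg2 / 3.0
        f_g2_end = self.f_m_onset
        rho = np.ones_like(u)
        g1 = u < f_g1
        rho[g1] = 1.0 - u[g1] / f_g1
        s = (u >= f_g1) & (u < f_s_end)
        rho[s] = 0.0
        g2 = (u >= f_s_end) & (u < f_g2_end)
        rho[g2] = (u[g2] - f_s_end) / (f_g2_end - f_s_end)
        return rho

    def targets(self) -> np.ndarray:
        t_tilde = self.t - self.state.t0
        rho = self._rho(t_tilde)
        out = (1.0 + self.state.g * t_tilde) * 0.5 * (1.0 + rho * rho)
        out[self.state.differentiating] = 0.0
        return out

    # -- phases ------------------------------------------------------------

    def run_phase(self, duration_hours: float, recording: bool) -> None:
        self._recording = recording
        n_steps = int(round(hours(duration_hours) / self.cfg.dt))
        record_every = max(1, int(round(hours(self.cfg.record_every_hours) / self.cfg.dt)))
        if recording:
            self._record()
        for step in range(n_steps):
            self._step()
            if self.mesh.n_cells < 16:
                raise RuntimeError(
                    "tissue shrank below 16 cells; the periodic vertex-model "
                    "approximation is no longer valid (cells comparable to the box)"
                )
            if recording and (step + 1) % record_every == 0:
                self._record()
            if self.cfg.audit_every_steps and (step + 1) % self.cfg.audit_every_steps == 0:
                issues = meshmod.topology_audit(self.mesh, tol=1e-6)
                if issues:
                    raise RuntimeError(f"mesh invariant violation at t={self.t:g}: {issues}")
        if recording and n_steps % record_every != 0:
            self._record()

    def reset_clock_and_found_clones(self) -> None:
        """End of equilibration: reset time, label founders, designate pMN."""
        self.state.t0 -= self.t
        self.t = 0.0
        n = len(self.state)
        self.state.clone = np.arange(n, dtype=np.int64)
        if self.cfg.pmn_fraction > 0:
            mask = designate_pmn(self.mesh, self.cfg.pmn_fraction)
            self.state.domain[mask] = PMN
            t_T = hours(self.cfg.t_T_hours_pmn)
            self.state.t_T[mask] = t_T
            self.state.g[mask] = sample_growth_rate(
                self.rng_growth, size=int(mask.sum()), mean=1.0 / t_T,
                sd_fraction=self.cfg.g_sd_fraction,
            )
        self.events = EventLog()
        self.series_rows = []

    # -- one Euler step -----------------------------------------------------

    def _step(self) -> None:
        cfg = self.cfg
        self.t += cfg.dt
        targets = self.targets()

        forces = vertex_forces(self.mesh, self.params, targets)
        step_vertices(self.mesh, forces, self.params)
        self.mesh.invalidate()

        f_r, f_h = scale_forces(self.mesh, self.params, targets)
        self.scale = step_scales(
            self.mesh, self.scale, f_r, f_h, self.mesh.n_cells, cfg.dt
        )

        self._differentiation_step()
        self._division_step()
        self._t1_step()

    def _differentiation_step(self) -> None:
        cfg = self.cfg
        # differentiation only acts after the equilibration reset
        if not self._recording or self._diff_rates_zero():
            return
        st = self.state
        rate = np.where(st.domain == PMN, cfg.diff_rate_pmn, cfg.diff_rate_pd)
        p = (rate / PER_HOUR) * cfg.dt
        flips = (~st.differentiating) & (self.rng_diff.random(len(st)) < p)
        if np.any(flips):
            st.differentiating |= flips
            if self._recording:
                for c in np.flatnonzero(flips):
                    self.events.differentiations.append(
                        (self.t, int(c), int(st.clone[c]), DOMAIN_NAMES[int(st.domain[c])])
                    )

    def _diff_rates_zero(self) -> bool:
        cfg = self.cfg
        if cfg.diff_rate_pd > 0:
            return False
        return not (cfg.diff_rate_pmn > 0 and np.any(self.state.domain == PMN))

    def _division_step(self) -> None:
        st = self.state
        f = self.mesh.flat()
        _, _, _, areas, _ = self.mesh.edge_geometry()
        t_tilde = self.t - st.t0
        if self.cfg.division.criterion == "volume":
            size = 1.0 + st.g * t_tilde
        else:
            size = areas
        ready = (
            (t_tilde > self.f_m_onset * st.t_T)
            & (size > self.cfg.division.A_c)
            & ~st.differentiating
            & (f.nsides >= 4)
        )
        idxs = np.flatnonzero(ready)
        if idxs.size == 0:
            return
        inc = IncidenceMap(self.mesh)
        for alpha in idxs:
            alpha = int(alpha)
            a, b, info = meshmod.divide_cell(self.mesh, alpha, self.rng_division, inc)
            domain = int(st.domain[alpha])
            clone = int(st.clone[alpha])
            g_mean = 1.0 / st.t_T[alpha]
            g1, g2 = sample_growth_rate(
                self.rng_growth, size=2, mean=g_mean, sd_fraction=self.cfg.g_sd_fraction
            )
            # daughter a reuses the mother's slot, daughter b is appended
            st.t0[alpha] = self.t
            st.g[alpha] = g1
            st.append(
                t0=self.t, g=g2, t_T=st.t_T[alpha],
                differentiating=False, clone=clone, domain=domain,
            )
            if self._recording:
                self.events.divisions.append(
                    (self.t, alpha, clone, DOMAIN_NAMES[domain], info["angle"])
                )

    def _t1_step(self) -> None:
        # a removal renumbers vertices and cells, invalidating the queued
        # junction ids; re-detect and continue (bounded number of passes)
        for _ in range(10):
            if not self._t1_pass():
                break

    def _t1_pass(self) -> bool:
        """One pass over the short-edge queue; returns True if a removal
        interrupted the pass (caller should re-detect and continue)."""
        shorts = meshmod.detect_short_edges(self.mesh, self.cfg.topology)
        shorts.extend(self._degenerate_cell_edges())
        if not shorts:
            return False
        inc = IncidenceMap(self.mesh)
        st = self.state
        seen = set()
        for edge in shorts:
            if edge in seen:
                continue
            seen.add(edge)
            i, j = edge
            shared = meshmod._shared_cells(self.mesh, inc, i, j)
            if len(shared) != 2:
                continue  # stale after an earlier swap this step
            # a triangle reduced by the swap becomes two-sided and is
            # extruded; the removal rule applies unconditionally
            collapse = min(len(self.mesh.cells[c]) for c in shared) <= 3
            try:
                info = meshmod.t1_transition(
                    self.mesh, edge, self.cfg.topology, inc, allow_collapse=collapse
                )
            except meshmod.MeshError:
                continue  # forbidden configuration: deferred to a later step
            if self._recording:
                cells = [c for c in info["cells"] if c < len(st)]
                n_pmn = int(np.sum(st.domain[cells] == PMN))
                domain = DOMAIN_NAMES[PMN if n_pmn >= 2 else PD]
                self.events.t1s.append(
                    (self.t, info["old_angle"], info["new_angle"], domain)
                )
            if info["removed"] is not None:
                gone = info["removed"]["cell"]
                if self._recording:
                    self.events.extrusions.append(
                        (self.t, int(st.clone[gone]), DOMAIN_NAMES[int(st.domain[gone])])
                    )
                st.delete(gone)
                return True
        return False

    def _degenerate_cell_edges(self) -> list[tuple[int, int]]:
        """Shortest edge of any cell whose area has dropped to the collapsed
        scale, so it enters the T1/extrusion pathway even if the edge sits
        just above the relative threshold (a coarse Euler step can otherwise
        drive such a cell through zero area between detections)."""
        _, lens, _, areas, _ = self.mesh.edge_geometry()
        l_elim = self.cfg.topology.t1_threshold_fraction * float(lens.mean())
        eps_area = 3.0 * l_elim * l_elim
        tiny = np.flatnonzero(areas < eps_area)
        if tiny.size == 0:
            return []
        f = self.mesh.flat()
        out = []
        for alpha in tiny:
            # queue every edge of the degenerate cell (ascending length):
            # its shortest edge alone may sit in a blocked configuration
            sl = np.arange(f.starts[alpha], f.starts[alpha + 1])
            for slot in sl[np.argsort(lens[sl])]:
                i, j = int(f.loop[slot]), int(f.loop[f.nxt[slot]])
                out.append((min(i, j), max(i, j)))
        return out

    # -- recording ----------------------------------------------------------

    def _record(self) -> None:
        f = self.mesh.flat()
        targets = self.targets()
        row = {
            "t": self.t,
            "t_hours": self.t / PER_HOUR,
            "n_cells": self.mesh.n_cells,
            "L_DV": float(self.mesh.box[0]),
            "L_AP": float(self.mesh.box[1]),
            "aspect_ratio": float(self.mesh.box[1] / self.mesh.box[0]),
            "mean_sides": float(f.nsides.mean()),
            "mean_target_area": float(targets.mean()),
            "n_differentiating": int(self.state.differentiating.sum()),
        }
        if np.any(self.state.domain == PMN):
            row["pmn_dv_fraction"] = _pmn_dv_fraction(self.mesh, self.state)
        else:
            row["pmn_dv_fraction"] = np.nan
        self.series_rows.append(row)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Equilibrate, reset, and run the main phase; deterministic per seed."""
    eng = _Engine(config)
    eng.run_phase(config.equilibration_hours, recording=False)
    eng.reset_clock_and_found_clones()
    eng.run_phase(config.run_hours, recording=True)
    series = pd.DataFrame(eng.series_rows)
    clones = track_clones(eng.mesh, eng.state)
    return SimulationResult(
        mesh=eng.mesh,
        state=eng.state,
        scale=eng.scale,
        events=eng.events,
        series=series,
        clones=clones,
        config=config,
    )
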