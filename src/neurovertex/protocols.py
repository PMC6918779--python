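"""Canonical study protocols and their summary measurements.

Three simulation protocols recur throughout the analysis of neuroepithelial
growth; they are collected here so scripts, examples and tests run exactly
the same conditions:

``reference``
    10x10 tissue at preset V, no differentiation, drags mu'=0.02, mu''=1;
    30 h equilibration, then 48 h with every cell founding a clone.  Yields
    the baseline proliferation rate, whole-tissue anisotropy, clone shapes
    and T1 activity.
``two_domain``
    15x15 tissue; after equilibration a band covering 30% of the DV length
    is designated pMN (differentiation 0.1/h, dividing-cell cycle 11.7 h)
    and the remainder pD (no differentiation); 48 h of tracking.
``uniform_differentiation``
    15x15 tissue with differentiation 0.1/h everywhere and an 11.7 h cycle,
    48 h after equilibration (the larger grid keeps the shrinking tissue
    well above the small-size limit of the periodic approximation).

All protocols use the desk-scale Euler step dt = 0.05 (about 2000 steps
per 13 h cycle; statistics are converged with respect to dt, see
docs/methods.md) and can be made heavier by passing a smaller ``dt``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import SimulationConfig, SimulationResult, run_simulation
from .stats import clone_spread_ratio, geometry_table, proliferation_rate
from .units import PER_HOUR

__all__ = [
    "reference_protocol",
    "two_domain_protocol",
    "uniform_differentiation_protocol",
    "summarise_reference",
    "summarise_two_domain",
    "t1_rate_in_final_hour",
]


def reference_protocol(seed: int, dt: float = 0.05, **overrides) -> SimulationConfig:
    base = dict(
        preset="V", n_rows=10, n_cols=10, equilibration_hours=30.0, run_hours=48.0,
        dt=dt, seed=seed, mu_dv=0.02, mu_ap=1.0, pmn_fraction=0.0,
        audit_every_steps=5000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def two_domain_protocol(seed: int, dt: float = 0.05, **overrides) -> SimulationConfig:
    base = dict(
        preset="V", n_rows=15, n_cols=15, equilibration_hours=30.0, run_hours=48.0,
        dt=dt, seed=seed, mu_dv=0.02, mu_ap=1.0,
        pmn_fraction=0.30, diff_rate_pmn=0.1, t_T_hours_pmn=11.7,
        audit_every_steps=5000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def uniform_differentiation_protocol(seed: int, dt: float = 0.05, **overrides) -> SimulationConfig:
    base = dict(
        preset="V", n_rows=15, n_cols=15, equilibration_hours=30.0, run_hours=48.0,
        dt=dt, seed=seed, mu_dv=0.02, mu_ap=1.0,
        pmn_fraction=1.0, diff_rate_pmn=0.1, t_T_hours_pmn=11.7,
        audit_every_steps=5000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def t1_rate_in_final_hour(res: SimulationResult) -> float:
    """T1 events per cell per hour over the last simulated hour."""
    s = res.series
    t_end = s["t_hours"].iloc[-1]
    t1 = res.events.t1_frame()
    n_events = int((t1["t"] / PER_HOUR > t_end - 1.0).sum()) if len(t1) else 0
    n_mean = float(s.loc[s["t_hours"] > t_end - 1.0, "n_cells"].mean())
    return n_events / n_mean


def measured_proliferation_rate(
    res: SimulationResult, t_start: float = 0.0, t_stop: float = 10.0
) -> float:
    """lambda = d / (N~ dt) over a window of biological hours."""
    div = res.events.divisions_frame()
    th = div["t"] / PER_HOUR if len(div) else pd.Series(dtype=float)
    d = int(((th > t_start) & (th <= t_stop)).sum()) if len(div) else 0
    s = res.series
    sel = (s["t_hours"] > t_start) & (s["t_hours"] <= t_stop)
    n_mean = float(s.loc[sel, "n_cells"].mean())
    return proliferation_rate(d, n_mean, t_stop - t_start)


def summarise_reference(results: list[SimulationResult]) -> dict:
    """Pool the reference-protocol observables over replicates."""
    out: dict = {}
    out["mean_target_area"] = float(
        np.mean([r.series["mean_target_area"].iloc[-1] for r in results])
    )
    out["clone_spread_ratio"] = float(
        np.mean([clone_spread_ratio(r.clones) for r in results])
    )
    out["aspect_ratio"] = float(np.mean([r.aspect_ratio for r in results]))
    out["t1_rate"] = float(np.mean([t1_rate_in_final_hour(r) for r in results]))
    out["proliferation_rate"] = float(
        np.mean([measured_proliferation_rate(r) for r in results])
    )
    out["mean_cells_per_clone"] = float(
        np.mean([r.clones["n_cells"].mean() for r in results])
    )
    return out


def summarise_two_domain(res: SimulationResult) -> dict:
    """pMN shrinkage, per-domain clone sizes and cell DV lengths."""
    out: dict = {}
    out["pmn_dv_percent"] = float(res.series["pmn_dv_fraction"].iloc[-1] * 100.0)
    cl = res.clones
    pd_clones = cl[cl["domain"] == "pD"]
    pmn_clones = cl[cl["domain"] == "pMN"]
    out["pd_cells_per_clone"] = float(pd_clones["n_cells"].mean())
    out["pmn_cells_per_clone"] = (
        float(pmn_clones["n_cells"].mean()) if len(pmn_clones) else 0.0
    )
    out["pd_clone_ratio"] = clone_spread_ratio(pd_clones)
    table = geometry_table(res.mesh, res.state)
    dv = table.groupby("domain")["dv_length"].mean()
    out["pd_over_pmn_dv_length_pct"] = float(100.0 * (dv["pD"] / dv["pMN"] - 1.0))
    return out
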