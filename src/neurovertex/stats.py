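"""Quantitative descriptors and screening scores for cell geometry tables,
clone shapes and event logs.

Cell-shape descriptors follow the conventions used for segmented apical
images of the neuroepithelium:

* elongation: square root of the ratio of the largest to smallest
  eigenvalue of the second-moment matrix of the cell's vertex coordinates
  about their centroid;
* orientation: ``arctan(x1/y1)`` of the major-axis eigenvector, where
  ``y1`` is the DV and ``x1`` the AP component, so 0 means the long axis
  points along the DV axis;
* DV length: ``max(x) - min(x)`` of the (unwrapped) vertex coordinates.

The parameter-screen scores compare simulated and reference geometry
tables through Kolmogorov-Smirnov distances between *mean* empirical
cumulative distribution functions (replicate ECDFs averaged pointwise on
the merged support before taking the sup) plus absolute differences of
distribution standard deviations, and whole-tissue growth through DV
length change and final AP/DV aspect ratio.
"""
from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import circular_extent
from .units import AREA_UNIT_UM2

__all__ = [
    "cell_elongation",
    "cell_orientation_angle",
    "cell_dv_length",
    "ks_statistic",
    "mean_ecdf_ks",
    "geometry_similarity_score",
    "tissue_fit_score",
    "clone_spread_ratio",
    "proliferation_rate",
    "effective_growth_rate",
    "t1_statistics",
    "division_angle_distribution",
    "lewis_law_fit",
    "aspect_ratio_bounds",
    "synthetic_geometry_fixture",
    "geometry_table",
]


# ---------------------------------------------------------------------------
# single-cell shape descriptors


def _second_moment(loop: np.ndarray) -> np.ndarray:
    pts = np.asarray(loop, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three vertices")
    centred = pts - pts.mean(axis=0)
    return centred.T @ centred / len(pts)


def cell_elongation(loop: np.ndarray) -> float:
    """sqrt(lambda_max / lambda_min) of the vertex second-moment matrix.

    1 for shapes with a symmetry that equalises the two moments (regular
    polygons); rotation invariant.  Collinear (degenerate) loops raise.
    """
    m = _second_moment(loop)
    ev = np.linalg.eigvalsh(m)
    if ev[0] <= 0:
        raise ValueError("degenerate (collinear) vertex loop")
    return float(np.sqrt(ev[1] / ev[0]))


def cell_orientation_angle(loop: np.ndarray, tol: float = 1e-9) -> float:
    """Major-axis angle w.r.t. the DV axis, ``arctan(x1/y1)`` with ``x1``
    the AP (y) and ``y1`` the DV (x) eigenvector component.

    Returns a value in ``(-pi/2, pi/2]``; 0 means elongated along DV.
    Raises for (near-)isotropic cells, which have no unique major axis.
    """
    m = _second_moment(loop)
    ev, vec = np.linalg.eigh(m)
    if ev[1] - ev[0] <= tol * max(ev[1], tol):
        raise ValueError("isotropic cell: orientation undefined")
    major = vec[:, 1]  # (dv, ap) components
    y1, x1 = major[0], major[1]
    if y1 == 0.0:
        return np.pi / 2
    return float(np.arctan(x1 / y1))


def cell_dv_length(loop: np.ndarray) -> float:
    """DV extent ``max(x) - min(x)`` of an unwrapped vertex loop."""
    x = np.asarray(loop, dtype=float)[:, 0]
    return float(x.max() - x.min())


# ---------------------------------------------------------------------------
# geometry tables


def geometry_table(mesh, state=None) -> pd.DataFrame:
    """Per-cell geometry descriptors of a simulated tissue snapshot.

    Columns: area, perimeter, n_neighbours, elongation, orientation_angle
    (NaN for isotropic cells), dv_length, and, when ``state`` is given,
    clone_id and domain.  The table's ``attrs["units"]`` is
    ``"nondimensional"``; experimental tables should carry ``"um"``.
    """
    f = mesh.flat()
    _, _, _, areas, perims = mesh.edge_geometry()
    rows = []
    for alpha in range(mesh.n_cells):
        loop = mesh.unwrapped_loop(alpha)
        elong = cell_elongation(loop)
        try:
            angle = cell_orientation_angle(loop)
        except ValueError:
            angle = np.nan
        rows.append((elong, angle, cell_dv_length(loop)))
    rows = np.array(rows)
    out = pd.DataFrame(
        {
            "area": areas,
            "perimeter": perims,
            "n_neighbours": f.nsides,
            "elongation": rows[:, 0],
            "orientation_angle": rows[:, 1],
            "dv_length": rows[:, 2],
        }
    )
    if state is not None:
        from .engine import DOMAIN_NAMES

        out["clone_id"] = state.clone
        out["domain"] = [DOMAIN_NAMES[d] for d in state.domain]
    out.attrs["units"] = "nondimensional"
    return out


# ---------------------------------------------------------------------------
# distribution comparison


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic, sup |ECDF_a - ECDF_b|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    grid = np.union1d(a, b)
    ea = np.searchsorted(np.sort(a), grid, side="right") / a.size
    eb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(ea - eb)))


def mean_ecdf_ks(samples_a: Sequence, samples_b: Sequence) -> float:
    """K-S distance between *mean* ECDFs of two replicate collections.

    Each side is a list of replicate samples (e.g. images or runs); their
    ECDFs are averaged pointwise on the merged support grid and the sup
    difference of the averages is returned.  With one replicate per side
    this reduces to :func:`ks_statistic`.
    """
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("need at least one replicate per side")
    arrs_a = [np.sort(np.asarray(s, dtype=float)) for s in samples_a]
    arrs_b = [np.sort(np.asarray(s, dtype=float)) for s in samples_b]
    if any(a.size == 0 for a in arrs_a + arrs_b):
        raise ValueError("samples must be non-empty")
    grid = np.unique(np.concatenate(arrs_a + arrs_b))
    ea = np.mean([np.searchsorted(a, grid, side="right") / a.size for a in arrs_a], axis=0)
    eb = np.mean([np.searchsorted(b, grid, side="right") / b.size for b in arrs_b], axis=0)
    return float(np.max(np.abs(ea - eb)))


def _require_matching_units(sim_tables, ref_tables, area_scale):
    units = {t.attrs.get("units", "nondimensional") for t in [*sim_tables, *ref_tables]}
    if len(units) > 1 and area_scale is None:
        raise ValueError(
            f"tables carry mixed units {units}; supply area_scale "
            f"(e.g. {AREA_UNIT_UM2} um^2 per nondimensional unit)"
        )


def geometry_similarity_score(
    sim_tables: Sequence[pd.DataFrame],
    ref_tables: Sequence[pd.DataFrame],
    area_scale: float | None = None,
) -> float:
    """Screen score for cell-geometry agreement (lower = better).

    Mean of five components: mean-ECDF K-S distances for cell area, cell
    perimeter and neighbour number, plus the absolute differences of the
    standard deviations of area and of perimeter.  The sd components
    compare the reference mean (average of per-replicate sds) with each
    simulated replicate and average those absolute differences.

    ``area_scale`` (reference area units per nondimensional unit) must be
    supplied when the tables carry different units; simulated areas are
    multiplied by it (perimeters by its square root).
    """
    if len(sim_tables) == 0 or len(ref_tables) == 0:
        raise ValueError("need at least one table per side")
    _require_matching_units(sim_tables, ref_tables, area_scale)
    a_scale = 1.0 if area_scale is None else float(area_scale)
    l_scale = np.sqrt(a_scale)

    sim_area = [t["area"].to_numpy() * a_scale for t in sim_tables]
    sim_perim = [t["perimeter"].to_numpy() * l_scale for t in sim_tables]
    sim_nn = [t["n_neighbours"].to_numpy() for t in sim_tables]
    ref_area = [t["area"].to_numpy() for t in ref_tables]
    ref_perim = [t["perimeter"].to_numpy() for t in ref_tables]
    ref_nn = [t["n_neighbours"].to_numpy() for t in ref_tables]

    ks_area = mean_ecdf_ks(sim_area, ref_area)
    ks_perim = mean_ecdf_ks(sim_perim, ref_perim)
    ks_nn = mean_ecdf_ks(sim_nn, ref_nn)

    ref_sd_area = np.mean([np.std(a, ddof=1) for a in ref_area])
    ref_sd_perim = np.mean([np.std(p, ddof=1) for p in ref_perim])
    d_sd_area = np.mean([abs(ref_sd_area - np.std(a, ddof=1)) for a in sim_area])
    d_sd_perim = np.mean([abs(ref_sd_perim - np.std(p, ddof=1)) for p in sim_perim])

    return float(np.mean([ks_area, ks_perim, ks_nn, d_sd_area, d_sd_perim]))


def tissue_fit_score(
    sim_delta_dv: Sequence[float],
    sim_final_aspect: Sequence[float],
    ref_delta_dv: float,
    ref_final_aspect: float,
) -> float:
    """Screen score for whole-tissue growth (lower = better).

    Per run: ``|log(dDV_sim) - log(dDV_ref)| + |aspect_sim - aspect_ref|``,
    averaged over runs.  ``dDV`` is the change in tissue DV length over the
    tracking window; non-positive changes raise.
    """
    d = np.asarray(sim_delta_dv, dtype=float)
    a = np.asarray(sim_final_aspect, dtype=float)
    if d.shape != a.shape or d.size == 0:
        raise ValueError("need matching, non-empty per-run series")
    if np.any(d <= 0) or ref_delta_dv <= 0:
        raise ValueError("DV length change must be positive")
    return float(np.mean(np.abs(np.log(d) - np.log(ref_delta_dv)) + np.abs(a - ref_final_aspect)))


# ---------------------------------------------------------------------------
# clone and rate statistics


def clone_spread_ratio(clones: pd.DataFrame) -> float:
    """Mean AP/DV clone spread ratio with the one-unit correction:
    ``(mean AP extent - 1) / (mean DV extent - 1)``.

    Raises when either corrected mean extent is non-positive (clones too
    small for the corrected ratio).
    """
    if len(clones) == 0:
        raise ValueError("no clones")
    ap = float(clones["ap_extent"].mean()) - 1.0
    dv = float(clones["dv_extent"].mean()) - 1.0
    if ap <= 0 or dv <= 0:
        raise ValueError("clones too small for corrected ratio")
    return ap / dv


def proliferation_rate(d: int, n_mean: float, window_hours: float) -> float:
    """lambda = d / (N~ * dt): divisions per cell per hour."""
    if n_mean <= 0 or window_hours <= 0:
        raise ValueError("mean cell count and window must be positive")
    return d / (n_mean * window_hours)


def effective_growth_rate(n_start: float, n_end: float, window_hours: float) -> float:
    """k = ln(N_end / N_start) / dt, per hour."""
    if n_start <= 0 or n_end <= 0 or window_hours <= 0:
        raise ValueError("counts and window must be positive")
    return float(np.log(n_end / n_start) / window_hours)


def fold_angle(angles) -> np.ndarray:
    """Fold angles in [0, pi) to [0, pi/2] (DV = 0, AP = pi/2)."""
    a = np.mod(np.asarray(angles, dtype=float), np.pi)
    return np.where(a > np.pi / 2, np.pi - a, a)


def t1_statistics(
    t1_frame: pd.DataFrame,
    window_hours: float,
    n_mean: float,
    bins: int = 9,
) -> tuple[float, np.ndarray, np.ndarray]:
    """T1 frequency per cell per hour and the folded new-edge angle
    histogram (angles in [0, pi/2] w.r.t. the DV axis).

    ``t1_frame`` holds the events inside the window; an empty frame gives
    rate 0 and an empty histogram.
    """
    if n_mean <= 0 or window_hours <= 0:
        raise ValueError("mean cell count and window must be positive")
    rate = len(t1_frame) / (n_mean * window_hours)
    if len(t1_frame) == 0:
        return 0.0, np.zeros(bins), np.linspace(0, np.pi / 2, bins + 1)
    folded = fold_angle(t1_frame["new_angle"].to_numpy())
    hist, edges = np.histogram(folded, bins=bins, range=(0, np.pi / 2))
    return float(rate), hist, edges


def division_angle_distribution(divisions: pd.DataFrame, bins: int = 9):
    """Division-axis angles (perpendicular to the recorded new edge),
    folded to [0, pi/2] w.r.t. the DV axis, with a uniformity test.

    Returns ``(angles, histogram, (ks_statistic, p_value))`` where the test
    is a one-sample K-S test against the uniform distribution on
    [0, pi/2].
    """
    if len(divisions) == 0:
        raise ValueError("need at least one division")
    axis = np.mod(divisions["new_edge_angle"].to_numpy() + np.pi / 2, np.pi)
    folded = fold_angle(axis)
    hist, _ = np.histogram(folded, bins=bins, range=(0, np.pi / 2))
    res = sps.kstest(folded, sps.uniform(loc=0, scale=np.pi / 2).cdf)
    return folded, hist, (float(res.statistic), float(res.pvalue))


def lewis_law_fit(table: pd.DataFrame) -> tuple[float, float, float]:
    """Least-squares fit of mean relative cell area against neighbour
    number (Lewis's law): returns (slope, intercept, R^2).

    Areas are normalised by the table mean; needs at least three distinct
    neighbour classes.
    """
    rel = table["area"].to_numpy() / table["area"].mean()
    nn = table["n_neighbours"].to_numpy()
    classes = np.unique(nn)
    if len(classes) < 3:
        raise ValueError("need at least three neighbour classes")
    means = np.array([rel[nn == c].mean() for c in classes])
    res = sps.linregress(classes.astype(float), means)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def aspect_ratio_bounds(mu_dv: float, mu_ap: float) -> tuple[float, float]:
    """(fast-growth, slow-growth) limits of the AP/DV tissue aspect ratio:
    ``(sqrt(mu'/mu''), 1)``.  Rapid growth drives the ratio towards the
    square root of the drag-coefficient ratio; vanishing growth leaves the
    tissue isotropic."""
    if mu_dv <= 0 or mu_ap <= 0:
        raise ValueError("drag coefficients must be positive")
    return float(np.sqrt(mu_dv / mu_ap)), 1.0


# ---------------------------------------------------------------------------
# synthetic geometry fixture


def synthetic_geometry_fixture(
    n_cells: int = 300,
    seed: int = 0,
    mean_area: float = AREA_UNIT_UM2,
    sd_area: float | None = None,
    neighbour_sd: float = 1.5,
    units: str = "um",
) -> pd.DataFrame:
    """Generate a geometry table emulating a segmented apical image of the
    embryonic neuroepithelium, for exercising the screening machinery
    without experimental data (synthetic stand-in, not measured data).

    Areas are Gamma-distributed (unimodal, positive) around ``mean_area``
    (default: the 23 um^2 reference area) with sd defaulting to 35% of the
    mean; perimeters follow a hexagon-like shape factor with noise;
    neighbour counts are discretised around a mean of six with sd
    ``neighbour_sd`` (clipped to [3, 12]); elongations are 1 plus a
    half-normal spread.  Deterministic per seed.
    """
    if mean_area <= 0 or n_cells < 1:
        raise ValueError("mean_area and n_cells must be positive")
    sd_area = 0.35 * mean_area if sd_area is None else sd_area
    if sd_area < 0 or neighbour_sd < 0:
        raise ValueError("spreads must be non-negative")
    rng = np.random.default_rng(seed)
    if sd_area == 0:
        areas = np.full(n_cells, mean_area)
    else:
        shape = (mean_area / sd_area) ** 2
        areas = rng.gamma(shape, mean_area / shape, size=n_cells)
    shape_factor = 3.72  # regular hexagon: perimeter = 3.72 sqrt(area)
    perims = shape_factor * np.sqrt(areas) * (1.0 + 0.05 * rng.standard_normal(n_cells))
    nn = np.clip(np.rint(rng.normal(6.0, neighbour_sd, size=n_cells)), 3, 12).astype(int)
    elong = 1.0 + np.abs(rng.normal(0.0, 0.25, size=n_cells))
    angles = rng.uniform(-np.pi / 2, np.pi / 2, size=n_cells)
    dv_len = np.sqrt(areas) * (1.0 + 0.1 * rng.standard_normal(n_cells))
    out = pd.DataFrame(
        {
            "area": areas,
            "perimeter": perims,
            "n_neighbours": nn,
            "elongation": elong,
            "orientation_angle": angles,
            "dv_length": np.abs(dv_len),
        }
    )
    out.attrs["units"] = units
    return out
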