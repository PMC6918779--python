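"""Tiny (lambda_bar, gamma_bar) screen against a reference geometry table.

Each grid point is simulated briefly and scored with the five-component
geometry-similarity score: mean-ECDF Kolmogorov-Smirnov distances for cell
area, perimeter and neighbour number, plus |delta sd| of area and
perimeter.  Lower is better.  The reference here is a synthetic stand-in
for a segmented-image table (see synthetic_geometry_fixture); substitute
experimental tables for a real screen.
"""
import numpy as np

from neurovertex import (
    NondimensionalParams,
    SimulationConfig,
    classify_phase_region,
    geometry_similarity_score,
    geometry_table,
    run_simulation,
    synthetic_geometry_fixture,
)
from neurovertex.units import AREA_UNIT_UM2

reference = [synthetic_geometry_fixture(n_cells=300, seed=k) for k in range(3)]

print(f"{'lambda_bar':>10} {'gamma_bar':>10} {'region':>7} {'score':>10}")
for lb, gb in [(-0.3, 0.1), (0.075, 0.04), (0.3, 0.01)]:
    region = classify_phase_region(NondimensionalParams(lb, gb))
    try:
        tables = []
        for rep in range(2):
            cfg = SimulationConfig(
                preset=None, lambda_bar=lb, gamma_bar=gb, n_rows=6, n_cols=6,
                equilibration_hours=8.0, run_hours=0.0, dt=0.05,
                seed=50 + rep, audit_every_steps=0,
            )
            tables.append(geometry_table(run_simulation(cfg).mesh))
        score = f"{geometry_similarity_score(tables, reference, area_scale=AREA_UNIT_UM2):10.3f}"
    except RuntimeError:
        score = " collapsed"  # region IV: cells shrink away, no tissue to score
    print(f"{lb:10.3f} {gb:10.3f} {region:>7} {score}")
print("\nPoints inside the solid (epithelial) region of the phase diagram")
print("score best; the score surface is how the working parameter sets")
print("were located in the tension/contractility plane.")
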