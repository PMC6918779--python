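"""Trace the interkinetic-nuclear-movement (IKNM) target area of one cell
through its cycle.

The apicobasal nuclear position rho drops from apical (1) to basal (0)
through G1, stays basal in S, returns in G2 and is apical in M; the target
apical area is (1 + g*t) * f(rho) with f interpolating between 1/2 and 1.
"""
import numpy as np

from neurovertex import CellCyclePhases, apicobasal_position, target_area

phases = CellCyclePhases.from_proportions(t_T_hours=13.0)
g = 1.0 / phases.t_T  # volume doubles over one cycle

print(f"cycle: G1={phases.t_G1:.1f}  S={phases.t_S:.1f}  G2={phases.t_G2:.1f}"
      f"  M={phases.t_M:.1f}  (total {phases.t_T:.1f} time units = 13 h)")
print(f"{'t/t_T':>6} {'phase':>6} {'rho':>6} {'A0':>6}")
for frac in [0.0, 0.25, 0.55, 0.62, 0.80, 0.95, 1.0]:
    t = frac * phases.t_T
    rho = apicobasal_position(t, phases)
    a0 = target_area(t, g, phases)
    phase = ("G1" if frac < 0.55 else "S" if frac < 0.6833 else
             "G2" if frac < 0.95 else "M")
    print(f"{frac:6.2f} {phase:>6} {rho:6.2f} {a0:6.2f}")
print("The target area dips while the nucleus is basal (S phase) and")
print("doubles by the end of the cycle, when the cell divides apically.")
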