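# neurovertex

Vertex-model simulation of the growing apical surface of the embryonic
neural tube, with the analysis layer used to compare simulated tissues to
segmented apical images and clonal data.

The vertebrate neuroepithelium is a pseudostratified epithelium whose
progenitors undergo interkinetic nuclear movement (IKNM): nuclei travel
basally through G1/S and return apically for mitosis, so a cell's apical
footprint breathes with its cycle. Neurons differentiate — most rapidly in
the motor-neuron progenitor (pMN) domain — and are extruded from the
apical plane. Lineage tracing shows clones that are elongated
dorsoventrally (DV) everywhere except the pMN, where clones are small and
round. `neurovertex` implements the mechanical model that explains this:
a 2D vertex model on a torus with energy

    E = Σ_α K/2 (A_α − A_α⁰(t))² + Σ_⟨ij⟩ Λ l_ij + Σ_α Γ/2 L_α²,

overdamped Euler dynamics `μ ṙ_i = −∂E/∂r_i`, a cycle-dependent target
area `A_α⁰(t) = (1 + g t̃) f(ρ)` encoding IKNM, length-weighted division
through opposite edge midpoints, T1 rearrangements (edges under 3% of the
tissue mean are swapped), differentiation as a per-hour hazard that sends
the target area to zero until the cell is extruded, and global growth of
the two torus radii against anisotropic drag (`2μ′N_c Ṙ = −∂E/∂R`,
likewise `μ″` for the AP radius). With DV drag fifty times weaker than AP
drag, growth is DV-biased through oriented T1 intercalation — not through
oriented division — and regions with high differentiation grow more
isotropically. For the model details and every numerical choice see
[docs/methods.md](docs/methods.md).

## Worked example

```python
from neurovertex import SimulationConfig, run_simulation, clone_spread_ratio

cfg = SimulationConfig(preset="V", n_rows=8, n_cols=8, dt=0.05, seed=4,
                       equilibration_hours=5.0, run_hours=20.0,
                       mu_dv=0.02, mu_ap=1.0, audit_every_steps=0)
res = run_simulation(cfg)
print(res.series[["t_hours", "n_cells", "aspect_ratio"]].iloc[[0, -1]])
```

prints (seed 4):

```
      t_hours  n_cells  aspect_ratio
0    0.000000       81      0.824483
41  19.997222      206      0.670094
```

i.e. starting from 81 cells after a short equilibration, the tissue
grows 2.5-fold over 20 h of biological time (13 h cell cycle) while the
AP/DV box ratio falls from 0.82 towards the anisotropic regime — the DV
axis absorbs most of the growth because its drag (`mu_dv = 0.02`) is far
weaker than the AP drag (`mu_ap = 1`). Longer runs (30 h equilibration +
48 h, as in `neurovertex.protocols`) settle near AP/DV ≈ 0.3 with a
measured proliferation rate `λ = d/(Ñ Δt) ≈ 0.05 h⁻¹`.

The `examples/` directory holds one short narrative script per
capability: relaxation, the IKNM target-area cycle, growth anisotropy,
two-domain differentiation with clone tracking, and the
tension/contractility parameter screen. A thin CLI mirrors the library
(`neurovertex run|screen|analyze`, see `neurovertex --help`).

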