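# Model and methods

`neurovertex` simulates the apical surface of the embryonic neural tube —
a pseudostratified neuroepithelium — as a two-dimensional vertex model on
a periodic rectangle (an unwrapped torus), coupled to global growth of the
domain against anisotropic drag, with cell-cycle-driven target areas
(interkinetic nuclear movement, IKNM), stochastic neuronal differentiation
and extrusion, and lineage (clone) tracking.

## Vertex model

Cells are polygons sharing straight edges and trivalent vertices; on the
torus this forces a mean polygon side count of exactly six. The tissue
energy is

    E = Σ_α K/2 (A_α − A_α⁰(t))² + Σ_⟨ij⟩ Λ l_ij + Σ_α Γ/2 L_α²,

with uniform area elasticity `K`, junction tension `Λ` and perimeter
contractility `Γ` (combining the last two terms per cell gives an
effective target perimeter `L₀ = −Λ/2Γ`). Vertices move by overdamped
first-order dynamics `μ dr_i/dt = −∂E/∂r_i`, integrated with an explicit
Euler step; forces are analytic gradients on minimum-image unwrapped
loops, so the periodic seam is invisible to the dynamics (verified against
central finite differences to better than 1e-5 relative).

**Units.** Lengths and areas are nondimensionalised by a reference apical
area of 23 µm² and time by 460 s, so one biological hour is ≈ 7.83 time
units and the 13 h progenitor cell cycle is ≈ 101.7 units.

**Nondimensional parameters.** Mechanics are summarised by
`λ̄ = Λ/(K A⁰^{3/2})` and `γ̄ = Γ/(K A⁰)` evaluated at the reference
cycle-averaged target area `A⁰ = 1.25`. This is the standard
vertex-model convention; the exact printed normalisation is not legible in
the source text, so the convention itself is a documented choice. Six
named working points I–VI (from `(−0.4, 0.14)` to `(0.15, 0.02)`) are
provided as presets; the default working point is V, `(0.075, 0.04)`.

**Phase diagram.** Ground states are classified from the hexagonal
ground-state analysis of the standard model: *soft* (region I) when the
preferred perimeter reaches the regular-hexagon shape index ≈ 3.722 of a
unit-area cell (degenerate ground state, zero shear modulus); *hexagonal
solid* at negative (II) or positive (III) tension; *collapsed* (IV) when
shrinking cells to zero area is energetically favourable (decided
numerically from the per-cell energy profile). Regions II/III are the
epithelial regimes; all six presets classify there. The exact printed
boundary relation is not available, so the classification is validated by
those presets rather than reproduced symbol-for-symbol.

## IKNM target area

Each cell carries a birth time and a growth rate `g` drawn from
`Normal(1/780 min⁻¹, sd = 20% of mean)` (redrawn if non-positive; the
printed "variance of 20% of the mean" is dimensionally inconsistent as a
literal variance, so it is read as a standard deviation). Its target
apical area is

    A⁰(t̃) = (1 + g t̃) · f(ρ(t̃)),

the product of linear volume growth and an apicobasal interpolant of the
nuclear position ρ (1 apical, 0 basal): ρ falls linearly through G1, is 0
through S, rises linearly through G2 and is 1 in M (and for cells waiting
in M beyond the nominal cycle). The interpolant `f(ρ) = (1 + ρ²)/2`
satisfies the stated constraints — f(0) = ½, f(1) = 1, increasing, rising
fastest near the apical surface — and is a configurable hook because the
printed formula is not legible. Default phase proportions (also
stand-ins for an illegible table): G1 55%, S+G2 40% (S one third, G2 two
thirds of that block), M 5% of a 13 h cycle.

## Division

A cell divides when it is in M phase **and** its volume has exceeded a
critical value. Since cell volume is the linearly growing factor
`1 + g t̃` of the target-area model, the default criterion is volume
doubling (`A_c = 2`), reached at `t̃ = 1/g`, i.e. after one nominal cycle;
this keeps the effective proliferation rate at the calibrated
`λ = ln 2/t_T ≈ 0.05 h⁻¹` independently of mechanical compression, and
makes the 11.7 h dividing-cell cycle under 0.1 h⁻¹ differentiation exact.
An alternative criterion compares the instantaneous *apical area* with
`A_c`; it couples division to compression (at preset V the solid tissue
sits at ~0.5–0.6 of its target area, so an area threshold of 2 would
stretch effective cycles to ~1.4 t_T) and is retained as
`DivisionRule(criterion="apical_area")` for comparison.

The division plane joins the midpoint of a randomly chosen edge (selected
with probability proportional to edge length) to the midpoint of the
opposite edge; for odd-sided cells the nearer of the two "mid" candidates
is used, ties broken by the lower edge index. Daughters inherit clone and
domain labels and start fresh cycles with independently drawn growth
rates.

## T1 transitions and extrusion

An edge strictly shorter than 3% of the tissue-mean edge length is
eliminated and replaced by a perpendicular junction of length `l_new`
(default: twice the elimination length — the printed constant is not
legible — configurable in absolute or relative form; end-state T1
frequencies were checked to be insensitive over 1.1–3× the elimination
length). Short edges are processed in ascending length, one swap per edge
per step. If the swap reduces a triangle to a two-sided cell, that cell is
removed: its two parallel junctions merge, its two vertices disappear and
the neighbours are re-stitched (each loses two sides; the operation
subtracts (2, 1, 3) from (N_v, N_c, E)). This removal rule is applied
unconditionally, to differentiating and non-differentiating cells alike:
mechanically squeezed triangles must also be able to extrude, because the
area-elastic restoring force vanishes with cell size while junction
tension does not.

Numerical safeguards: (i) a swap is committed only if some expansion
direction leaves all four touched cells positively oriented, otherwise it
is deferred; (ii) any cell whose area falls below the collapsed scale
(3 × elimination-length²) has all its edges queued for T1 processing, so
cells being crushed between threshold crossings still enter the extrusion
pathway; (iii) a run aborts if the tissue drops below 16 cells, where
cells become comparable to the periodic box and the approximation fails.

## Differentiation

Neuronal differentiation removes progenitors from the apical plane: each
eligible cell is marked with a fixed hazard per unit time (first-order
`rate·dt` per step; a warning fires if `rate·dt > 0.1`), its target area
is set to zero thereafter, it can no longer divide, and its shrinking
footprint is eliminated through the T1/extrusion pathway. In two-domain
simulations a contiguous band covering 30% of the DV length is designated
pMN at the end of equilibration (differentiation 0.1 h⁻¹, dividing-cell
cycle 11.7 h); pMN identity is a lineage label inherited by daughters, not
re-evaluated positionally — the band is only the initial condition, and
its DV extent shrinks as progenitors are lost. Whether a cell that was
mid-M at marking may still divide is unspecified in the source; here the
flag takes precedence (marked cells never divide).

## Tissue-scale growth

The tube is a torus with DV radius `R` (`L_DV = 2πR`) and AP radius `H`.
Each radius grows against a per-cell drag,

    2 μ′ N_c dR/dt = −∂E/∂R,   2 μ″ N_c dH/dt = −∂E/∂H,

where the generalised forces are exact derivatives of the energy under
affine dilation at fixed angular coordinates. After each radius update all
vertices are rescaled affinely (operator splitting with the vertex step).
The exact per-cell drag normalisation is not recoverable from the text;
the form above (total drag proportional to cell number) reproduces the
target whole-tissue anisotropy at the default drags `μ′ = 0.02, μ″ = 1`.
A per-step cap of 0.5% relative change per radius tames the initial
transient (it converts a potentially unstable explicit step into a slower
relaxation towards the same balance point and is inactive once growth
settles). Fast growth drives AP/DV towards `√(μ′/μ″)` ≈ 0.14; vanishing
growth leaves the tissue isotropic — simulated tissues sit between these
limits (≈ 0.3 at the end of the reference protocol).

## Simulation protocol

A run is: build an `n×n` hexagonal tissue (100 or 225 cells; a sheared
honeycomb construction closes periodically for any grid ≥ 2×2 and is
exactly regular for even row counts), jitter vertices slightly to break
the lattice symmetry, equilibrate for 30 h of biological time with full
dynamics but no differentiation, then reset the clock, label every cell a
clone founder, optionally designate the pMN band, and run (typically 48 h)
with event logging. The fixed per-step order is: targets → vertex forces
and Euler step → scale step → differentiation marking → divisions →
T1s/extrusions. All randomness derives from one master seed through named
child streams, so runs are bit-reproducible and subsystems independently
replayable.

**Step size.** The reference discretisation is `dt = 1.017e-3` (1e5 steps
per 13 h cycle). Desk-scale runs use `dt = 0.05` (~2000 steps per cycle):
across `dt ∈ {0.05, 0.02, 0.01}` the measured proliferation rate
(0.048/0.049/0.048 h⁻¹), end-state T1 frequency (0.058/0.059/0.058
cell⁻¹h⁻¹), final aspect ratio (0.32/0.37/0.31) and clone spread ratio
(0.65/0.60/0.64) agree within replicate scatter, so the coarse step does
not bias these observables.

## Analysis layer

Cell elongation is `√(λ_max/λ_min)` of the second-moment matrix of the
cell's vertex coordinates about their centroid; orientation is
`arctan(x₁/y₁)` of the major-axis eigenvector (y₁ the DV component), so 0
means DV-aligned; cell DV length is `max(x) − min(x)` of the unwrapped
loop. Event angles are folded to [0, π/2] (DV = 0) for bias summaries;
full angles stay in the log. Clone AP and DV extents use the
circular-range rule (box length minus the largest empty arc), which makes
seam-straddling clones measure exactly like their translated copies; the
spread ratio subtracts one nondimensional length unit from each mean
extent before dividing. Extents default to *centroid* coordinates — one
point per cell, mirroring the experimental clone data in which each
labelled cell contributes a single coordinate — with vertex bounding boxes
(one cell size larger per axis) as the documented alternative. The pMN
band's DV extent is likewise measured over centroids, the same coordinates
that define band membership, so a freshly designated 30% band measures
exactly 30%.

Distribution comparison uses the Kolmogorov–Smirnov distance between
*mean* ECDFs: replicate ECDFs are averaged pointwise on the merged support
grid before taking the sup. The geometry screen score is the mean of five
components (K–S for area, perimeter and neighbour number, plus the
absolute sd differences of area and perimeter, each sd difference averaged
over simulated replicates against the reference mean); the tissue screen
score is `|Δlog ΔDV| + |Δ aspect|` averaged over runs. Proliferation is
measured as `λ = d/(Ñ Δt)` and cross-checked against
`k = ln(N₁/N₀)/Δt`, which coincide for growth without loss.

`synthetic_geometry_fixture` generates tables that *emulate* segmented
apical images (Gamma-distributed areas around 23 µm², hexagon-like
perimeter scaling, neighbour counts with mean 6 and sd 1.5, elongations
≥ 1). It is a synthetic stand-in: it reproduces the marginal moments and
unimodality of such tables but none of the spatial correlations,
segmentation artefacts or inter-embryo variability of real images, so
screens against it exercise the machinery rather than re-derive the
experimental parameter region.

## Known limitations

* The flat periodic rectangle ignores the curvature of the real tube and
  any apicobasal (3D) shape changes beyond the IKNM area proxy; vertices
  are strictly trivalent (no rosettes).
* Several printed constants of the source study (the exact IKNM
  interpolant, the phase-duration table, `l_new`, the drag normalisation
  and the phase-boundary formulas) are not recoverable from the available
  text; the stand-ins above are isolated behind configuration and flagged
  where they matter.
* With growth active throughout (including equilibration), roughly half of
  the whole-run anisotropy develops before clones are founded; clone
  spread ratios measured over the 48 h tracking window are therefore
  systematically higher (~0.5) than the whole-history tissue ratio (~0.3).
* Population mean target areas measured at run end are ~1.0 rather than
  1.25: with division after one nominal cycle the age distribution is
  young-weighted and any admissible interpolant (½ ≤ f ≤ 1) caps the mean
  near 1; values near 1.25 would require effective cycles of ~1.3–1.4 t_T
  and correspondingly slower proliferation.
* Tissues below ~16 cells (extreme differentiation) abort rather than
  simulate: cells comparable to the box invalidate the minimum-image
  geometry.
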