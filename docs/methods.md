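# Methods

## Model overview

A tissue construct is a set of spherical cell agents with a contact graph.
Ice appears in an unfrozen cell `j` through two independent Poisson
mechanisms: spontaneous intracellular nucleation at rate `J^i(t)` (identical
for all cells — same cell type, no thermal gradients) and propagation from
each frozen neighbour at rate `J^p(t)`, giving the total rate
`J_j = J^i + k_j J^p` with `k_j` the frozen-neighbour count.  In the
non-dimensional clock `τ = ∫ J^i dt` and with `α = J^p/J^i`, cell `j`
freezes at rate `1 + k_j α` per unit `τ`.  Frozen is absorbing.  The model
deliberately excludes extracellular ice, cryoprotectants, solute/heat
transport and per-cell temperature differences; it targets constructs small
enough (≲150 µm) that a uniform temperature is a fair assumption.

## Single-cell biophysics (dimensional time)

Water leaves the cell osmotically during linear cooling `T(t) = T₀ − Bt`:

    dV/dT = (L_p(T) A R T / (B v_w)) · [ln x_w + (ΔH_f/R)(1/T − 1/T_R)]

with `x_w` expressed through volumes as `(V−V_b)/((V−V_b)+v_w v_s n_s)`.
The bracket is the chemical-potential difference between intracellular
water and extracellular water in equilibrium with ice; it vanishes at
osmotic equilibrium, and for a supercooled interior it is positive so the
cell shrinks as `T` falls.  (The sign convention is fixed by this physical
requirement.)  `L_p` follows an Arrhenius law with activation energy
`E_Lp = 342 kJ/mol`, which makes the membrane effectively impermeable below
roughly 260 K — the origin of the strong cooling-rate dependence: slow
cooling dehydrates the cell almost completely, fast cooling (400 K/min)
traps most of the water.

The spontaneous nucleation rate is the diffusion-limited heterogeneous
form

    J^i = A Ω₀ (η₀/η) (T/T_f0)^½ exp[−κ₀/(T³ (T_f−T)²) · (T_f/T_f0)⁴],

where `T_f` is the *current* freezing point of the dehydrating cytosol
(from `1/T_f = 1/T_f0 − (R/ΔH_f) ln x_w`); it also plays the role of the
melting temperature in the supercooling term, so a cell in osmotic
equilibrium (`T_f` tracking just below `T`) never nucleates — the
quasi-static limit.  `η` is the crowding viscosity
`η_w(T)·exp(2.5 φ_s/(1−0.609 φ_s))` with `η_w = 0.139 (T/225−1)^−1.64`,
and `η₀` its value at isotonic composition and `T_f0`.

### Reconstructed parameters (rat hepatocyte defaults)

| symbol | value | provenance |
|---|---|---|
| A | 1.412×10³ µm² | printed; consistent with a 21 µm sphere (4π·10.5² ≈ 1385 µm²), so the printed µm³ unit is read as µm² |
| V_iso | (4/3)π·10.5³ ≈ 4849 µm³ | from the 21 µm hepatocyte diameter |
| n_s | 0.155 mol/L × (1−v_b)·V_iso ≈ 3.68×10⁻¹³ mol | isotonic NaCl in the osmotically active water |
| φ_s | 1 − V_w/V | volume fraction of all non-water material; equals v_b = 0.51 at isotonic and → 1 on dehydration |
| ΔH_f | 5.94124×10¹⁶ µm³·atm/mol, converted once to 6020 J/mol | stored in both unit systems to prevent silent unit bugs |
| T_end | 258.15 K (−15 °C) | packaged protocol endpoint: hepatocyte cryomicroscopy IIF assays are complete by −15 °C, and below ~260 K the membrane is shut anyway |
| κ₀ exponent | treated as a pure number with the printed magnitudes | the literature units (K⁵ s) are dimensionally inconsistent |

Seeding starts at `T₀ = 272.15 K`, slightly below the isotonic cytoplasm
freezing point 272.63 K, with the cell at its full isotonic volume.

### Numerical choices

Dehydration: adaptive explicit Runge–Kutta (rtol 10⁻⁸, atol 10⁻⁶ µm³),
output on a 0.05 K temperature grid; when `V − V_b` falls below
10⁻⁶·V_iso the state is held (fully dehydrated) to avoid the logarithmic
singularity.  `τ` is a composite trapezoid over dimensional time; the
τ↔t↔T maps are linear interpolants of the same grid, with values beyond
the protocol's final τ mapped to "never froze".

## Exact Markov solver

For `N ≤ 20` cells the 2^N frozen-subset states are partitioned into
orbits of the contact graph's automorphism group (supplied per fixture, or
auto-detected via VF2 for `N ≤ 12`).  The per-cell rates `1 + k α` are
symmetric under any edge-preserving permutation, so the chain lumps
exactly; the reduced generator row from class C sums `1 + k_j(S)·α` over
the unfrozen cells of a representative subset S.  The master equation is
solved with the matrix exponential stepped between grid points (`N ≤ 12`)
or LSODA beyond.  Probability conservation is enforced to 10⁻⁹.

The packaged 2×2 fixture treats all four cells as mutual neighbours
(diagonals included) with the dihedral-4 symmetry group, giving six state
classes and the transition rates 4, 2+2α / 1+α, 2+4α, 1+3α.

## Monte Carlo samplers

*Fixed step*: synchronous updates with per-step probability `(1+k α)Δτ`
and `Δτ = ε/((1+nα)N)`, `ε = 0.05` by default — the probability bound for
any IIF event per step.  `n` defaults to the maximum degree of the supplied
graph and can be overridden (the historical 2×2 validation uses `n = 2`,
which yields exactly 1744 steps on τ ∈ [0,1]).  Neighbour counts are taken
at the start of the step, so multiple freezes per step are possible but do
not cascade within a step; the bias this induces is O(ε) and vanishes
against the exact chain at the default ε.  A per-step probability reaching
1 raises a step-size error rather than clamping silently.

*Gillespie*: exact event-driven sampling — waiting time ~ Exponential(Λ)
with `Λ = Σ_unfrozen (1+k_j α)`, event cell chosen proportionally to its
rate, rates updated incrementally.

Each replicate draws from its own RNG stream keyed by (seed, replicate
index), so ensembles are bit-reproducible and order-independent;
re-running any configuration with the same seed reproduces the event logs
exactly.

## Geometry

All constructs are deterministic, in µm, centred on the centroid:

* **disc** — hexagonal (default) or square lattice at spacing
  0.85 × diameter (within the 20%-radius-overlap bound), retained in order
  of distance from the centre; "lattice-free in character, reproducible in
  practice".
* **spheroid** — FCC sites at the same spacing, distance-sorted from the
  centre; 103 cells of 21 µm land at a ≈113 µm bounding diameter.
* **slab** — simple cubic lattice of touching cells (spacing = diameter).

Neighbour rules: *radius* (centre distance < R) and *contact*
(distance ≤ (1+slack)(r_i+r_j), slack 1%).  On a cubic lattice no single
radius yields a maximum degree of 8 (face/diagonal shells give 6, 18, 26),
so the packaged slab uses the face-contact rule (max degree 6); the Moore
neighbourhood (k = 8) arises on the 2-D square monolayer with R just above
the planar diagonal.

## Mechanics

Center-based pairwise forces along the centre line: repulsion
`c_rep (1−d/s)²` inside membrane contact (`s = r_i+r_j`), adhesion
`c_adh (1−d/reach)²` out to `reach = 1.25·s`.  The printed "maximum
adhesion distance 1.25 µm" is read as the standard *relative* reach —
an absolute 1.25 µm would be unreachable for non-overlapping 21 µm
cells; an absolute mode remains available.  Motion is overdamped with drag
1 pN·s/µm (the drag only sets the timescale, not equilibria or detachment
topology), Δt = 1 ms.  Two equal 10.5 µm cells equilibrate at
d* ≈ 0.952·s ≈ 20 µm.

On freezing, the remaining liquid water expands by the factor 1.09 and the
cell volume is fixed: `V_frozen = (V−V_w) + 1.09·V_w`, an exact
bookkeeping identity maintained throughout a run.  Frozen cells stay
mobile rigid spheres by default (a pinned mode exists).  A contact is
severed when the pair separates beyond the adhesive reach; the fissure
report lists severed pairs, per-cell lost contacts and the surviving
attachment components.

In a full experiment the driver integrates the shared dehydration
trajectory once, maps each replicate's freeze clocks τ_j to the first
mechanics grid time with τ(t) ≥ τ_j (the "very close" matching rule made
concrete as grid-first-crossing), and replays one chosen replicate with
expansion events and force stepping.

## What the synthetic constructs do and do not emulate

The generators reproduce the published study conditions in kind — cell
counts, diameters, overlap bound, seeding positions, cooling rates,
α values — but not the original (unpublished) coordinates, so figure-level
results are reproduced as properties (symmetry, ordering, thresholds)
rather than coordinate-exact maps.  Real hepatic tissue adds vasculature,
heterogeneous cell types, extracellular ice and thermal gradients, all out
of scope here; passing tests demonstrate correctness of the stochastic and
mechanical model, not predictive accuracy for whole organs.

## Known limitations

* With the printed nucleation coefficients the prefactor `A·Ω₀ ≈ 15.5 s⁻¹`
  caps the accumulated clock at τ ≈ 2.7 even at 400 K/min, so the
  asymptotic single-cell IIF probability saturates below 100% at every
  tested cooling rate; the 0%-at-slow-cooling limit is reproduced, the
  100%-convergence claim is not attainable with these magnitudes.
* The dehydration plateau at 400 K/min matches the published
  normalized-volume reading (≈0.85 of the isotonic volume; the literal
  water-volume ratio is ≈0.65).
* The α-threshold of the 22-cell disc is resolution-dependent: at 10³
  replicates the α = 50 and α = 200 all-frozen curves differ by a genuine
  cascade-time shift ∝ 1/α in the steep onset region, so the
  3-standard-error comparison selects the top of the α grid rather than 50.
* On the 2387-cell slab, global spontaneous nucleation (unit rate per
  cell) percolates the whole construct around τ ≈ 0.09, so freeze-time
  ordering by distance from a single corner seed holds only for small
  constructs or early times, not construct-wide.
* Replicate counts in the packaged studies (10³–10⁴ for validation curves,
  10² for probability maps) were chosen to keep full runs at interactive
  speed; binomial standard errors are reported everywhere so users can
  scale them up.
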