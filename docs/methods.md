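# Methods

## Model

The package simulates chondrogenic differentiation of mesenchymal stem
cells (MSCs) in a 1D two-layer hydrogel construct: cell-seeded scaffold on
0 < x < 1 (dimensionless), cell-free culture medium on 1 < x < 2, both of
physical height L = 2.4 mm. Cells are immotile, do not proliferate and do
not die over the simulated window (1–10 days); the only cellular process is
threshold-switched differentiation of MSCs into chondrocytes at rate Λ₁
once the MSC receptor-occupancy fraction f exceeds f_d. TGF-β is tracked
through a simplified life cycle: chondrocytes secrete the latent form (c),
which binds to the matrix for storage (b), is chemically activated (a),
and finally binds to cell receptors (occupancies f on MSCs, g on
chondrocytes). Both diffusible pools (c, a) obey no-flux boundaries at
x = 0 and x = 2. Matrix binding and activation coefficients are applied
uniformly over the whole domain, including the medium region — the model
equations carry no spatial masking, and cell-dependent terms vanish where
no cells are present. The receptor equations evolve the *bound masses*
p = f·m and q = g·n rather than the fractions: when an MSC differentiates,
its receptor-bound TGF-β transfers to the newly created chondrocyte, which
the product form expresses as an exact sink/source pair.

Assumptions worth keeping in mind: a single well-mixed receptor pool per
cell with fast internalisation; constant matrix density (absorbed into the
binding rate); activation by chemical interactions only (no
mechanotransduction); a single initial exogenous dose (no replenishment —
a dosing-schedule hook is declared but deliberately unimplemented); 1D
geometry representing the centre of a disc construct.

## Parameters

Dimensional reference values (per-minute rates unless noted):

| symbol | meaning | default |
|---|---|---|
| Λ₁ | differentiation rate above threshold | 6×10⁻³ |
| f_d | receptor-occupancy threshold | 0.01 |
| λ₃ | latent TGF-β secretion (ng/(min·10⁶ cells)) | 1.094×10⁻¹ |
| λ₄ | matrix binding | 10⁻¹ |
| λ₅, λ₇ | latent decay (free, bound) | 6×10⁻³ |
| λ₆ | activation | 6×10⁻² |
| λ₈ | active decay | 0.258 |
| λₘ₉, λₙ₉ | receptor binding (/(min·ng/mL)) | 6×10⁻² |
| λₘ₁₀, λₙ₁₀ | internalisation | 0.25 |
| Ftot, Gtot | max bound mass per cell (ng/10⁶ cells) | 0.623 |
| Dc, Da | diffusivities (m²/min) | 1.278×10⁻⁹ |

Concentrations are scaled by A0 = 1 ng/mL, densities by M0 = 10⁶ cells/mL,
lengths by L and time by 1/Λ₁ (≈ 2.78 h per dimensionless unit). The
solver operates exclusively on the dimensionless set (the
non-dimensionalisation is applied once at scenario construction), which
avoids unit mistakes in the right-hand side. The key dimensionless
groups: active TGF-β decays at rate λ̃₈ = 43 (half-life ≈ 0.016), so its
penetration depth √(D̃/λ̃₈) ≈ 0.03 is small against the layer depth — the
physics behind the strong geometry dependence of culture outcomes.

## Numerics

* **Discretisation.** Vertex-centred uniform grid over [0, 2] including
  both endpoints (default N = 200, h ≈ 0.01); second-order central
  differences with ghost-node reflection for the no-flux boundaries. The
  trapezoidal integral of the discrete Laplacian vanishes identically, so
  the boundaries leak no mass.
* **Layer edges.** Initial layers are built by evaluating step-function
  indicator products at the nodes with the H(0) = 0 convention; an edge
  falling between nodes is effectively snapped to within h/2. This gives
  critical thresholds an O(h) bias (measured: the critical seeding density
  at equal layer heights moves from 0.270 at N = 200 to 0.259 at N = 400),
  which is why threshold searches should not request tolerances far below
  h — the grid-independence test uses 0.01.
* **Stiff integration.** scipy `solve_ivp` BDF with an explicit Jacobian
  sparsity pattern (7×7 dense block per node plus diffusion neighbours for
  c and a), rtol 10⁻⁶, atol 10⁻⁹, max step 0.05 so the integrator cannot
  step over switch ignition. Results are tolerance-controlled, not tied to
  any particular stiff method.
* **Switch handling.** The Heaviside switch is integrated in its exact
  discontinuous form by default, mirroring the reference treatment. An
  optional linear ramp of half-width ε_H on f − f_d is available for
  robustness and convergence studies (the smooth-problem O(h²) test uses
  ε_H = 0.02); it defaults to off.
* **Fraction recovery.** f = p/m is computed only where m exceeds an
  emptiness guard (10⁻⁹ in dimensionless density) and clipped to [0, 1];
  empty nodes carry f = 0. Stiff integrators produce small negative
  undershoots of order the absolute tolerance; the right-hand side clips
  negatives smaller in magnitude than max(10⁻⁷, 10⁻⁶·max|field|) — a
  scale-aware bound, since admissible undershoots grow with the field
  magnitude in high-dose runs (a0 up to 10⁸ in the geometry studies) —
  and aborts on anything larger, surfacing genuine instability instead of
  masking it.
* **Stopping rule and t90.** A terminal integration event tracks
  N(t) = ∫₀^(1−d) n dx against 0.9 × the initial MSC number (both by
  trapezoidal quadrature on the snapped initial state); the run stops at
  the crossing (t90) or at t_end = 20, by which the system is typically
  near steady state — proximity is reported as max |dy/dt| at the terminal
  state, not enforced. A series-based interpolating detector is provided
  for stored trajectories.

## Outcome classification and searches

Runs are labelled **full** if t90 was reached *or* the terminal occupancy
satisfies f ≥ f_d everywhere MSCs remain above 10⁻⁶ (those stragglers are
committed and will differentiate beyond the simulated window); **none** if
the final yield falls below 10⁻⁴ × the initial MSC number; **partial**
otherwise. The yield floor and the emptiness guard are this package's
conventions — the boundary between "none" and "partial" has no canonical
numerical definition — and label robustness to 10× changes in both is part
of the test suite.

Critical thresholds (seeding density n0, exogenous dose a0) are located by
bisection on the full/non-full classification: linear in n0, in log10 for
a0 because the phase boundary spans orders of magnitude. The assumed
monotonicity of outcome in the bisected parameter is validated from the
evaluation log (the none→partial ordering can genuinely break; a violation
attaches a warning rather than failing silently). Phase diagrams are
produced by exhaustive classification over an (a0, n0) grid; aborted cells
are recorded and skipped.

## What the tests do and do not show

The acceptance suite re-derives the study-level results at N = 200: the
critical seeding density ≈ 0.27 for equal layer heights, the critical dose
≈ 203 (this package measures ≈ 217, within the acknowledged parameter
uncertainty band), the ≈ 0.026 partial-yield ceiling, the thin-layer
synergy region, and the t90 spot values ≈ 10.0 / ≈ 9.1 for the combined
strategy. Two reference claims are *not* reproduced and their tests fail
by design rather than being weakened:

1. at n0 = 0.3, d = 0.5 the remaining MSC fraction at t = 8 is 2.4%, not
   < 1% — with t90 = 6.57 and unit-rate decay of committed cells,
   0.1·e^−(8−6.57) ≈ 2.4% is forced, so the reference claim requires an
   earlier t90 than this implementation (or the reference's own switching
   narrative) supports;
2. the dose ladder point a0 = 2000 (n0 = 0.1, d = 0.125) classifies full
   at N = 200 (partial at N ≥ 300): the ignition boundary there is steep
   and carries the O(h) sensitivity discussed above, and the reference
   boundary (between 2000 and 2500) sits inside that sensitivity band.

More generally: all quantitative results in this package are properties of
the idealised 1D model with the reference parameter set. They show the
mechanism — diffusion-limited, threshold-switched ignition — robustly, but
absolute thresholds inherit both the usual biological parameter
uncertainty and a grid bias of order one cell width, and no claim is made
that they transfer quantitatively to a 3D construct with replenished
dosing.

## Problem sizes

Default production runs use N = 200 nodes (the grid at which the reference
results are stated) and t_end = 20. Unit tests exercise the same code
paths at N = 20–100 where grid resolution is not the property under test;
the grid-independence and convergence tests go up to N = 400 and down to
N = 51 respectively. A single N = 200 simulation takes roughly 0.3–5 s on
one CPU; a bisection 8–15 simulations.
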