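# Methods

## Physical setting

A circular perfusion chamber (radius R = 4 mm, fluid height h₁ = 1 mm)
with rectangular access channels (1 mm wide, 2 mm long, full chamber
height) on opposite sides.  Culture medium is an incompressible Newtonian
fluid, ρ = 1020 kg/m³, μ = 1.1 mPa·s.  Gravity is omitted: the system is
isothermal and single-phase, so gravity contributes only a hydrostatic
offset while the pump drives the motion.  At the working flow rate of
170 μL/min the inlet Reynolds number is ≈ 3.35 and the local Reynolds
number stays below 20 everywhere, firmly laminar.

Models 2 and 3 suspend chevron ("herringbone") pillars from the lid,
height h₂ = 0.5 mm, leaving a 0.5 mm gap above the culture surface.  Each
chevron is the union of two rectangles (lengths l and s, width w) joined
at a 60° bend; the segments span their full length starting w/2 behind the
apex so they share a corner block (at a 90° bend with l = s = w this gives
the classic L-shape of area lw + sw − w²).  Published figures of such
devices show the arrays but not pillar coordinates, so the default layout
is generated: staggered rows across the flow axis with alternating apex
direction, row pitch 1.5·(l+s)·sin(θ/2), in-row pitch 1.3·span + 0.2 mm,
trimmed to a 0.1 mm clearance inside the disc and a 0.1 mm minimum
inter-pillar gap.  This yields 7 large chevrons (9.5 mm² footprint) for
Model 2 and 17 small ones (9.0 mm²) for Model 3.  Layouts are data: any
user-supplied list of disjoint in-disc pillars is accepted.

The culture surface is the chamber floor inside the full 4 mm disc by
default (configurable); cells beneath pillars are part of it.

## Inlet waveforms

A roller pump emits one pulse per roller pass, f = RPM·rollers/60.  Each
pulse is a raised cosine of width d·T (duty cycle d) on an optional
baseline b; the amplitude is solved in closed form, A = 2(v̄ − b)/d, so
the cycle average equals the mean velocity v̄ implied by the target flow
(3.61 mm/s for 170 μL/min through the 1 mm inlet).  Defaults — 30 rpm,
2 rollers (f = 1 Hz), d = 0.5, b = 0 — are deliberately generic: pump
catalogues rarely print the effective waveform, so these knobs are exposed
and the study's conclusions are additionally checked across a small sweep
(d = 0.3, 0.7; b = 0.2; 60 rpm).  The sample grid is nudged (never more
than doubled) so pulse edges land on sample points; trapezoid quadrature
of the raised cosine is then exact and the series mean matches the
analytic target to round-off rather than by numeric rescaling.  The
steady comparator is a constant series at v̄ spanning the same window, so
steady and pulsatile conditions are matched in cycle-averaged flow by
construction.

## Flow solver

A staggered-grid (MAC) projection method, explicit in time: hybrid
centred/upwind advection (centred wherever the cell Peclet number is
below 2, which at the study resolutions is everywhere that matters),
second-order viscous diffusion with a quadratic no-slip wall ghost (exact
for parabolic profiles, which keeps the wall-shear extraction
second-order), then a pressure Poisson solve (direct sparse LU, assembled
once per run) and velocity correction.  Boundary conditions: plug inflow,
zero-pressure outlet with zero-gradient velocity, no-slip walls.  The
time step is CFL-derived with a 1 ms cap; every transient starts from a
converged steady solve at the waveform mean (area-averaged floor shear
changing < 10⁻⁶ between successive 100-step windows).  The discrete
divergence residual is checked every step against the configured
tolerance (10⁻⁸ relative; the direct solve leaves ~10⁻¹³), and identical
inputs reproduce bit-identical fields — the solver has no stochastic
component.

Two 2-D reductions replace a full 3-D solve:

* **Plan mode** (culture-surface maps).  Depth-averaged flow in the local
  gap h(x, y) (1 mm open, 0.5 mm under pillars): a Brinkman drag
  −12 μ ū/h² models floor/lid friction, continuity is enforced on the
  volume flux ∇·(h ū) = 0 (the conserved quantity of a variable-gap thin
  film), and floor shear uses the locally-parabolic closure
  τ = 6 μ ū/h.  The drag factor is folded into the face conductance of
  the Poisson operator so the steady balance recovers dp/dx = −12 μ ū/h²
  without operator-splitting bias.  Face gaps at height steps take the
  smaller neighbour, throttling flux the way the narrower passage does.
* **Section mode** (wall-normal structure).  The vertical x–z mid-plane
  through the inlet–outlet axis with pillar cross-sections hanging from
  the lid; floor shear is μ ∂u/∂z from a one-sided second-order stencil
  through the no-slip wall.  Phase-resolved comparisons use this mode:
  the Stokes layer makes wall shear lead the bulk velocity (≈ 2° at
  Womersley number 0.76, more at higher frequency), which is exactly the
  physics behind the acceleration/deceleration asymmetry at matched
  instantaneous inflow.  The plan-mode closure ties shear to the
  instantaneous depth-averaged velocity and cannot represent that lead.

Verification: plane-Poiseuille floor shear within 0.2% of 6 μ ū/h at the
default section resolution (errors strictly decreasing under refinement),
Hele-Shaw pressure gradient within 0.2% of 12 μ ū/h², Womersley
wall-shear amplitude within 0.2% and phase within 0.01° of the complex
closed form μ λ tanh(λa) v̂ / (1 − tanh(λa)/(λa)), λ = √(iω/ν), which is
exact (no series truncation).

## Metrics

TAWSS, OSI and RRT are evaluated per culture-surface cell by trapezoid
quadrature over the final full pump cycle (three cycles are run; the
first two absorb initialisation transients).  OSI of an all-zero history
is defined as 0.  RRT diverges as OSI → 0.5 or TAWSS → 0; the denominator
is floored at 10⁻¹² Pa, capped cells are flagged and excluded from mean
RRT and its quartiles.  Surface summaries use population statistics
(divisor N) over equally-weighted uniform cells, so area weighting
reduces to the arithmetic mean; U% = (1 − CV)·100.  Phase-matched
comparison locates the rising- and falling-flank crossings of the target
inlet velocity in the final cycle by linear interpolation and interpolates
the area-weighted WSS to those instants.

## Synthetic shear histories

The generator emulates cyclic wall-shear vector series with known ground
truth so the metric stage is testable without the solver.  The cycle is
split into equal raised-cosine lobes; a reversal fraction r flips the
direction of the last k = r·K/2 lobes, giving OSI = k/K exactly (r is
quantised to the realisable grid and the realised value reported).
Piecewise-constant magnitudes emit duplicated samples at flip instants so
trapezoid quadrature integrates the jump exactly; smooth sinusoid
modulation supports no reversal.  Per-cell amplitudes and direction
(a common base angle plus per-cell jitter, which the metrics are invariant
to) come from a seeded generator — randomness exists only here, with
default seed 20260108.  What these fixtures do not emulate: spatially
correlated shear patterns, corner eddies, or any geometry-specific
structure; they validate the metric algebra, not the flow.

## Problem sizes

Default study resolution is 0.125 mm in plan (96×66 cells, the finest
pillar segment spanning 4 cells) and 0.05 mm in section (240×20), chosen
so the full six-condition study with phase analysis completes in a few
minutes on one CPU.  Halving the plan cell size to 0.0625 mm changes mean
surface TAWSS by under 2% and leaves every ordinal comparison unchanged;
resolution is a configuration knob.

## Limitations

* The two 2-D reductions bracket, but do not reproduce, 3-D reality.  In
  the single-layer depth-averaged model the flow can detour in-plane
  around a pillar under a single-valued pressure field, whereas in 3-D a
  lid-mounted pillar also displaces flux vertically into the gap beneath
  it.  The model does force flow under the dense arrays (under-pillar
  floor shear runs 1.5–1.9× the open-chamber value), but it understates
  the extra squeeze beneath *large* pillars, so contrasts between the two
  pillared designs (which design has the higher surface-mean WSS or the
  tighter shear distribution) come out as near-ties of order 1–2% and can
  order either way — too close to call at this level of reduction.
* With matched mean flow, a linear (creeping-flow) model yields exactly
  equal cycle-averaged shear fields for steady and pulsatile perfusion,
  and rectification of transient reversals can only raise the pulsatile
  TAWSS above the steady value (here by 0.3–0.7%).  A reported ordering
  of steady above pulsatile is therefore a genuinely 3-D, nonlinear
  effect that this desk-scale model does not capture.
* Directional oscillation on the floor is overstated: surface-mean OSI
  comes out around 10⁻³–10⁻² (growing with pulse frequency), an order
  above typical 3-D values, because decelerating depth-averaged flow
  reverses more readily than a resolved 3-D near-wall layer.
* The full-disc culture ROI includes the port jets and the stagnant rim,
  which dominates the flat chamber's shear heterogeneity; analyses of a
  central sub-region can be configured but are not the default.
* Rigid walls (the < 5 Pa pressure drop makes PDMS compliance
  negligible), no cell layer, plug inlet profile, and no tubing-compliance
  model beyond the raised-cosine pulse abstraction.
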