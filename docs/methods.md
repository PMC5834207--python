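# Methods

## Model

Microtubules are represented as chains of unit vectors, one per 8 nm ring of
tubulin (ℓ = 8 nm, the simulation length unit).  The cell is a closed,
watertight triangular mesh with outward unit vertex normals; everything else
is measured in micrometres.  One time step corresponds to 0.1–0.2 s of real
time (a plus-end growth speed of 3–5 μm/min); the package reports simulated
time as `n_steps · step_seconds` with `step_seconds = 0.12` by default.

Each step applies, in a fixed order:

1. **Nucleation.**  The number of new filaments is binomial with
   `n_trials = area/ℓ²` and success probability `n_p` (default
   4.7·10⁻⁷ per ℓ² per step, i.e. ~2.4–3.4 events per step on the standard
   shapes).  Positions are uniform per unit area (area-weighted triangle
   choice, uniform barycentric coordinates).  The initial direction is a
   uniform *tangential* unit vector by default (see "Design choices").
2. **Minus ends**, in creation order.  A filament that has not yet started
   shrinking does so with probability `n_s` (default 10⁻³) per step; once
   shrinking it loses one minus-end segment per step until it disappears.
3. **Plus ends**, in creation order.  A filament in catastrophe removes one
   plus-end segment.  Otherwise a direction is proposed,

       r' = normalize((1 − r_d − b_d)·r + r_d·u + b_d·b),

   with `u` a fresh isotropic unit vector (normalized 3-D Gaussian),
   `r_d = 0.025` the directional noise and `b` the optional cue direction
   weighted by `b_d`.  Then:
   - if another filament's segment endpoint lies within 25 nm of the tip,
     the encounter is classified by the *line* angle between tip and target
     directions: strictly below α = 40° the tip zippers (adopts the
     sign-adjusted host direction); at or above α it starts a catastrophe
     (no rescue).
   - else, under **strong anchoring** the proposal is projected onto the
     tangent plane at the tip's nearest surface point and the new endpoint
     is snapped back onto the surface (filaments live on the membrane).
     Under **weak anchoring**, if the tip is within 10 nm of the membrane,
     a proposal steeper than α to the local tangent plane starts a
     catastrophe; a shallower proposal is accepted if its endpoint stays
     inside the cell, redrawing `u` up to 32 times otherwise and finally
     falling back to the tangential projection.  Tips farther than 10 nm
     grow freely (an 8 nm step cannot cross a >10 nm gap, so endpoints
     never leave the cell).

Newly created filaments take their first minus/plus updates the step after
nucleation.  Segments added during a step are immediately visible to later
filaments in the same step; segments removed earlier in the step are gone.
A filament whose last segment is removed is deleted.

The circumferential cue is `b = normalize(axis × radial)` at the tip, i.e.
hoop-wise around the long axis of the ellipsoid; on the axis itself the cue
is undefined and the noise-only rule applies.

## Directional persistence

The nominal persistence length is `p = 2ℓ/r_d²` (25.6 μm at defaults, in
the range measured in vivo).  The exact one-step correlation of the growth
rule is

    E[r'·r] = ∫ (a + b c) / sqrt(a² + b² + 2 a b c) dc/2,  a = 1−r_d, b = r_d,

over `c = u·r` uniform on [−1, 1]; for `r_d = 0.025` this evaluates to
0.99978085, which is ≈ `1 − r_d²/3` at low order rather than the commonly
quoted `1 − r_d²/4`.  By conditional isotropy the tangent–tangent
correlation decays exactly as `E[r'·r]^s`, and the test suite checks the
simulated decay against this quadrature value (the `2ℓ/r_d²` figure is kept
as the model's reported parameterization).

## Geometry

Rounded boxes are built by projecting a subdivided box onto the offset
surface of the box shrunk by the corner radius (the Minkowski-sum surface),
so the minimal radius of curvature equals the corner radius by construction
and vertex normals are exact.  Ellipsoids are scaled icospheres with
analytic normals.  The standard shapes are the cube (8.8 μm)³, the "square"
9×9×4.7 μm and the "long" 4.8×4.8×15.6 μm box, sharp (r = 1.3 μm) or smooth
(r = 4.7 μm, capped at half the smallest dimension where the nominal value
would make the shape impossible: 4.4 μm for the cube, 2.35/2.4 μm for
square/long), plus a 10.3×16.8 μm ellipsoid of revolution for cue studies.

Nearest-point queries bin triangles into a uniform grid by bounding box and
search ring by ring outward from the query point's cell; the search stops
once the ring's minimum possible distance exceeds the best hit, which makes
it exact (verified against a brute-force all-triangle scan).  The membrane
is approximated locally by the plane through the nearest point with the
barycentric interpolation of vertex normals; containment is the sign of
`(p − nearest)·normal`, robust for the convex standard shapes.  Weak-anchoring
tips cache the number of steps for which the 10 nm rule provably cannot
trigger (distance decreases at most ℓ per step), which avoids redundant
queries without approximation.

## Engine

Segment endpoints live in a persistent spatial hash of 50 nm buckets (twice
the interaction radius, so the buckets overlapped by the 25 nm query ball
are at most 2 per axis).  The hash is open-addressed with per-bucket
intrusive chains; insertions and removals track every append/remove, and
the table is rebuilt when its load grows.  The nearest candidate wins;
exact distance ties break by lower filament id.  All randomness comes from
one stream seeded per run, consumed in the fixed serial order above, so
identical (seed, parameters, mesh) reproduce trajectories bit for bit.
The stepping loop is a single compiled (numba) kernel over flat arrays;
storage grows geometrically as the network grows.

## Quantification

- **Anisotropy**: per cube of a 3×3×3 grid over the mesh bounding box
  (≈27 cubes), `M = DᵀD/N` over the segment directions in the cube,
  `A = sqrt(3/2 Σ(λᵢ−λ_m)²/Σλᵢ²)` from its eigenvalues; the cell average
  runs over non-empty cubes.  Finer grids give systematically higher
  values, so grid size is part of the metric's definition.
- **Bundled fraction**: a segment is bundled if a segment of a different
  filament lies within 25 nm at a line angle ≤ 40° — the same geometry that
  produces zippering.  The thresholds are exposed as arguments.
- **Membrane distance**: mean nearest-surface distance over all segment
  endpoints (per-filament averaging available as an option), reported
  in nm.
- **Orientation**: per-face histograms select segments within 0.5 μm of a
  face plane, project directions into the face and fold the signed angle to
  the reference axis into (−90°, 90°]; cue response uses |r·axis| over all
  segments.
- **Rendering**: each endpoint adds 1.0 to its voxel and 0.3 to the 6
  face-adjacent voxels (26 available as an option); z-projection sums the
  stack, conserving intensity exactly.

## Design choices

- **Nucleation direction (tangential by default).**  The direction of the
  first segment is not constrained by the growth rules.  With isotropic
  inward initial directions every newborn tip starts within 10 nm of the
  membrane pointing inward, so over a third catastrophe immediately and the
  survivors transit the cell interior, which floods the volume with
  filaments (mean membrane distance ~0.5 μm, bundling ~19% on the sharp
  cube).  Tangential initial directions reproduce the cortical regime this
  model family is known for (mean distance in the 50–250 nm range, bundling
  30–75%) and match nucleation from membrane-bound complexes in planta, so
  they are the default; `nucleation_direction="isotropic"` switches the
  rule.
- "Unit surface" for `n_p` is read as ℓ²; the resulting 2–3.5 events per
  step bracket the expected order of magnitude for these cell sizes.
- Encounters compare undirected lines, so shallow antiparallel contacts
  zipper (bundles of mixed polarity).  The boundary angle α itself
  catastrophes.  A zippered tip re-enters the normal noise rule on later
  steps; while it stays within 25 nm of its host the encounter rule keeps
  re-aligning it, so "permanent" adoption of the host direction emerges
  without a bound state.
- Filament–filament encounters take precedence over the membrane rule
  (their 25 nm radius exceeds the 10 nm membrane distance).
- Both ends may shrink in the same step (treadmilling with a catastrophic
  plus end), removing two segments per step.
- Strong-anchoring endpoints are re-snapped to the surface every step, so
  segment lengths deviate from ℓ by O(ℓ²/R) — below 10⁻³ relative on the
  standard shapes.

## Synthetic data and problem sizes

All inputs are generated: there is no external data.  The generator *is*
the model at its default parameters; what passing tests show is therefore
internal consistency of the implementation plus reproduction of the
network-level regimes (cortical localization, bundling ranges, effect signs,
orientation patterns, cue response) at the sizes below — not agreement with
any particular experimental cell, which would require realistic severing,
branching nucleation and tubulin pools that this model deliberately omits.

The test suite and the acceptance script use desk-scale protocols chosen so
network summaries have reached their plateau (total segment count and the
reported metrics are stable well before the final step):

- cortical localization / bundling: 10,000 steps (~20 simulated minutes),
  3 seeds per sharp shape, weak anchoring;
- anchoring and curvature effect signs: 4,000 steps, 5 seed-pairs on the
  square shape (the growth regime in which the encounter-driven differences
  between anchoring modes are expressed; see Limitations);
- cue response: 4,000 steps on the ellipsoid, `n_p = 2.4·10⁻⁷`,
  `b_d ∈ {0, 0.001, 0.002, 0.01, 0.02}` — the orientation response to the
  cue is established within the first ~2,000 steps, and strongly cued
  networks (few catastrophe-producing encounters) grow very large, so
  longer runs add cost without changing the ordering;
- free-trajectory persistence: 3,000 trajectories × 4,000 steps.

Full-scale replication (50,000 steps, 5 replicates) is available through
`replicate_experiment(..., scale="full")`.

## Limitations

- No severing, branching nucleation, nuclear-envelope nucleation, rescue,
  pause states or limiting tubulin pool; cues are abstract direction
  fields, not mechanical models.
- The only death channels are encounter- and membrane-induced
  catastrophes.  Under strong anchoring (no membrane deaths) the induced
  catastrophe rate falls as the array coarsens into aligned domains, so
  filament number and mean length keep creeping upward over tens of
  thousands of steps; comparisons between anchoring modes are therefore
  made in the growth regime and are protocol-dependent at very late times.
  A spontaneous catastrophe rate or a limiting tubulin pool would provide
  the missing saturation mechanism.
- Containment logic assumes convex (or near-convex) cells.
- The bundling criterion is geometric; the literature has no single
  standard definition, so absolute bundling numbers depend on the 25 nm /
  40° thresholds (kept equal to the interaction geometry).
- Mesh resolution (default 0.4 μm target edge) is part of the numerical
  scheme; surface area converges below 1% when halving the edge length,
  but very coarse meshes distort the membrane interaction.
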