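# Model and methods

## The physical picture

The *Drosophila* embryonic hindgut is a single-layered epithelial tube
that rotates 90° counterclockwise (viewed from the posterior) during
development.  Before the rotation the apical surfaces of its cells are
left-right asymmetric — "chiral" — with cell axes and cell boundaries
tilted leftward relative to the anterior-posterior (AP) axis.  The package
implements a cell-based vertex model of this system: the tube surface is a
closed polyhedral sheet of 452 polygonal cells (plus two cap faces closing
the ends), vertices move in 3D under overdamped gradient dynamics, and an
imposed chiral cell shape, once allowed to relax, converts into a
directional twist of the whole tube through "cell sliding" — anterior
cells shifting circumferentially relative to their posterior neighbours
without junctional remodelling.

## Geometry construction

A rectangle of 15.75 × 28.7 (dimensionless units; the relaxed cell area is
the unit of area) is seeded with 452 hard discs of diameter 0.82 by random
sequential adsorption, periodic in the width direction.  Its Voronoi
diagram is computed on a generator set augmented with periodic copies
(±width) and mirror images across the two height boundaries, which makes
the top/bottom boundary lines exact Voronoi edges and yields the clipped
cells directly.  The rectangle is rolled onto a cylinder of diameter 5.0
(azimuth φ = 2πx/15.75, z = y); the two boundary vertex rings become the
end rings, and two cap polygons close the surface.  All vertices are
3-valent, so the closed surface has exactly V = 2·F_cells = 904 vertices.
The mean polygonal area is ≈ 1 and the enclosed volume ≈ 551 (the
polyhedral surface is inscribed in the cylinder, so it falls ~2% short of
πr²h).

## Potential energy

U = U_L + U_ES + U_EV + U_B, with

* U_L = σ_L Σ_cells Σ_edges w·L — edge tension.  The sum runs per cell
  over that cell's own edges, so each interior edge contributes through
  both incident cells; cap faces contribute no edge energy.  w = 1
  everywhere except on "special" edges during chirality induction.
* U_ES = κ_S Σ_cells (S − S_o)² — area elasticity, lateral cells only.
  The area of a (generally non-planar) polygon is the centroid-fan
  triangulation sum; an alternative definition (magnitude of the summed
  triangle area vectors, `area_mode="vector"`) is implemented and gives
  nearly identical dynamics.
* U_EV = κ_V (V − V_o)² — elasticity of the enclosed tube volume,
  computed by the divergence theorem over all faces including caps.
* U_B = κ_B Σ_rings [(r_j − r̄)² − R²]² — end-ring restraint: ring
  vertices are held near circles of radius R about the instantaneous
  in-plane ring centroid.  Because the quartic constrains only the
  in-plane radius, ring-vertex z is additionally frozen at the cap height,
  which realises the "circles at the tube ends" (leaving z free lets edge
  tension shorten the tube by ~20%, contradicting the fixed tube height).

Defaults: σ_L = 2.2, κ_S = 10.0, κ_V = 0.2, κ_B = 1.0, S_o = 1,
V_o = 566.64, R = 2.5.  Forces are exact analytic gradients (validated
against central finite differences at relative 1e-5) evaluated on a
flattened half-edge structure, and integrated with classical RK4 at fixed
step h = 0.005.  Between topology changes U is non-increasing (gradient
flow), asserted in the tests.

## Chirality induction

Each cell receives a polarity unit vector in its local tangent plane,
rotated by the deflection angle from +z toward −φ (positive deflection =
leftward for an observer outside the tube with anterior up).  The plane
through the cell centroid normal to the polarity crosses exactly two cell
edges — edges roughly parallel to the polarity — and those receive tension
weight w = 3.5.  Dynamics run to t = 5.0 (wild type, +30°) or t = 10.0
(inverted, −35°), the clock is reset to 0, and all weights return to 1.
Degenerate selections (plane through a vertex) are retried with a 1e-9
plane offset and otherwise left isotropic (< 2% of cells).

Induction runs **without** neighbour exchange.  Under sustained strong
contraction a T1-swapped special edge is immediately re-selected and
re-collapsed; with exchange enabled the induction degenerates into a
directed-intercalation treadmill (thousands of events and a tube-scale
counter-rotation during induction, i.e. convergent extension along the
polarity — a mode explicitly absent from this model), and the subsequent
relaxation twists with the wrong handedness.  Imprinting at fixed topology
produces the expected leftward bias of cell axes and edges at t = 0 and
the correct twist handedness on release.

## Reconnection (T1)

When an interior cell-cell edge *becomes* shorter than δ = 0.3 — a
downward crossing; edges already below δ at the start of a run re-arm only
after first recovering above δ — the two 3-valent endpoints exchange
neighbours: the two flanking faces lose the edge, the two side faces gain
it, and the pair is re-seated perpendicular to the old edge in the local
tangent plane at separation 1.05·δ.  V, E, F are conserved; events whose
four incident faces include a cap, or whose flanking face would drop below
3 sides, are skipped.  A per-edge refractory time of 1 time unit prevents
numerical flip-flop at a freshly swapped junction (observed repeat counts
are ≤ 2 per edge pair, so the cooldown is a safeguard rather than an
active control).  Applying the swap twice restores the cell adjacency
exactly and the vertex wiring up to relabelling the two junction vertices.

## Measurements

All planar statistics use the cylinder projection x = (D/2)·φ (rightward
for an outside observer), y = z (anterior up); leftward-slanted structures
have negative angles.  Cells within two cell rows of either end are
excluded (graph distance on face adjacency).

* **Cell axis / deviation** — the polygon's momental ellipse (matched
  second area moments); axis angle = major-axis direction from +y folded
  into (−90°, 90°], deviation = (d_max − d_min)/(d_max + d_min).  A 2:1
  rectangle gives deviation 1/3 exactly.
* **Twist** — mean unwrapped azimuth change of the top ring minus the
  bottom ring, in degrees; positive = counterclockwise viewed from the
  posterior (−z) end, the wild-type handedness.  A helical map φ += c·z
  reports −c·H exactly (calibration test).  A regression-slope variant
  over all vertices is provided as a cross-check.
* **Sliding** — for each axially adjacent (upper, subjacent) cell pair,
  the relative circumferential displacement of the upper cell with the
  subjacent cell as origin; negative = leftward.
* **Boundary tilt** — the angle change of each axial pair's shared
  boundary, classified ccw / unchanged / cw with a 2° tolerance.
* **Intercalation** — an axially adjacent pair in contact that separates
  while an intervening cell becomes adjacent to both; the direction is the
  side the intervening cell came from (undetermined within 1e-6 of the
  midline).

## What the simulations show, and a known quantitative limitation

With the published parameter set the model reproduces, from a fresh random
tessellation: the leftward bias of cell axes and edges at t = 0 and its
dissolution during the twist; a positive (left-handed-screw) twist whose
fast early phase precedes most sliding; strictly opposite twist for the
enantiomorphic protocol; near-zero twist with end rotation blocked while
the edge-angle bias still dissolves by > 90%; sparse neighbour exchange
(tens of distinct junctions out of ~1300 edges); and sliding displacements
whose sign matches the twist at every saved state.

The *magnitude* of the long-time twist is smaller than the published
simulation by roughly a factor of two (≈ 40–45° rather than ≈ 85–90° at
t = 80, with or without reconnection).  The azimuth-change profile along
the tube shows why: in this implementation the creep concentrates in a few
cell rows next to each end ring while the interior rotates almost as a
rigid block, whereas the published tube twists nearly uniformly along its
length.  Extensive variant testing (per-edge vs per-cell-edge tension
counting, both non-planar area definitions, volume target equal to the
measured initial volume, symmetric special-edge weighting, pre-relaxation
before induction, free ring z, energy-gated reconnection) moves this
number by at most a few degrees, so the discrepancy appears to trace to a
modelling detail that the available description does not pin down (the
original polygon-area definition and the exact 3D reconnection geometry
are given only in an unavailable supplement, and the boundary treatment is
described in one sentence).  The handedness, time course shape, variant
ordering (no-reconnection slightly below wild type) and all qualitative
behaviours are insensitive to these choices.

## Problem sizes and determinism

The test suite exercises the physics on a 63-cell miniature tube
(rect 7.875 × 8.0, targets S_o and V_o recomputed from its own initial
state) and runs the full-scale experiments with five wild-type seeds, two
inverted seeds, three fixed-ends seeds and one no-reconnection run
(statistics noisy at a single seed are taken as medians).  The acceptance
script uses three wild-type seeds, one no-reconnection and one inverted
run.  The only randomness is
the disc seeding; everything downstream is deterministic, so a
(configuration, seed) pair replays bit-exactly.
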