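# chiratube

A 3D cell-based vertex model of chiral epithelial tube twisting, with the
polygon-shape, cell-sliding and intercalation quantification that goes with
it.

## The problem

During *Drosophila* embryogenesis the hindgut — a single-layered epithelial
tube — rotates 90° counterclockwise as seen from the posterior.  Before the
rotation its cells are *chiral*: their apical outlines and cell boundaries
tilt leftward relative to the anterior-posterior axis.  `chiratube` models
how that intrinsic cell-shape chirality, once allowed to relax, converts
into a directional twist of the whole tube via **cell sliding** (cells
changing position relative to their posterior neighbours without junctional
remodelling).  It is aimed at tissue-mechanics researchers who want a
self-contained, reproducible implementation of the tube model and its
measurement pipeline.

## The model

The tube surface is a closed polyhedral sheet: 452 polygonal cells from a
periodic Voronoi tessellation of a 15.75 × 28.7 rectangle (hard-disc
seeding, diameter 0.82) rolled onto a cylinder of diameter 5, plus two cap
faces; all 904 vertices are 3-valent.  Vertices follow the overdamped
gradient flow

    dr_i/dt = −∇_i U,
    U = σ_L Σ_α Σ_k w_αk L_αk + κ_S Σ_α (S_α − S_o)² + κ_V (V − V_o)²
        + κ_B Σ_rings [(r_j − r̄)² − R²]²

(edge tension, cell-area elasticity, tube-volume elasticity, end-ring
restraint; σ_L = 2.2, κ_S = 10, κ_V = 0.2, κ_B = 1, S_o = 1,
V_o = 566.64, R = 2.5), integrated by classical RK4 with h = 0.005.
Cell chirality is imprinted by contracting, in every cell, the two edges
crossed by the plane normal to a polarity vector tilted +30° leftward from
the tube axis (weight w = 3.5, run to t = 5), then releasing all weights
and resetting the clock.  When an edge becomes shorter than δ = 0.3 its
vertices exchange neighbours (a T1 transition extended to the curved
surface).  Presets cover the four experiments: `wildtype`, `inverted`
(−35°, induction to t = 10), `no-reconnect` and `fixed-ends`.

Measurements: per-cell axis angle and circular deviation from the momental
ellipse of the cylinder-projected polygon; edge-angle distributions; tube
twist (mean azimuth change of the top ring minus the bottom ring, positive
= counterclockwise from the posterior); per-pair sliding displacement;
boundary-tilt classification; intercalation detection.  See
`docs/methods.md` for definitions, conventions and known limitations.

## Worked example

A miniature 63-cell tube runs in seconds and shows the full pipeline:

```python
import chiratube as ct
from chiratube import analysis

fx = ct.make_fixture(seed=7)                       # 63-cell tube
mesh, _, _ = ct.build_chiral_tube(
    fx["mesh"], ct.ChiralityProtocol(deflection_deg=30.0, w_special=3.5,
                                     t_end_induction=2.0),
    fx["params"])
st = analysis.shape_stats(mesh, fx["diameter"])
cells = st["cells"][st["cells"].included]
print(f"t=0 axis bias {analysis.angle_bias(cells.theta_deg.values):+.2f}, "
      f"mean deviation {cells.deviation.mean():.2f}")

traj = ct.run(mesh, fx["params"], ct.RunOptions(t_end=8.0, save_every=2.0))
for t, tw in zip(traj.times, traj.twist_deg):
    print(f"t={t:4.1f}  twist={tw:6.1f} deg")
```

prints

```
t=0 axis bias +0.29, mean deviation 0.20
t= 0.0  twist=  -0.0 deg
t= 2.0  twist=  19.3 deg
t= 4.0  twist=  34.3 deg
t= 6.0  twist=  41.8 deg
t= 8.0  twist=  47.2 deg
```

The positive bias says most cell axes tilt leftward after induction; on
release the tube twists in the wild-type direction (counterclockwise from
the posterior, a left-handed screw), fast at first and then by slow creep.
The same pipeline at full scale runs from the command line:

```sh
chiratube run --preset wildtype --seed 1 --t-end 80 --out out/wt
chiratube analyze out/wt --out out/wt_tables
```

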