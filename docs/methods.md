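# Methods

## Structural model

A tree is a `TreeModel`: nodes with 3-D coordinates, beams made of
contiguous tapered spans, one homogeneous linear-elastic material, and a
single fully-fixed support at the lowest node. Each span carries a start
and an end cross section; section properties vary continuously along
the span (see *Taper interpolation*). Beams are tagged `trunk` or
`branch`; the connectivity must form a tree (checked with union–find in
`TreeModel.validate`).

Kinematics are 3-D Euler–Bernoulli (shear deformation neglected — slender
members), small displacements, linear elasticity. Each sub-element is a
standard 12-DOF space-frame element (axial, two bending planes,
St-Venant torsion); element local frames are built as
`global z × axis` with a global-x fallback for members within 1° of
vertical. Spans are subdivided (`subdivisions`, default 8) and each
sub-element uses the section properties at its own midpoint, so taper is
resolved piecewise.

**Assumption:** element section axes are taken aligned with the element
local frame; the principal-axis rotation of strongly asymmetric polygon
sections is reported (`principal_angle`) but not applied to the
stiffness. For near-circular stems (Iy ≈ Iz) the error vanishes.

## Cross sections

* `CircularSection(R, r)` — closed forms: A = π(R²−r²),
  I = π(R⁴−r⁴)/4, J = π(R⁴−r⁴)/2.
* `PolygonSection(outer, holes)` — Green's-theorem line integrals give
  A, centroid, Iy = ∫z²dA, Iz = ∫y²dA, Iyz; holes are subtracted via
  orientation. Torsion uses the membrane-analogy approximation
  J ≈ A⁴/(40·Ip), exact to a few percent for convex compact shapes
  (≈7 % for a square against the exact 0.1406·a⁴).
* Extreme fibers: per-quadrant maximum |y|, |z| distances over the
  vertex/fiber cloud; stresses are evaluated on that cloud.
* Shell metrics for hollow sections: wall ratio t/R = (R−r)/R (flagged
  below 0.3) and residual bending-modulus ratio 1 − (r/R)⁴.

### Taper interpolation

Each property (A, Iy, Iz, J) is mapped to a circular-equivalent radius
(A→√(A/π), I→(4I/π)^¼, J→(2J/π)^¼); the radii are interpolated linearly
in the span fraction and mapped back. Endpoints are exact and for
circular ends this reduces to linear-radius taper, so A(s) is quadratic
and the outer radius linear in s.

## Loads

* **LC1** self-weight: line load ρ·g·A(s) along −z per span.
* **LC2** foliage: total foliage mass (measured, or allometric
  a·DBH^b) spread uniformly over the foliage-bearing branches
  (default: all `branch` beams; a subset, e.g. only the upper crown
  branches, can be configured via `foliage_beams`).
* **LC3/LC4** wind along +x/+y: crown force F = q·A_reduced with
  q = ½·ρ_air·v²·c_f, spread uniformly over the foliage branch length;
  each trunk span additionally carries q·d(s) with d the local outer
  diameter.
* Combinations: C1 = LC1+LC2, C2 = C1+LC3, C3 = C1+LC4, unit factors.

Consistent nodal loads (wL/2 forces, ±wL²/12 fixed-end moments) are
used per sub-element with the *Simpson mean* of the intensity over the
sub-element. Because A(s) is quadratic and d(s) linear under the taper
rule, Simpson integration is exact and load resultants match the
continuous integrals to round-off; global equilibrium residuals are
< 1e-10 relative.

## Stress recovery

End forces per sub-element are f_int = k_loc·T·u − f_eq (equivalent
loads removed). Extreme-fiber normal stress
σ = N/A + My·z/Iy − Mz·y/Iz is scanned over the section fiber cloud
(closed form √(My²+Mz²)·c/I when Iy ≈ Iz); tension is positive.
Torsional shear is not combined into σ (normal-stress criterion only).
Risk flags report utilizations |σ|/strength (defaults 20 MPa both
signs — green-wood order of magnitude, configurable) and the t/R flag;
the package never asserts "safe", it reports ratios.

## Imaging

Tomograms are classified by nearest reference color
(intact/decayed/cavity/background); void regions (cavity, plus decayed
under the default `decayed_counts_as_void` policy — a conservative
choice) are vectorized with `skimage.find_contours` at the 0.5 level and
Douglas–Peucker simplification (0.5 px), yielding a `PolygonSection`
with holes. Round-trip cavity-area error is < 1 % at 1000² px. Crown
transparency is the opaque-pixel ratio inside the crown mask; the
reduced area is that ratio times the outline area.

## Parameters (defaults)

| parameter | default | unit |
|---|---|---|
| wood density ρ | 657 | kg/m³ |
| modulus of elasticity E | 8.8e9 | Pa |
| shear modulus G | 0.046·E | Pa |
| air density ρ_air | 1.25 | kg/m³ |
| force coefficient c_f | 1.0 | – |
| reference wind speed v | 33 | m/s |
| reduced crown area | 71.14 | m² |
| foliage mass | 301.61 | kg |
| strength (tension/compression) | 20e6 | Pa |
| subdivisions per span | 8 | – |
| g | 9.80665 | m/s² |

## Synthetic generator

`generate_tree(PAPER_LIKE)` builds a deterministic plane-tree-like
model: a 9 m trunk split into three 4-node chains (B1–B3, basal radius
0.41 m tapering to 0.12 m), ten first-order branches (B4–B13, eight
3-segment and two 4-segment) with seeded direction jitter — 13 beams,
42 nodes, 44 distinct sections. The decayed variant replaces the second
trunk span's sections with hollow ones at r/R = 0.7 (t/R = 0.30).
`solid_twin` removes the hollow for like-for-like comparison.
`generate_tomogram` and `generate_crown_image` produce matching imagery
with known ground truth. The generator covers single-stem broadleaf
topology only; no roots, no second-order branching, no dynamic effects.

## Limitations

Linear statics only (no P-Δ, no dynamics or gust resonance), isotropic
homogeneous wood, rigid clamped base (no root-plate rotation), wind as
a static equivalent pressure, torsion approximate for polygons, section
principal axes assumed aligned with element axes.
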