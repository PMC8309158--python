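# treestatics

Static structural risk assessment of single urban trees with a 3-D
space-frame finite-element model.

A standing tree is idealized as a branched assembly of tapered
Euler–Bernoulli beams clamped at the stem base. Cross sections come
either from closed-form circles/annuli or from arbitrary polygons with
holes — e.g. decay cavities vectorized out of acoustic tomograms. Four
load cases are analysed: wood self-weight (LC1), foliage weight (LC2)
and quasi-static wind along two horizontal axes (LC3/LC4), combined as
C1 = LC1+LC2, C2 = C1+LC3, C3 = C1+LC4. The wind drag force is the
Eurocode-style basic velocity pressure q = ½·ρ_air·v²·c_f times the
crown's transparency-reduced silhouette area. Results are nodal
displacements, extreme-fiber bending + axial stresses along every span,
support reactions, and dimensionless risk indicators (stress
utilization, shell-wall ratio t/R of hollow sections).

## Quick start

```python
import treestatics as ts

model = ts.generate_tree()            # paper-like synthetic plane tree:
                                      # 13 beams, 42 nodes, 44 sections,
                                      # hollow trunk span (t/R = 0.30)
wind  = ts.WindSpec(velocity=33.0, exposed_area=71.14)  # q·A = 48.42 kN

res = ts.TreeStatics(model=model, wind=wind,
                     foliage_mass=301.61, subdivisions=8).fit()
print(res.summary())
res.to_directory("out/")              # CSV tables + summary.json
```

For the bundled synthetic tree this prints (units mm / MPa):

```
C1: max |u| =  37.6 mm at N34;  sigma = +1.39 / -1.42 MPa
C2: max |u| = 894.0 mm at N34;  sigma = +10.25 / -10.36 MPa
C3: max |u| = 683.3 mm at N34;  sigma = +9.14 / -9.54 MPa  (at the hollow span)
```

Wind dominates: the crosswind combination C3 concentrates its stress
extreme exactly at the decayed hollow trunk span (beam B1, span 1),
while gravity alone (C1) stays below 1.5 MPa everywhere. All
utilizations against the default 20 MPa strength stay below 0.52.

## Command line

```bash
treestatics synth --preset paper_like --seed 1 --out fixture/
treestatics validate fixture/model.json
treestatics solve fixture/model.json --exposed-area 71.14 \
    --foliage-mass 301.61 --out results/
treestatics report fixture/model.json --exposed-area 71.14 --foliage-mass 301.61
```

`synth` also writes a synthetic acoustic tomogram (`tomogram.png`) and a
crown-transparency image (`crown.png`); `treestatics.imaging` turns such
images back into polygon sections and reduced crown areas, and
`treestatics.dxf` round-trips sections and skeletons through ASCII DXF.

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch — wind pressure/force,
synthetic-model counts and mass, per-combination displacement/stress
extremes with equilibrium residuals, hollow-section shell metrics,
tomogram/crown image round-trip errors, and closed-form solver
benchmark errors — as JSON `{name: {"value": ..., "n": ...}}`.

See `docs/methods.md` for model assumptions, parameter tables and
numerical choices.
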