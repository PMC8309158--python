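"""Load cases and combinations for static tree analysis.

Four load cases drive the model, mirroring common arboricultural FE
practice:

* **LC1** — wood self-weight, per-span distributed load ρ·g·A(s) acting
  along −z, varying with the tapered section area.
* **LC2** — foliage self-weight: a total crown foliage mass (measured or
  allometric) spread uniformly over the foliage-bearing branches, −z.
* **LC3 / LC4** — quasi-static wind along +x / +y: crown drag force
  F = q·A_reduced (q = ½·ρ_air·v²·c_f, the basic velocity pressure)
  spread uniformly over the foliage branches, plus a trunk line load
  q·d (d = local outer diameter).

Combinations: C1 = LC1+LC2, C2 = C1+LC3, C3 = C1+LC4 with unit factors.
Intensities are kept in N and N/m internally; reports use kN and kN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import G_ACCEL, ModelError, TreeModel

_AXIS = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
         "z": np.array([0, 0, 1.0])}


class LoadError(ValueError):
    pass


@dataclass(frozen=True)
class DistributedLoad:
    """Line load on one span: constant or section-varying intensity (N/m)."""

    beam_id: str
    span_index: int
    direction: tuple[float, float, float]  # unit vector, global frame
    intensity: float                       # N/m (uniform part)
    variation: str = "uniform"             # "uniform" | "linear-with-A" | "width"
    # scale factors for non-uniform variations:
    #   linear-with-A: intensity_at(s) = scale * A(s)   [scale = rho*g]
    #   width:         intensity_at(s) = scale * 2*c(s) [scale = q]
    scale: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise LoadError("direction must be a finite nonzero vector")
        object.__setattr__(self, "direction", tuple((d / n).tolist()))
        if not np.isfinite(self.intensity):
            raise LoadError("non-finite intensity")

    def intensity_at(self, span, s: float) -> float:
        if self.variation == "uniform":
            return self.intensity
        props = span.properties_at(s)
        if self.variation == "linear-with-A":
            return self.scale * props.area
        if self.variation == "width":
            return self.scale * 2.0 * props.c_max
        raise LoadError(f"unknown variation {self.variation!r}")

    def mean_intensity(self, span, s0: float = 0.0, s1: float = 1.0) -> float:
        """Exact segment average of the intensity (Simpson's rule).

        The section area is quadratic and the width linear in the span
        fraction under equivalent-radius interpolation, so Simpson
        integrates both variations exactly; load totals therefore match
        the continuous integrals to round-off.
        """
        if self.variation == "uniform":
            return self.intensity
        return (self.intensity_at(span, s0)
                + 4.0 * self.intensity_at(span, (s0 + s1) / 2)
                + self.intensity_at(span, s1)) / 6.0


@dataclass(frozen=True)
class NodalLoad:
    """Concentrated force (N) and moment (N·m) at a model node."""

    node_id: str
    force: tuple[float, float, float]
    moment: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LoadCase:
    name: str
    loads: tuple[DistributedLoad, ...]
    axis: str  # global axis the case acts along ("x", "y", "z")
    nodal: tuple[NodalLoad, ...] = ()

    def total_force(self, model: TreeModel) -> np.ndarray:
        """Integrated load vector (N) over all spans and nodal loads."""
        total = np.zeros(3)
        for dl in self.loads:
            beam = model.beam(dl.beam_id)
            span = beam.spans[dl.span_index]
            length = span.length(model.nodes)
            total += np.asarray(dl.direction) * dl.mean_intensity(span) * length
        for nl in self.nodal:
            total += np.asarray(nl.force)
        return total


def point_load_case(name: str, node_id: str, force,
                    moment=(0.0, 0.0, 0.0), axis: str = "x") -> LoadCase:
    """Load case with a single concentrated nodal force (testing aid)."""
    return LoadCase(name, (), axis=axis,
                    nodal=(NodalLoad(node_id, tuple(force), tuple(moment)),))


@dataclass(frozen=True)
class LoadCombination:
    name: str
    cases: tuple[LoadCase, ...]
    factors: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.factors:
            object.__setattr__(self, "factors", tuple(1.0 for _ in self.cases))
        if len(self.factors) != len(self.cases):
            raise LoadError("one factor per member case required")


@dataclass(frozen=True)
class WindSpec:
    """Quasi-static wind input: basic velocity pressure parameters."""

    velocity: float                 # m/s, reference wind speed
    air_density: float = 1.25       # kg/m³
    force_coefficient: float = 1.0  # aerodynamic/structural factor c_f
    exposed_area: float | None = None  # m², transparency-reduced crown area

    def __post_init__(self):
        if self.velocity < 0 or self.air_density <= 0 or self.force_coefficient <= 0:
            raise LoadError("wind parameters must be positive")


def wind_pressure(spec: WindSpec) -> float:
    """Basic velocity pressure q = ½·ρ_air·v²·c_f (Pa)."""
    return 0.5 * spec.air_density * spec.velocity**2 * spec.force_coefficient


def wind_force(spec: WindSpec) -> float:
    """Crown drag force F = q·A_reduced (N)."""
    if spec.exposed_area is None or spec.exposed_area < 0:
        raise LoadError("wind force needs a non-negative exposed_area")
    return wind_pressure(spec) * spec.exposed_area


def foliage_mass(dbh: float | None = None, a: float | None = None,
                 b: float | None = None, mass_override: float | None = None) -> float:
    """Crown foliage mass (kg): power-law allometry M = a·DBH^b or override.

    The allometric coefficients are species-specific configuration; a
    direct field-measured mass can be passed instead.
    """
    if mass_override is not None:
        if mass_override < 0:
            raise LoadError("foliage mass must be non-negative")
        return float(mass_override)
    if a is None or b is None:
        raise LoadError("need allometric coefficients a, b or mass_override")
    if a == 0:
        return 0.0
    if dbh is None or dbh <= 0:
        raise LoadError("allometric mass needs a positive DBH")
    return float(a * dbh**b)


def _foliage_beams(model: TreeModel, subset: list[str] | None) -> list:
    if subset is not None:
        beams = [b for b in model.beams if b.id in subset]
    else:
        beams = [b for b in model.beams if b.role == "branch"]
    if not beams:
        raise LoadError("foliage beam subset is empty")
    return beams


def self_weight_case(model: TreeModel) -> LoadCase:
    """LC1: wood self-weight ρ·g·A(s) per span, acting along −z."""
    rho_g = model.material.density * G_ACCEL
    loads = []
    for beam in model.beams:
        for i, span in enumerate(beam.spans):
            mid_a = span.properties_at(0.5).area
            loads.append(DistributedLoad(
                beam_id=beam.id, span_index=i, direction=(0, 0, -1),
                intensity=rho_g * mid_a, variation="linear-with-A",
                scale=rho_g))
    return LoadCase("LC1", tuple(loads), axis="z")


def foliage_case(model: TreeModel, mass: float,
                 foliage_beams: list[str] | None = None) -> LoadCase:
    """LC2: foliage weight spread uniformly over foliage branches, −z."""
    beams = _foliage_beams(model, foliage_beams)
    length = sum(s.length(model.nodes) for b in beams for s in b.spans)
    if length <= 0:
        raise LoadError("zero total branch length")
    w = mass * G_ACCEL / length  # N/m
    loads = tuple(
        DistributedLoad(b.id, i, (0, 0, -1), w)
        for b in beams for i in range(len(b.spans)))
    return LoadCase("LC2", loads, axis="z")


def wind_case(model: TreeModel, spec: WindSpec, axis: str = "x",
              foliage_beams: list[str] | None = None) -> LoadCase:
    """LC3 (+x) or LC4 (+y): crown drag on branches + trunk line load.

    The crown force F = q·A_reduced is distributed uniformly over the
    foliage-bearing branch length; each trunk span additionally carries
    q times its midpoint outer diameter as a horizontal line load.
    """
    if axis not in ("x", "y"):
        raise LoadError("wind axis must be 'x' or 'y'")
    q = wind_pressure(spec)
    f_crown = wind_force(spec)
    beams = _foliage_beams(model, foliage_beams)
    length = sum(s.length(model.nodes) for b in beams for s in b.spans)
    if length <= 0:
        raise LoadError("zero total branch length")
    w_branch = f_crown / length
    direction = tuple(_AXIS[axis].tolist())
    loads = [DistributedLoad(b.id, i, direction, w_branch)
             for b in beams for i in range(len(b.spans))]
    for beam in model.beams:
        if beam.role != "trunk":
            continue
        for i, span in enumerate(beam.spans):
            d_mid = 2.0 * span.properties_at(0.5).c_max
            loads.append(DistributedLoad(beam.id, i, direction, q * d_mid))
    return LoadCase("LC3" if axis == "x" else "LC4", tuple(loads), axis=axis)


_COMBO_DEFS = {"C1": ("LC1", "LC2"), "C2": ("LC1", "LC2", "LC3"),
               "C3": ("LC1", "LC2", "LC4")}


def combine(name: str, cases: dict[str, LoadCase]) -> LoadCombination:
    """Build a named combination (C1/C2/C3) from its member cases."""
    if name not in _COMBO_DEFS:
        raise LoadError(f"unknown combination {name!r}")
    try:
        members = tuple(cases[c] for c in _COMBO_DEFS[name])
    except KeyError as e:
        raise LoadError(f"combination {name} needs case {e}") from e
    return LoadCombination(name, members)


@dataclass(frozen=True)
class LoadConfig:
    """Resolved loading configuration for a full pipeline run."""

    wind: WindSpec
    foliage_mass: float
    foliage_beams: list[str] | None = None
    combinations: tuple[str, ...] = ("C1", "C2", "C3")


def build_cases(model: TreeModel, config: LoadConfig) -> dict[str, LoadCase]:
    cases = {
        "LC1": self_weight_case(model),
        "LC2": foliage_case(model, config.foliage_mass, config.foliage_beams),
    }
    if any(c in ("C2",) for c in config.combinations):
        cases["LC3"] = wind_case(model, config.wind, "x", config.foliage_beams)
    if any(c in ("C3",) for c in config.combinations):
        cases["LC4"] = wind_case(model, config.wind, "y", config.foliage_beams)
    return cases


def build_combinations(model: TreeModel, config: LoadConfig) -> dict[str, LoadCombination]:
    cases = build_cases(model, config)
    return {name: combine(name, cases) for name in config.combinations}
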