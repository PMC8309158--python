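"""Structural data model of a tree: nodes, beams, tapered spans, material.

A tree is represented the way a frame-analysis program sees it: a set of
3D nodes (z up, metres), beams that are ordered chains of nodes, and one
span between each consecutive node pair.  Every span carries a cross
section at each end ("two cross sections method"); properties vary along
the span by equivalent-radius interpolation.  Exactly one node — a
geometric minimum in z — is fully fixed (all six degrees of freedom),
standing in for the root plate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .sections import (CrossSection, interpolate_section, section_from_dict,
                       section_to_dict)

G_ACCEL = 9.80665  # m/s², standard gravity


class ModelError(ValueError):
    """Raised for invalid tree-model input, with a located diagnostic."""


@dataclass(frozen=True)
class Node:
    id: str
    xyz: tuple[float, float, float]

    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass(frozen=True)
class Span:
    """Beam segment between two nodes, with a cross section at each end."""

    start: str
    end: str
    section_start: CrossSection
    section_end: CrossSection

    def length(self, nodes: dict[str, Node]) -> float:
        return float(np.linalg.norm(nodes[self.end].pos() - nodes[self.start].pos()))

    def properties_at(self, s: float):
        return interpolate_section(self.section_start, self.section_end, s)


@dataclass(frozen=True)
class Beam:
    id: str
    spans: tuple[Span, ...]
    role: str  # "trunk" | "branch"

    def __post_init__(self):
        if self.role not in ("trunk", "branch"):
            raise ModelError(f"beam {self.id}: role must be trunk|branch")
        for a, b in zip(self.spans, self.spans[1:]):
            if a.end != b.start:
                raise ModelError(f"beam {self.id}: spans not contiguous at {a.end}")

    @property
    def node_chain(self) -> list[str]:
        return [self.spans[0].start] + [s.end for s in self.spans]


@dataclass(frozen=True)
class Material:
    """Green-wood material: density, longitudinal modulus, shear modulus.

    If the shear modulus is not given it defaults to 0.046·E_L, a
    published G_LT/E_L ratio for basswood.
    """

    density: float          # kg/m³
    E: float                # Pa, longitudinal modulus of elasticity
    G: float | None = None  # Pa, shear modulus (None → 0.046·E)
    strength_compression: float | None = None  # Pa
    strength_tension: float | None = None      # Pa

    def __post_init__(self):
        if self.density < 0 or self.E <= 0:
            raise ModelError("density must be non-negative and E positive")
        if self.G is None:
            object.__setattr__(self, "G", 0.046 * self.E)
        if self.G <= 0:
            raise ModelError("G must be positive")


@dataclass(frozen=True)
class TreeModel:
    nodes: dict[str, Node]
    beams: tuple[Beam, ...]
    material: Material
    support: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> dict:
        """Check all structural invariants; return a count report."""
        if self.support not in self.nodes:
            raise ModelError(f"support node {self.support!r} not defined")
        edges = []
        for beam in self.beams:
            for span in beam.spans:
                for nid in (span.start, span.end):
                    if nid not in self.nodes:
                        raise ModelError(f"beam {beam.id}: unknown node {nid!r}")
                if span.length(self.nodes) <= 0:
                    raise ModelError(
                        f"beam {beam.id}: zero-length span {span.start}-{span.end}")
                edges.append((span.start, span.end))
        if len(edges) != len(self.nodes) - 1:
            raise ModelError(
                f"{len(edges)} spans with {len(self.nodes)} nodes: not a tree "
                "(needs exactly n-1 edges)")
        # connectivity + acyclicity via union-find
        parent = {nid: nid for nid in self.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra == rb:
                raise ModelError(f"cycle detected at span {a}-{b}")
            parent[ra] = rb
        roots = {find(n) for n in self.nodes}
        if len(roots) != 1:
            raise ModelError("connectivity graph is not a single connected tree")
        z_min = min(n.xyz[2] for n in self.nodes.values())
        if self.nodes[self.support].xyz[2] > z_min + 1e-9:
            raise ModelError(f"support node {self.support} is not a minimum in z")
        return {
            "nodes": len(self.nodes),
            "beams": len(self.beams),
            "spans": len(edges),
            "sections": self.section_count(),
        }

    def section_count(self) -> int:
        """Number of distinct section objects referenced by the spans."""
        seen: list = []
        for beam in self.beams:
            for span in beam.spans:
                for sec in (span.section_start, span.section_end):
                    if not any(sec is s for s in seen):
                        seen.append(sec)
        return len(seen)

    # -- geometry queries ----------------------------------------------------

    def beam(self, beam_id: str) -> Beam:
        for b in self.beams:
            if b.id == beam_id:
                return b
        raise ModelError(f"no beam {beam_id!r}")

    def beam_length(self, beam_id: str) -> float:
        return sum(s.length(self.nodes) for s in self.beam(beam_id).spans)

    def total_branch_length(self, subset: list[str] | None = None) -> float:
        """Total length of role=branch beams (optionally a named subset)."""
        total = 0.0
        for beam in self.beams:
            if subset is not None:
                if beam.id in subset:
                    total += sum(s.length(self.nodes) for s in beam.spans)
            elif beam.role == "branch":
                total += sum(s.length(self.nodes) for s in beam.spans)
        return total

    def mass(self) -> float:
        """Wood mass Σ spans ∫ ρ·A(s) ds (kg).

        A(s) is quadratic in the span fraction under equivalent-radius
        interpolation, so Simpson's rule integrates it exactly.
        """
        rho = self.material.density
        total = 0.0
        for beam in self.beams:
            for span in beam.spans:
                a = (span.properties_at(0.0).area
                     + 4.0 * span.properties_at(0.5).area
                     + span.properties_at(1.0).area) / 6.0
                total += rho * a * span.length(self.nodes)
        return total

    # -- editing -------------------------------------------------------------

    def split_beam(self, beam_id: str, position: float) -> "TreeModel":
        """Insert a node at ``position`` (m along the beam); split in two.

        The section at the split is the tapered interpolation at that
        fraction of the containing span; total length and mass are
        conserved.  Splitting exactly at an existing node is rejected.
        """
        beam = self.beam(beam_id)
        total = self.beam_length(beam_id)
        if not 0.0 < position < total:
            raise ModelError(f"split position {position} outside beam {beam_id}")
        acc = 0.0
        for i, span in enumerate(beam.spans):
            ell = span.length(self.nodes)
            if acc + ell >= position - 1e-12:
                local = position - acc
                if local < 1e-9 or abs(local - ell) < 1e-9:
                    raise ModelError("split position coincides with an existing node")
                frac = local / ell
                break
            acc += ell
        else:  # pragma: no cover - guarded by range check
            raise ModelError("split position not located")

        new_id = f"{beam_id}_split"
        k = 0
        while new_id in self.nodes:
            k += 1
            new_id = f"{beam_id}_split{k}"
        p0 = self.nodes[span.start].pos()
        p1 = self.nodes[span.end].pos()
        new_node = Node(new_id, tuple((p0 + frac * (p1 - p0)).tolist()))

        from .sections import CircularSection  # local: avoid cycle at import
        props = span.properties_at(frac)
        sec_a, sec_b = span.section_start, span.section_end
        if isinstance(sec_a, CircularSection) and isinstance(sec_b, CircularSection):
            mid_sec: CrossSection = CircularSection(
                R=(1 - frac) * sec_a.R + frac * sec_b.R,
                r=(1 - frac) * sec_a.r + frac * sec_b.r)
        else:
            mid_sec = CircularSection(R=np.sqrt(props.area / np.pi))

        first = beam.spans[:i] + (
            Span(span.start, new_id, span.section_start, mid_sec),)
        second = (Span(new_id, span.end, mid_sec, span.section_end),) + beam.spans[i + 1:]
        beam_a = Beam(f"{beam_id}a", first, beam.role)
        beam_b = Beam(f"{beam_id}b", second, beam.role)
        beams = tuple(b for b in self.beams if b.id != beam_id) + (beam_a, beam_b)
        nodes = dict(self.nodes)
        nodes[new_id] = new_node
        return replace(self, nodes=nodes, beams=beams)


def total_branch_length(model: TreeModel, subset: list[str] | None = None) -> float:
    return model.total_branch_length(subset)


# ---------------------------------------------------------------------------
# Model file I/O (JSON / YAML)
# ---------------------------------------------------------------------------

def model_to_dict(model: TreeModel) -> dict:
    sec_defs: dict[int, str] = {}
    sections: dict[str, dict] = {}

    def ref(sec: CrossSection) -> str:
        key = id(sec)
        if key not in sec_defs:
            name = f"S{len(sec_defs) + 1}"
            sec_defs[key] = name
            sections[name] = section_to_dict(sec)
        return sec_defs[key]

    beams = []
    for beam in model.beams:
        beams.append({
            "id": beam.id,
            "role": beam.role,
            "nodes": beam.node_chain,
            # one [start, end] section pair per span: sections may change
            # discontinuously at a node (e.g. where a decayed span begins)
            "sections": [[ref(s.section_start), ref(s.section_end)]
                         for s in beam.spans],
        })
    mat = model.material
    return {
        "nodes": [{"id": n.id, "xyz": list(n.xyz)} for n in model.nodes.values()],
        "beams": beams,
        "sections": sections,
        "material": {
            "density": mat.density, "E": mat.E, "G": mat.G,
            "strength_compression": mat.strength_compression,
            "strength_tension": mat.strength_tension,
        },
        "support": model.support,
        "meta": model.meta,
    }


def model_from_dict(data: dict) -> TreeModel:
    nodes: dict[str, Node] = {}
    for nd in data["nodes"]:
        nid = str(nd["id"])
        if nid in nodes:
            raise ModelError(f"duplicate node id {nid!r}")
        xyz = tuple(float(v) for v in nd["xyz"])
        if len(xyz) != 3 or not all(np.isfinite(xyz)):
            raise ModelError(f"node {nid!r}: bad coordinates {nd['xyz']}")
        nodes[nid] = Node(nid, xyz)

    sec_objs = {name: section_from_dict(d) for name, d in data.get("sections", {}).items()}

    beams = []
    for bd in data["beams"]:
        chain = [str(n) for n in bd["nodes"]]
        refs = bd["sections"]
        n_spans = len(chain) - 1
        # accepted forms: per-node list of refs, or per-span [start, end] pairs
        if refs and isinstance(refs[0], (list, tuple)):
            if len(refs) != n_spans:
                raise ModelError(
                    f"beam {bd['id']}: {len(refs)} section pairs for "
                    f"{n_spans} spans")
            pairs = refs
        else:
            if len(refs) != len(chain):
                raise ModelError(
                    f"beam {bd['id']}: {len(refs)} section refs for "
                    f"{len(chain)} nodes")
            pairs = [(refs[i], refs[i + 1]) for i in range(n_spans)]
        try:
            spans = tuple(
                Span(chain[i], chain[i + 1], sec_objs[a], sec_objs[b])
                for i, (a, b) in enumerate(pairs))
        except KeyError as e:
            raise ModelError(f"beam {bd['id']}: missing section {e}") from e
        beams.append(Beam(str(bd["id"]), spans, bd.get("role", "branch")))

    m = data["material"]
    material = Material(
        density=float(m["density"]), E=float(m["E"]),
        G=None if m.get("G") is None else float(m["G"]),
        strength_compression=m.get("strength_compression"),
        strength_tension=m.get("strength_tension"))
    return TreeModel(nodes=nodes, beams=tuple(beams), material=material,
                     support=str(data["support"]), meta=data.get("meta", {}))


def load_model(path: str | Path) -> TreeModel:
    """Load and fully validate a JSON or YAML tree-model file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return model_from_dict(data)


def save_model(model: TreeModel, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=True))
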