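"""Synthetic study inputs: tree skeletons, tomogram rasters, crown images.

No real surveyed geometry ships with the package, so every pipeline stage
is exercised against generated stand-ins:

* parametric branching skeletons with tapering circular sections and an
  optional decayed (hollow) trunk span,
* tomogram-like rasters in the standard green/red/blue palette,
* crown silhouette images with a prescribed transparency fraction.

The ``paper_like`` preset mirrors the published study's model scale — 13
beams (3 trunk + 10 branches) joined at 42 nodes through 44 distinct
cross sections, with the hollow span between the 2nd and 3rd trunk node —
so qualitative findings (wind-dominated displacements, stress
concentration at the decayed span) can be reproduced on a geometry of the
same character.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .imaging import PALETTE, CrownImage
from .model import Beam, Material, Node, Span, TreeModel
from .sections import CircularSection


class RecipeError(ValueError):
    pass


@dataclass(frozen=True)
class DecaySpec:
    """Hollow span: which trunk span decays and how much of the radius."""

    beam_id: str = "B1"
    span_index: int = 1       # between the 2nd and 3rd node of the beam
    hollow_fraction: float = 0.7  # r/R of the cavity

    def __post_init__(self):
        if not 0.0 <= self.hollow_fraction < 1.0:
            raise RecipeError("hollow_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TreeRecipe:
    """Parametric description of a synthetic tree skeleton."""

    trunk_height: float = 9.0         # m, total trunk length
    basal_radius: float = 0.41        # m
    trunk_top_radius: float = 0.12    # m
    branch_count: int = 10
    branch_length: float = 5.0        # m, mean total branch length
    branch_tip_radius: float = 0.03   # m
    branch_elevation_deg: float = 40.0  # mean elevation above horizontal
    jitter: float = 0.15              # relative geometric jitter
    decay: DecaySpec | None = field(default_factory=DecaySpec)
    density: float = 657.0            # kg/m³ (green lime wood)
    E: float = 8.8e9                  # Pa, longitudinal modulus
    seed: int = 0

    def __post_init__(self):
        if self.trunk_height <= 0 or self.basal_radius <= 0:
            raise RecipeError("trunk dimensions must be positive")
        if self.trunk_top_radius >= self.basal_radius:
            raise RecipeError("trunk must taper (top radius < basal radius)")


PAPER_LIKE = TreeRecipe()
DECAYED_TRUNK = TreeRecipe(decay=DecaySpec(hollow_fraction=0.8))


def minimal_cantilever(length: float = 10.0, radius: float = 0.15,
                       density: float = 657.0, E: float = 8.8e9) -> TreeModel:
    """Smallest valid model: a vertical prismatic pole, fixed at the base."""
    sec = CircularSection(R=radius)
    nodes = {"N1": Node("N1", (0.0, 0.0, 0.0)),
             "N2": Node("N2", (0.0, 0.0, length))}
    beam = Beam("B1", (Span("N1", "N2", sec, sec),), "trunk")
    return TreeModel(nodes=nodes, beams=(beam,),
                     material=Material(density=density, E=E), support="N1",
                     meta={"preset": "minimal_cantilever"})


def generate_tree(recipe: TreeRecipe = PAPER_LIKE) -> TreeModel:
    """Build a valid TreeModel from a recipe (deterministic per seed).

    Topology: three trunk beams stacked vertically (B1–B3, 4+4+4 node
    chain), ten branches (B4–B13) fanned around the trunk; radii taper
    monotonically from the base to every tip.  With the default recipe the
    counts are exactly 13 beams / 42 nodes / 44 distinct sections.
    """
    rng = np.random.default_rng(recipe.seed)
    nodes: dict[str, Node] = {}
    counter = [0]

    def new_node(xyz) -> str:
        counter[0] += 1
        nid = f"N{counter[0]}"
        nodes[nid] = Node(nid, tuple(float(v) for v in xyz))
        return nid

    def trunk_radius(z: float) -> float:
        f = min(max(z / recipe.trunk_height, 0.0), 1.0)
        return recipe.basal_radius + f * (recipe.trunk_top_radius
                                          - recipe.basal_radius)

    # --- trunk: B1/B2/B3, 4-node chains, 3 m each ---------------------------
    jit = recipe.jitter
    trunk_ids: list[str] = [new_node((0.0, 0.0, 0.0))]
    z_levels = np.linspace(0, recipe.trunk_height, 10)  # N1..N10 heights
    xy = np.zeros(2)
    for z in z_levels[1:]:
        xy = xy + rng.normal(0, 0.05 * jit * recipe.trunk_height, 2)
        trunk_ids.append(new_node((xy[0], xy[1], float(z))))

    trunk_secs = {nid: CircularSection(R=trunk_radius(nodes[nid].xyz[2]))
                  for nid in trunk_ids}

    def chain_spans(chain: list[str], secs: dict) -> tuple[Span, ...]:
        return tuple(Span(a, b, secs[a], secs[b])
                     for a, b in zip(chain, chain[1:]))

    beams: list[Beam] = []
    trunk_chains = [trunk_ids[0:4], trunk_ids[3:7], trunk_ids[6:10]]
    for i, chain in enumerate(trunk_chains, start=1):
        beams.append(Beam(f"B{i}", chain_spans(chain, trunk_secs), "trunk"))

    # decayed hollow span
    if recipe.decay is not None:
        d = recipe.decay
        target = next(b for b in beams if b.id == d.beam_id)
        if d.span_index >= len(target.spans):
            raise RecipeError(f"decay span {d.span_index} outside {d.beam_id}")
        spans = list(target.spans)
        old = spans[d.span_index]
        hollow = {nid: CircularSection(R=trunk_secs[nid].R,
                                       r=d.hollow_fraction * trunk_secs[nid].R)
                  for nid in (old.start, old.end)}
        spans[d.span_index] = Span(old.start, old.end,
                                   hollow[old.start], hollow[old.end])
        beams[beams.index(target)] = Beam(target.id, tuple(spans), target.role)

    # --- branches B4..B13 ----------------------------------------------------
    # eight 4-node and two 5-node chains → 8·3 + 2·4 = 32 new nodes
    seg_counts = [3] * (recipe.branch_count - 2) + [4, 4]
    attach_pool = trunk_ids[2:]  # N3..N10
    for k in range(recipe.branch_count):
        attach = attach_pool[k % len(attach_pool)]
        azimuth = 2 * math.pi * (k / recipe.branch_count) + rng.normal(0, jit)
        elev = math.radians(recipe.branch_elevation_deg
                            + rng.normal(0, 8 * jit / 0.15))
        direction = np.array([math.cos(azimuth) * math.cos(elev),
                              math.sin(azimuth) * math.cos(elev),
                              math.sin(elev)])
        n_seg = seg_counts[k]
        total_len = recipe.branch_length * (1 + rng.normal(0, jit))
        total_len = max(total_len, 1.0)
        seg_len = total_len / n_seg
        chain = [attach]
        pos = nodes[attach].pos()
        for j in range(n_seg):
            bend = rng.normal(0, 0.25 * jit, 3)
            step = direction + bend
            step[2] = abs(step[2])  # branches keep rising
            step /= np.linalg.norm(step)
            pos = pos + step * seg_len
            chain.append(new_node(pos))
            direction = step
        base_r = trunk_secs[attach].R
        secs = {attach: trunk_secs[attach]}  # shared junction section
        for j, nid in enumerate(chain[1:], start=1):
            f = j / n_seg
            secs[nid] = CircularSection(
                R=base_r + f * (recipe.branch_tip_radius - base_r))
        beams.append(Beam(f"B{4 + k}", chain_spans(chain, secs), "branch"))

    coords = np.array([nodes[n].pos() for n in nodes])
    dmat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 0.01:
        raise RecipeError(
            "recipe produced (near-)coincident nodes; try another seed")

    model = TreeModel(
        nodes=nodes, beams=tuple(beams),
        material=Material(density=recipe.density, E=recipe.E),
        support="N1",
        meta={"preset": "synthetic", "seed": recipe.seed,
              "decay": None if recipe.decay is None else {
                  "beam": recipe.decay.beam_id,
                  "span": recipe.decay.span_index,
                  "hollow_fraction": recipe.decay.hollow_fraction}})
    return model


def solid_twin(model: TreeModel) -> TreeModel:
    """Same geometry with every hollow section replaced by its solid outer."""
    beams = []
    for beam in model.beams:
        spans = []
        for span in beam.spans:
            def solidify(sec):
                if isinstance(sec, CircularSection) and sec.r > 0:
                    return CircularSection(R=sec.R)
                return sec
            spans.append(Span(span.start, span.end,
                              solidify(span.section_start),
                              solidify(span.section_end)))
        beams.append(Beam(beam.id, tuple(spans), beam.role))
    return TreeModel(nodes=model.nodes, beams=tuple(beams),
                     material=model.material, support=model.support,
                     meta={**model.meta, "solidified": True})


# ---------------------------------------------------------------------------
# Raster generators
# ---------------------------------------------------------------------------

def generate_tomogram(outer_radius_m: float, size: int = 400,
                      cavity_fraction: float = 0.0,
                      cavity_offset: float = 0.0,
                      decayed_ring: float = 0.0,
                      noise: float = 0.0, seed: int = 0) -> tuple[np.ndarray, float]:
    """Tomogram-like RGB raster of a circular stem slice.

    Returns ``(rgb array, scale m/px)``.  ``cavity_fraction`` is the
    cavity radius as a fraction of the stem radius; ``cavity_offset``
    shifts its centre (fraction of stem radius); ``decayed_ring`` adds a
    red annulus of that relative thickness around the cavity; ``noise``
    perturbs the class boundaries (std in pixels).
    """
    if not 0.0 <= cavity_fraction < 1.0:
        raise RecipeError("cavity_fraction must lie in [0, 1)")
    if cavity_fraction + abs(cavity_offset) >= 0.98:
        raise RecipeError("cavity larger than (or escaping) the section")
    rng = np.random.default_rng(seed)
    r_px = 0.45 * size
    scale = outer_radius_m / r_px
    cy = cx = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    rad = np.hypot(yy - cy, xx - cx)
    if noise > 0:
        rad = rad + rng.normal(0, noise, rad.shape)
    rgb = np.full((size, size, 3), PALETTE["background"], np.uint8)
    stem = rad <= r_px
    rgb[stem] = PALETTE["intact"]
    if cavity_fraction > 0:
        ccx = cx + cavity_offset * r_px
        crad = np.hypot(yy - cy, xx - ccx)
        if noise > 0:
            crad = crad + rng.normal(0, noise, crad.shape)
        cav_px = cavity_fraction * r_px
        if decayed_ring > 0:
            ring = (crad <= cav_px * (1 + decayed_ring)) & stem
            rgb[ring] = PALETTE["decayed"]
        rgb[(crad <= cav_px) & stem] = PALETTE["cavity"]
    return rgb, scale


def generate_crown_image(outline: str = "ellipse", transparency: float = 0.29,
                         size: tuple[int, int] = (1000, 1000),
                         outline_area: float = 100.2,
                         seed: int = 0) -> CrownImage:
    """Crown silhouette with Bernoulli(1−p) opaque pixels inside the mask.

    ``transparency`` is the expected fraction of see-through pixels; the
    outline area (m²) is carried as metadata for the wind-area reduction.
    """
    if not 0.0 <= transparency <= 1.0:
        raise RecipeError("transparency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = size
    if outline == "ellipse":
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (((yy - (h - 1) / 2) / (0.48 * h)) ** 2
                + ((xx - (w - 1) / 2) / (0.48 * w)) ** 2) <= 1.0
    elif outline == "full":
        mask = np.ones((h, w), bool)
    else:
        raise RecipeError(f"unknown outline {outline!r}")
    opaque = np.zeros((h, w), bool)
    opaque[mask] = rng.random(int(mask.sum())) >= transparency
    return CrownImage(opaque=opaque, mask=mask, outline_area=outline_area)


def save_rgb_png(rgb: np.ndarray, path) -> None:
    Image.fromarray(rgb).save(path)


def save_crown_png(img: CrownImage, path) -> None:
    arr = np.full(img.opaque.shape, 255, np.uint8)
    arr[img.opaque & img.mask] = 0
    Image.fromarray(arr).save(path)
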