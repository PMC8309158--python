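"""Cross-section geometry: areas, second moments, torsion and decay-risk metrics.

Two section families cover what a tree-statics model needs:

* :class:`PolygonSection` — an arbitrary closed outer ring with optional
  cavity holes, as traced from an acoustic tomogram or drawn in CAD.
  Properties are evaluated with Green's-theorem line integrals (the
  shoelace family of formulas), holes subtracted.
* :class:`CircularSection` — solid or hollow circle with closed-form
  properties, the shape of an undamaged (or uniformly decayed) stem slice.

Section-plane axes are (y, z): y to the right, z up, matching the local
bending axes of the beam elements that consume these properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


class SectionError(ValueError):
    """Raised for geometrically invalid section input."""


# ---------------------------------------------------------------------------
# Green's-theorem primitives on a single ring
# ---------------------------------------------------------------------------

def _as_ring(ring) -> np.ndarray:
    pts = np.asarray(ring, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise SectionError("a ring needs at least 3 (y, z) vertices")
    if not np.all(np.isfinite(pts)):
        raise SectionError("ring contains non-finite coordinates")
    # drop an explicit closing vertex
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise SectionError("degenerate ring after closing-vertex removal")
    return pts


def _signed_area(pts: np.ndarray) -> float:
    y, z = pts[:, 0], pts[:, 1]
    y1, z1 = np.roll(y, -1), np.roll(z, -1)
    return 0.5 * float(np.sum(y * z1 - y1 * z))


def polygon_area_centroid(ring) -> tuple[float, tuple[float, float]]:
    """Area and centroid of a closed ring via the shoelace formula.

    The signed area is converted to a positive area; self-intersecting
    rings are rejected.  Returns ``(area, (cy, cz))``.
    """
    pts = _as_ring(ring)
    if not _ShapelyPolygon(pts).is_valid:
        raise SectionError("self-intersecting or otherwise invalid ring")
    a = _signed_area(pts)
    if abs(a) < 1e-16:
        raise SectionError("zero-area ring")
    y, z = pts[:, 0], pts[:, 1]
    y1, z1 = np.roll(y, -1), np.roll(z, -1)
    cross = y * z1 - y1 * z
    cy = float(np.sum((y + y1) * cross) / (6.0 * a))
    cz = float(np.sum((z + z1) * cross) / (6.0 * a))
    return abs(a), (cy, cz)


def _ring_moments_origin(pts: np.ndarray) -> tuple[float, float, float, float]:
    """Signed (A, Iy, Iz, Iyz) about the coordinate origin.

    Iy = ∫ z² dA,  Iz = ∫ y² dA,  Iyz = ∫ y·z dA — all signed with the
    ring orientation, so CW holes subtract naturally.
    """
    y, z = pts[:, 0], pts[:, 1]
    y1, z1 = np.roll(y, -1), np.roll(z, -1)
    cross = y * z1 - y1 * z
    a = 0.5 * float(np.sum(cross))
    iy = float(np.sum((z * z + z * z1 + z1 * z1) * cross)) / 12.0
    iz = float(np.sum((y * y + y * y1 + y1 * y1) * cross)) / 12.0
    iyz = float(np.sum((y * z1 + 2 * y * z + 2 * y1 * z1 + y1 * z) * cross)) / 24.0
    return a, iy, iz, iyz


def _normalize_orientation(pts: np.ndarray, ccw: bool) -> np.ndarray:
    if (_signed_area(pts) > 0) != ccw:
        return pts[::-1].copy()
    return pts


# ---------------------------------------------------------------------------
# Section protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionProperties:
    """Centroidal properties of a cross section, in the principal frame.

    Units: m² for area, m⁴ for moments, m for fiber distances.  The
    extreme-fiber distances are offsets from the centroid along the two
    principal axes (+/− per axis), all non-negative.
    """

    area: float
    centroid: tuple[float, float]
    Iy: float
    Iz: float
    Iyz: float
    J: float
    c_y_pos: float
    c_y_neg: float
    c_z_pos: float
    c_z_neg: float
    principal_angle: float = 0.0
    fibers: tuple[tuple[float, float], ...] = ()  # (y, z) in principal frame

    @property
    def polar(self) -> float:
        return self.Iy + self.Iz

    def equivalent_radius(self) -> float:
        """Radius of the solid circle with the same area."""
        return math.sqrt(self.area / math.pi)


class CrossSection:
    """Common interface: every section exposes .properties()."""

    def properties(self) -> SectionProperties:  # pragma: no cover - abstract
        raise NotImplementedError

    # convenience pass-throughs
    @property
    def area(self) -> float:
        return self.properties().area

    @property
    def outer_radius_estimate(self) -> float:
        """Largest extreme-fiber distance — used as projected half-width."""
        p = self.properties()
        return max(p.c_y_pos, p.c_y_neg, p.c_z_pos, p.c_z_neg)


@dataclass(frozen=True)
class CircularSection(CrossSection):
    """Solid or hollow circular section (outer radius R, inner radius r)."""

    R: float
    r: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r < self.R):
            raise SectionError(f"need 0 <= r < R, got r={self.r}, R={self.R}")

    def properties(self) -> SectionProperties:
        R, r = self.R, self.r
        area = math.pi * (R * R - r * r)
        i = math.pi * (R**4 - r**4) / 4.0
        j = math.pi * (R**4 - r**4) / 2.0
        fibers = tuple(
            (R * math.cos(t), R * math.sin(t))
            for t in np.linspace(0.0, 2 * math.pi, 16, endpoint=False)
        )
        return SectionProperties(
            area=area, centroid=(0.0, 0.0), Iy=i, Iz=i, Iyz=0.0, J=j,
            c_y_pos=R, c_y_neg=R, c_z_pos=R, c_z_neg=R, fibers=fibers,
        )

    def risk_metrics(self, t_over_r_threshold: float = 0.3) -> dict:
        return shell_risk_metrics(self, t_over_r_threshold)


class PolygonSection(CrossSection):
    """Closed outer polygon with optional cavity holes.

    The outer ring is normalized counter-clockwise, holes clockwise, so
    signed Green's-theorem integrals subtract hole contributions.  Holes
    must lie strictly inside the outer ring and be pairwise disjoint.
    """

    def __init__(self, outer, holes=()):
        outer_pts = _as_ring(outer)
        outer_poly = _ShapelyPolygon(outer_pts)
        if not outer_poly.is_valid:
            raise SectionError("outer ring is self-intersecting")
        self.outer = _normalize_orientation(outer_pts, ccw=True)
        self.holes: list[np.ndarray] = []
        hole_polys = []
        for h in holes:
            pts = _as_ring(h)
            poly = _ShapelyPolygon(pts)
            if not poly.is_valid:
                raise SectionError("hole ring is self-intersecting")
            if not outer_poly.contains(poly):
                raise SectionError("hole not strictly inside the outer ring")
            for other in hole_polys:
                if poly.intersects(other) and not poly.touches(other):
                    raise SectionError("holes overlap")
            hole_polys.append(poly)
            self.holes.append(_normalize_orientation(pts, ccw=False))

    @cached_property
    def _props(self) -> SectionProperties:
        a, iy, iz, iyz = _ring_moments_origin(self.outer)
        sy = _first_moment(self.outer)
        for h in self.holes:
            ah, iyh, izh, iyzh = _ring_moments_origin(h)
            a += ah  # ah is negative for CW rings
            iy += iyh
            iz += izh
            iyz += iyzh
            sy = (sy[0] + _first_moment(h)[0], sy[1] + _first_moment(h)[1])
        if a <= 0:
            raise SectionError("non-positive net area")
        cy, cz = sy[0] / a, sy[1] / a
        # shift to centroid (parallel-axis theorem)
        iy_c = iy - a * cz * cz
        iz_c = iz - a * cy * cy
        iyz_c = iyz - a * cy * cz
        # principal frame
        theta = 0.5 * math.atan2(2.0 * iyz_c, iz_c - iy_c) if abs(iyz_c) > 1e-14 * max(iy_c, iz_c) else 0.0
        ct, st = math.cos(theta), math.sin(theta)
        # rotate axes by theta: coordinates transform (y', z') = (c y + s z, -s y + c z)
        iy_p = iy_c * ct * ct + iz_c * st * st - 2 * iyz_c * st * ct
        iz_p = iz_c * ct * ct + iy_c * st * st + 2 * iyz_c * st * ct
        verts = [self.outer] + list(self.holes)
        fib = []
        for ring in verts:
            d = ring - np.array([cy, cz])
            yp = d[:, 0] * ct + d[:, 1] * st
            zp = -d[:, 0] * st + d[:, 1] * ct
            fib.extend(zip(yp.tolist(), zp.tolist()))
        fib_arr = np.asarray(fib)
        j = a**4 / (40.0 * (iy_p + iz_p))  # St-Venant approximation
        return SectionProperties(
            area=a, centroid=(cy, cz), Iy=iy_p, Iz=iz_p, Iyz=0.0, J=j,
            c_y_pos=float(fib_arr[:, 0].max()), c_y_neg=float(-fib_arr[:, 0].min()),
            c_z_pos=float(fib_arr[:, 1].max()), c_z_neg=float(-fib_arr[:, 1].min()),
            principal_angle=theta, fibers=tuple(map(tuple, fib_arr)),
        )

    def properties(self) -> SectionProperties:
        return self._props

    @staticmethod
    def regular_circle(R: float, n: int = 256, r: float = 0.0,
                       center=(0.0, 0.0)) -> "PolygonSection":
        """Polygonized circle / annulus, mainly for convergence checks."""
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        cy, cz = center
        outer = np.c_[cy + R * np.cos(t), cz + R * np.sin(t)]
        holes = []
        if r > 0:
            holes.append(np.c_[cy + r * np.cos(t), cz + r * np.sin(t)])
        return PolygonSection(outer, holes)


def _first_moment(pts: np.ndarray) -> tuple[float, float]:
    """Signed first moments (∫y dA, ∫z dA) about the origin."""
    y, z = pts[:, 0], pts[:, 1]
    y1, z1 = np.roll(y, -1), np.roll(z, -1)
    cross = y * z1 - y1 * z
    qy = float(np.sum((y + y1) * cross)) / 6.0
    qz = float(np.sum((z + z1) * cross)) / 6.0
    return qy, qz


# ---------------------------------------------------------------------------
# Named operations used by the pipeline
# ---------------------------------------------------------------------------

def second_moments(section: CrossSection) -> tuple[float, float, float]:
    """Centroidal (Iy, Iz, Iyz) in the principal frame (Iyz → 0)."""
    p = section.properties()
    return p.Iy, p.Iz, p.Iyz


def extreme_fibers(section: CrossSection) -> tuple[float, float, float, float]:
    """(c_y+, c_y−, c_z+, c_z−): extreme offsets along the principal axes."""
    p = section.properties()
    return p.c_y_pos, p.c_y_neg, p.c_z_pos, p.c_z_neg


def torsion_constant(section: CrossSection) -> float:
    """St-Venant torsion constant J (exact for circles/annuli)."""
    return section.properties().J


def shell_risk_metrics(spec: CircularSection, t_over_r_threshold: float = 0.3) -> dict:
    """Visual-tree-assessment decay metrics for a hollow circular stem.

    ``t_over_R`` is the residual-wall ratio (t = R − r); values below
    ~0.3 are the classical breakage-risk criterion.  The residual section
    modulus of a hollow circle relative to the solid one is 1 − (r/R)⁴.
    """
    t_over_r = (spec.R - spec.r) / spec.R
    rr = spec.r / spec.R
    return {
        "t_over_R": t_over_r,
        "hollow_diameter_fraction": rr,
        "residual_modulus_ratio": 1.0 - rr**4,
        "flag": t_over_r < t_over_r_threshold,
        "threshold": t_over_r_threshold,
    }


@dataclass(frozen=True)
class InterpolatedProperties:
    """Section properties at a fractional position along a tapered span."""

    area: float
    Iy: float
    Iz: float
    J: float
    c_max: float  # governing extreme-fiber distance
    fibers: tuple[tuple[float, float], ...] = field(default=(), repr=False)


def interpolate_section(span_a: CrossSection, span_b: CrossSection,
                        s: float) -> InterpolatedProperties:
    """Properties at fraction ``s`` ∈ [0, 1] between two end sections.

    Each scalar property is mapped to the radius of the equivalent solid
    circle (A → √(A/π), I → (4I/π)^¼, J → (2J/π)^¼), the radii are
    interpolated linearly, and the property is mapped back.  For circular
    end sections this coincides with linear radius interpolation; for any
    end sections s=0 and s=1 reproduce the end properties exactly.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must lie in [0, 1], got {s}")
    pa, pb = span_a.properties(), span_b.properties()

    def lerp_pow(va, vb, k, c):
        ra, rb = (va / c) ** (1.0 / k), (vb / c) ** (1.0 / k)
        return c * ((1 - s) * ra + s * rb) ** k

    area = lerp_pow(pa.area, pb.area, 2, math.pi)
    iy = lerp_pow(pa.Iy, pb.Iy, 4, math.pi / 4)
    iz = lerp_pow(pa.Iz, pb.Iz, 4, math.pi / 4)
    j = lerp_pow(pa.J, pb.J, 4, math.pi / 2)
    ca = max(pa.c_y_pos, pa.c_y_neg, pa.c_z_pos, pa.c_z_neg)
    cb = max(pb.c_y_pos, pb.c_y_neg, pb.c_z_pos, pb.c_z_neg)
    c = (1 - s) * ca + s * cb
    # fibers: blend the two end fiber clouds radially for stress recovery
    fa = np.asarray(pa.fibers) if pa.fibers else np.zeros((0, 2))
    fb = np.asarray(pb.fibers) if pb.fibers else np.zeros((0, 2))
    scale_a = c / ca if ca > 0 else 1.0
    scale_b = c / cb if cb > 0 else 1.0
    fibers = tuple(map(tuple, np.vstack([fa * scale_a, fb * scale_b])))
    return InterpolatedProperties(area=area, Iy=iy, Iz=iz, J=j, c_max=c,
                                  fibers=fibers)


# ---------------------------------------------------------------------------
# JSON (de)serialization of section geometry
# ---------------------------------------------------------------------------

def section_from_dict(d: dict) -> CrossSection:
    """Build a section from its JSON/YAML description.

    ``{"circle": {"R": 0.4, "r": 0.0}}`` or
    ``{"outer": [[y, z], ...], "holes": [[[y, z], ...], ...]}`` (metres).
    """
    if "circle" in d:
        c = d["circle"]
        return CircularSection(R=float(c["R"]), r=float(c.get("r", 0.0)))
    if "outer" in d:
        return PolygonSection(d["outer"], d.get("holes", ()))
    raise SectionError(f"unrecognized section description: {sorted(d)}")


def section_to_dict(sec: CrossSection) -> dict:
    if isinstance(sec, CircularSection):
        return {"circle": {"R": sec.R, "r": sec.r}}
    if isinstance(sec, PolygonSection):
        return {
            "outer": np.asarray(sec.outer).tolist(),
            "holes": [np.asarray(h).tolist() for h in sec.holes],
        }
    raise SectionError(f"cannot serialize {type(sec).__name__}")
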