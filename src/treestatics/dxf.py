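"""Minimal ASCII-DXF polyline I/O.

Covers exactly the two exchange shapes the pipeline needs and nothing
more:

* 2D section geometry as closed ``LWPOLYLINE`` entities — one outer ring
  per section on layer ``SECTION``, cavity rings on layer ``CAVITY``;
* 3D tree skeletons as ``POLYLINE``/``VERTEX`` chains, one per beam,
  layer name carrying the beam id and role (``B1:trunk``).

DXF is a flat stream of (group-code, value) line pairs; only the ENTITIES
section is read, unknown entities are skipped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .sections import PolygonSection


class DxfError(ValueError):
    pass


def _pairs(text: str):
    lines = text.splitlines()
    if len(lines) % 2:
        lines = lines[:-1]
    for i in range(0, len(lines), 2):
        yield lines[i].strip(), lines[i + 1].strip()


def _entities(text: str):
    """Group the ENTITIES section into (entity_type, [(code, value), ...])."""
    in_entities = False
    current: list | None = None
    ctype = None
    for code, value in _pairs(text):
        if code == "0" and value == "SECTION":
            current = None
            ctype = "_header"
            continue
        if code == "2" and ctype == "_header":
            in_entities = value == "ENTITIES"
            ctype = None
            continue
        if code == "0" and value == "ENDSEC":
            if current is not None:
                yield current
            in_entities, current = False, None
            continue
        if not in_entities:
            continue
        if code == "0":
            if current is not None:
                yield current
            current = [value, []]
        elif current is not None:
            current[1].append((code, value))
    if current is not None:
        yield current


def _get(tags, code, default=None):
    for c, v in tags:
        if c == code:
            return v
    return default


# ---------------------------------------------------------------------------
# 2D sections
# ---------------------------------------------------------------------------

def write_sections_dxf(sections: list[PolygonSection], path: str | Path) -> None:
    """One closed LWPOLYLINE per ring; holes on the CAVITY layer."""
    out = ["0", "SECTION", "2", "ENTITIES"]

    def emit(ring: np.ndarray, layer: str):
        out.extend(["0", "LWPOLYLINE", "8", layer,
                    "90", str(len(ring)), "70", "1"])
        for y, z in np.asarray(ring):
            out.extend(["10", repr(float(y)), "20", repr(float(z))])

    for sec in sections:
        emit(sec.outer, "SECTION")
        for h in sec.holes:
            emit(h, "CAVITY")
    out.extend(["0", "ENDSEC", "0", "EOF"])
    Path(path).write_text("\n".join(out) + "\n")


def read_sections_dxf(path: str | Path) -> list[PolygonSection]:
    """Rebuild PolygonSections: each SECTION-layer ring owns the CAVITY
    rings that lie inside it."""
    from shapely.geometry import Polygon as _SP

    outers, holes = [], []
    for etype, tags in _entities(Path(path).read_text()):
        if etype != "LWPOLYLINE":
            continue
        layer = _get(tags, "8", "SECTION")
        ys = [float(v) for c, v in tags if c == "10"]
        zs = [float(v) for c, v in tags if c == "20"]
        if len(ys) != len(zs) or len(ys) < 3:
            raise DxfError("malformed LWPOLYLINE vertex list")
        ring = np.c_[ys, zs]
        (holes if layer == "CAVITY" else outers).append(ring)
    if not outers:
        raise DxfError("no SECTION-layer polylines found")
    sections = []
    for outer in outers:
        op = _SP(outer)
        mine = [h for h in holes if op.contains(_SP(h))]
        sections.append(PolygonSection(outer, mine))
    return sections


# ---------------------------------------------------------------------------
# 3D skeleton
# ---------------------------------------------------------------------------

def write_skeleton_dxf(chains: dict[str, np.ndarray], path: str | Path,
                       roles: dict[str, str] | None = None) -> None:
    """Write beam centre-lines as 3D POLYLINEs; layer = "<beam>:<role>"."""
    roles = roles or {}
    out = ["0", "SECTION", "2", "ENTITIES"]
    for beam_id, pts in chains.items():
        layer = f"{beam_id}:{roles.get(beam_id, 'branch')}"
        out.extend(["0", "POLYLINE", "8", layer, "66", "1", "70", "8"])
        for x, y, z in np.asarray(pts):
            out.extend(["0", "VERTEX", "8", layer,
                        "10", repr(float(x)), "20", repr(float(y)),
                        "30", repr(float(z))])
        out.extend(["0", "SEQEND"])
    out.extend(["0", "ENDSEC", "0", "EOF"])
    Path(path).write_text("\n".join(out) + "\n")


def read_skeleton_dxf(path: str | Path) -> dict[str, dict]:
    """Return {beam_id: {"points": (n,3) array, "role": str}}."""
    chains: dict[str, dict] = {}
    current_layer = None
    for etype, tags in _entities(Path(path).read_text()):
        if etype == "POLYLINE":
            current_layer = _get(tags, "8", "B?:branch")
        elif etype == "VERTEX" and current_layer is not None:
            x = float(_get(tags, "10", "nan"))
            y = float(_get(tags, "20", "nan"))
            z = float(_get(tags, "30", "nan"))
            beam_id, _, role = current_layer.partition(":")
            entry = chains.setdefault(
                beam_id, {"points": [], "role": role or "branch"})
            entry["points"].append((x, y, z))
        elif etype == "SEQEND":
            current_layer = None
    if not chains:
        raise DxfError("no POLYLINE skeleton found")
    for entry in chains.values():
        pts = np.asarray(entry["points"], float)
        if not np.all(np.isfinite(pts)):
            raise DxfError("non-finite skeleton vertex")
        entry["points"] = pts
    return chains
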