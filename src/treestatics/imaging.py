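"""Image processing for section and crown inputs.

Two raster products feed the structural model:

* **Acoustic tomograms** — color-coded cross-section maps (green = intact
  wood, red = decayed wood, blue = cavity) that are classified by nearest
  reference color and vectorized into closed section polygons, cavities
  (and, by default, decayed regions) becoming holes.
* **Crown silhouettes** — black/white crown images whose opaque-pixel
  ratio scales the measured crown outline area down to the wind-exposed
  area.

Pixel convention: image origin top-left, y down; traced contours are
converted to the section frame (y right, z up) on export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure

from .sections import PolygonSection, SectionError

# Fig-2-style tomogram palette (RGB)
PALETTE = {
    "intact": (0, 160, 0),
    "decayed": (220, 0, 0),
    "cavity": (0, 0, 220),
    "background": (255, 255, 255),
}
CLASS_CODES = {"background": 0, "intact": 1, "decayed": 2, "cavity": 3}
_CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


class ImagingError(ValueError):
    pass


@dataclass(frozen=True)
class TomogramRaster:
    """Class-labelled tomogram grid (codes per CLASS_CODES) + m/px scale."""

    classes: np.ndarray  # (H, W) uint8 class codes
    scale: float         # metres per pixel

    def __post_init__(self):
        if self.scale <= 0:
            raise ImagingError("scale must be positive")
        if not (self.classes == CLASS_CODES["intact"]).any():
            raise ImagingError("tomogram contains no intact-wood pixels")

    def count(self, name: str) -> int:
        return int((self.classes == CLASS_CODES[name]).sum())

    def class_area(self, name: str) -> float:
        """Pixel-count area of one class, m²."""
        return self.count(name) * self.scale**2


@dataclass(frozen=True)
class CrownImage:
    """Binary opacity grid restricted to a crown-outline mask."""

    opaque: np.ndarray      # (H, W) bool, True = non-transparent
    mask: np.ndarray        # (H, W) bool, True = inside crown outline
    outline_area: float     # m², area of the crown outline polygon

    def __post_init__(self):
        if not self.mask.any():
            raise ImagingError("empty crown mask")
        if self.outline_area <= 0:
            raise ImagingError("outline area must be positive")


def classify_tomogram(rgb, scale: float) -> TomogramRaster:
    """Nearest-reference-color classification of an RGB tomogram raster.

    ``rgb`` may be an (H, W, 3) array or a path to a PNG.
    """
    if isinstance(rgb, (str, Path)):
        rgb = np.asarray(Image.open(rgb).convert("RGB"))
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ImagingError("expected an (H, W, 3) RGB raster")
    rgb = rgb[..., :3].astype(float)
    names = list(PALETTE)
    refs = np.array([PALETTE[n] for n in names], float)  # (4, 3)
    dist = ((rgb[..., None, :] - refs) ** 2).sum(axis=-1)  # (H, W, 4)
    nearest = dist.argmin(axis=-1)
    codes = np.zeros(rgb.shape[:2], np.uint8)
    for i, n in enumerate(names):
        codes[nearest == i] = CLASS_CODES[n]
    wood = np.isin(codes, [CLASS_CODES["intact"], CLASS_CODES["decayed"]])
    if not wood.any():
        raise ImagingError("no wood-class pixels found in raster")
    return TomogramRaster(classes=codes, scale=scale)


def _trace_rings(mask: np.ndarray, tolerance: float = 0.5) -> list[np.ndarray]:
    """Closed 0.5-level contours of a binary mask, Douglas–Peucker simplified.

    Returned rings are in (row, col) pixel coordinates of the padded grid
    minus the 1-px pad, i.e. original image coordinates.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    rings = []
    for c in contours:
        c = c - 1.0  # undo pad
        simplified = measure.approximate_polygon(c, tolerance=tolerance)
        if len(simplified) >= 4:  # closed: first == last
            rings.append(simplified[:-1])
    return rings


def _to_section_frame(ring_rc: np.ndarray, scale: float, height: int) -> np.ndarray:
    """(row, col) pixel coords → (y, z) metres with z up."""
    y = ring_rc[:, 1] * scale
    z = (height - 1 - ring_rc[:, 0]) * scale
    return np.c_[y, z]


def vectorize_regions(tomo: TomogramRaster,
                      decayed_counts_as_void: bool = True) -> PolygonSection:
    """Trace the tomogram into a closed section polygon with cavity holes.

    The outer ring encloses the full section footprint (all wood + cavity
    classes); cavity regions — and decayed regions when
    ``decayed_counts_as_void`` (the conservative default, treating decayed
    wood as load-free) — become holes.  A cavity touching the section
    boundary is rejected as physically implausible.
    """
    codes = tomo.classes
    solid = codes != CLASS_CODES["background"]
    void = codes == CLASS_CODES["cavity"]
    if decayed_counts_as_void:
        void = void | (codes == CLASS_CODES["decayed"])

    # a void region adjacent to background ⇒ open cavity at the boundary
    from scipy import ndimage
    grown = ndimage.binary_dilation(void)
    if (grown & ~solid).any():
        raise ImagingError("cavity touches the section boundary")

    outer_rings = _trace_rings(solid)
    if not outer_rings:
        raise ImagingError("no section outline found")
    outer = max(outer_rings, key=lambda r: _poly_area(r))
    hole_rings = _trace_rings(void)
    h = codes.shape[0]
    try:
        return PolygonSection(
            _to_section_frame(outer, tomo.scale, h),
            [_to_section_frame(r, tomo.scale, h) for r in hole_rings])
    except SectionError as e:
        raise ImagingError(f"traced polygon invalid: {e}") from e


def _poly_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def load_crown_image(png, outline_area: float, mask=None) -> CrownImage:
    """Build a CrownImage from a black/white PNG (black = opaque wood/leaf).

    Without an explicit mask, every pixel belongs to the crown outline.
    """
    if isinstance(png, (str, Path)):
        arr = np.asarray(Image.open(png).convert("L"))
    else:
        arr = np.asarray(png)
    opaque = arr < 128
    if mask is None:
        mask = np.ones_like(opaque, bool)
    return CrownImage(opaque=opaque, mask=np.asarray(mask, bool),
                      outline_area=outline_area)


def crown_transparency(img: CrownImage) -> tuple[float, float]:
    """(ratio_opaque, A_reduced): opaque fraction and wind-exposed area.

    ratio_opaque = opaque pixels / mask pixels ∈ [0, 1];
    A_reduced = ratio_opaque × A_outline (m²).
    """
    n_mask = int(img.mask.sum())
    n_opaque = int((img.opaque & img.mask).sum())
    ratio = n_opaque / n_mask
    return ratio, ratio * img.outline_area
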