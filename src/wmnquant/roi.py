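"""Region-of-interest handling: manual polygons, the 0.5 mm margin rule, areas.

White-matter neuron counts are only meaningful if layer-VI neurons at the
grey/white interface are excluded. The manual workflow therefore erodes the
white-matter region by a set distance (default 0.5 mm) from the cortical
margin before counting; this module implements that rule on the pixel grid
with an exact Euclidean distance transform.

Pixel semantics: 0-based indices, pixel-centre coordinates; areas are pixel
counts times mpp², so area assertions are exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape

from .synthetic import SlideImage

AUTOMATED = "automated"
MANUAL = "manual"
FIELD = "field"


@dataclass
class ROIMask:
    """Binary counting region with provenance and applied exclusion margin."""

    mask: np.ndarray  # bool raster
    mpp: float
    provenance: str  # automated | manual | field
    exclusion_margin_mm: float = 0.0

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.mpp**2 / 1e6

    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def rasterize_polygon(poly: Polygon, shape_px: tuple[int, int], mpp: float) -> np.ndarray:
    """Rasterise a μm-coordinate polygon: pixel (r, c) is inside iff the
    polygon strictly contains the pixel centre ((c+0.5)·mpp, (r+0.5)·mpp).

    Axis-aligned rectangles take a closed-form fast path, so a 1 mm x 1 mm
    square at 1 μm/px covers exactly 10⁶ pixels.
    """
    rows, cols = shape_px
    minx, miny, maxx, maxy = poly.bounds
    r0 = max(0, int(np.ceil(miny / mpp - 0.5)))
    r1 = min(rows - 1, int(np.floor(maxy / mpp - 0.5)))
    c0 = max(0, int(np.ceil(minx / mpp - 0.5)))
    c1 = min(cols - 1, int(np.floor(maxx / mpp - 0.5)))
    mask = np.zeros(shape_px, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    bbox_area = (maxx - minx) * (maxy - miny)
    if abs(poly.area - bbox_area) <= 1e-9 * max(bbox_area, 1.0):
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, (cc + 0.5) * mpp, (rr + 0.5) * mpp)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def manual_roi(
    polygon_um: list[tuple[float, float]] | Polygon,
    image: SlideImage,
    tissue_mask: np.ndarray | None = None,
) -> ROIMask:
    """Rasterise a user-outlined polygon (μm coordinates) into an ROI.

    The polygon is clipped to the image bounds; if a tissue mask is supplied
    the ROI is intersected with it. Self-intersecting polygons are rejected.
    """
    poly = polygon_um if isinstance(polygon_um, Polygon) else Polygon(polygon_um)
    if not poly.is_valid:
        raise ValueError("ROI polygon is invalid (self-intersecting?)")
    mask = rasterize_polygon(poly, image.shape, image.mpp)
    if tissue_mask is not None:
        mask &= tissue_mask
    if not mask.any():
        warnings.warn("manual ROI contains no tissue pixels", stacklevel=2)
    return ROIMask(mask=mask, mpp=image.mpp, provenance=MANUAL)


def exclude_boundary_margin(
    wm_mask: ROIMask, cortex_mask: np.ndarray, margin_mm: float = 0.5
) -> ROIMask:
    """Remove ROI pixels closer than ``margin_mm`` to the cortical margin.

    ``cortex_mask`` should cover everything treated as cortex for the
    exclusion (including any blurred grey/white border class). Distances are
    Euclidean on the pixel grid at native resolution.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if wm_mask.mask.shape != cortex_mask.shape:
        raise ValueError("wm_mask and cortex_mask must share geometry")
    if margin_mm == 0 or not cortex_mask.any():
        return ROIMask(
            mask=wm_mask.mask.copy(),
            mpp=wm_mask.mpp,
            provenance=wm_mask.provenance,
            exclusion_margin_mm=margin_mm,
        )
    dist_um = ndimage.distance_transform_edt(~cortex_mask, sampling=wm_mask.mpp)
    keep = wm_mask.mask & (dist_um >= margin_mm * 1000.0)
    return ROIMask(
        mask=keep,
        mpp=wm_mask.mpp,
        provenance=wm_mask.provenance,
        exclusion_margin_mm=margin_mm,
    )


def roi_from_mask(mask: np.ndarray, mpp: float, provenance: str = AUTOMATED) -> ROIMask:
    return ROIMask(mask=mask.astype(bool), mpp=mpp, provenance=provenance)


def polygon_to_geojson(poly: Polygon, path: str | Path) -> None:
    """Write a polygon (μm coordinates) as GeoJSON."""
    Path(path).write_text(
        json.dumps({"type": "Feature", "properties": {"units": "um"}, "geometry": mapping(poly)})
    )


def polygon_from_geojson(path: str | Path) -> Polygon:
    data = json.loads(Path(path).read_text())
    geom = data["geometry"] if data.get("type") == "Feature" else data
    return shape(geom)
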