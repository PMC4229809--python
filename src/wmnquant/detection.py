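"""NeuN-positive profile detection and morphometry.

Two modes mirror the two image-analysis workflows:

* ``wsa`` — whole-slide analysis: the RGB image is unmixed into haematoxylin
  and DAB optical densities and profiles are connected components above a DAB
  OD threshold. The vendor software expressed its cutoff as an "intensity" of
  3.1 units on a proprietary scale; here the knob is kept with its nominal
  value and mapped to a base-10 optical density through a fixed calibration
  constant (0.1 OD per intensity unit, so nominal 3.1 → OD 0.31).
* ``sa_rgb`` — semi-automated field analysis: per-channel min/max bounds on
  raw R, G, B values, as used when thresholding pre-acquired fields.

Each detected profile carries its area, equivalent circular diameter, mean
DAB OD and a size class with the fixed bins small < 126.36 μm²,
126.36 ≤ medium ≤ 370 μm², large > 370 μm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label, regionprops

from .roi import FIELD, ROIMask
from .stains import rgb_to_stains, DAB, HAEM
from .synthetic import SlideImage

#: OD units per nominal vendor "intensity" unit.
OD_PER_INTENSITY_UNIT = 0.1
#: Nominal detection intensity (vendor scale) retained as the default knob.
NOMINAL_DETECTION_INTENSITY = 3.1

SIZE_SMALL_MAX_UM2 = 126.36
SIZE_MEDIUM_MAX_UM2 = 370.0

WSA = "wsa"
SA_RGB = "sa_rgb"


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds controlling profile detection.

    ``rgb_thresholds`` maps channel name ('r', 'g', 'b') to an inclusive
    (min, max) bound; a pixel is a candidate iff every channel is in bounds.
    """

    dab_od_threshold: float = NOMINAL_DETECTION_INTENSITY * OD_PER_INTENSITY_UNIT
    min_profile_area_um2: float = 10.0
    mode: str = WSA
    rgb_thresholds: dict = field(
        default_factory=lambda: {"r": (0, 255), "g": (0, 140), "b": (0, 140)}
    )
    #: resolve touching profiles by watershed on the distance transform;
    #: only components larger than ``split_candidate_area_um2`` are examined
    split_touching: bool = True
    split_candidate_area_um2: float = 60.0
    split_min_separation_um: float = 4.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.dab_od_threshold):
            raise ValueError("dab_od_threshold must be finite")
        if self.min_profile_area_um2 < 0:
            raise ValueError("min_profile_area_um2 must be >= 0")
        if self.mode not in (WSA, SA_RGB):
            raise ValueError(f"unknown detection mode {self.mode!r}")


@dataclass
class CellDetection:
    """One detected NeuN-positive profile."""

    x_um: float
    y_um: float
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: float  # mean DAB optical density
    size_class: str


def size_class_for_area(area_um2: float) -> str:
    """Fixed size bins; the medium bin is closed on both edges."""
    if area_um2 < SIZE_SMALL_MAX_UM2:
        return "small"
    if area_um2 <= SIZE_MEDIUM_MAX_UM2:
        return "medium"
    return "large"


def separate_stains(image: SlideImage) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB slide into (DAB OD, haematoxylin OD) rasters.

    Inverse of the renderer's Beer–Lambert forward model on noiseless
    fixtures; the light grey slide background contributes a small constant
    offset to both channels that sits far below any detection threshold.
    """
    stains = rgb_to_stains(image.rgb)
    return stains[..., DAB], stains[..., HAEM]


def _candidate_mask(image: SlideImage, params: DetectionParams) -> tuple[np.ndarray, np.ndarray]:
    dab_od, _ = separate_stains(image)
    if params.mode == WSA:
        return dab_od >= params.dab_od_threshold, dab_od
    rgb = image.rgb
    mask = np.ones(image.shape, dtype=bool)
    for idx, name in enumerate("rgb"):
        lo, hi = params.rgb_thresholds[name]
        chan = rgb[..., idx]
        mask &= (chan >= lo) & (chan <= hi)
    return mask, dab_od


def _split_touching(labelled: np.ndarray, mpp: float, params: DetectionParams) -> np.ndarray:
    """Split merged profiles by watershed on the Euclidean distance transform.

    Only components above ``split_candidate_area_um2`` are examined (cropped
    to their bounding box, so the cost scales with the number of large blobs,
    not the slide). Distance-transform peaks closer than
    ``split_min_separation_um`` are suppressed, so single convex profiles
    keep a single marker and are never split.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    min_px = params.split_candidate_area_um2 / mpp**2
    min_sep = max(1, int(round(params.split_min_separation_um / mpp)))
    out = labelled.copy()
    next_label = int(labelled.max()) + 1
    for region in regionprops(labelled):
        if region.area <= min_px:
            continue
        sub = region.image  # bbox-cropped boolean mask
        dist = ndimage.distance_transform_edt(sub)
        peaks = peak_local_max(dist, min_distance=min_sep, exclude_border=False, labels=sub)
        if len(peaks) < 2:
            continue
        markers = np.zeros(sub.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        parts = watershed(-dist, markers, mask=sub)
        r0, c0, _, _ = region.bbox
        sel = parts > 0
        out[r0 + np.nonzero(sel)[0], c0 + np.nonzero(sel)[1]] = parts[sel] + next_label - 1
        next_label += len(peaks)
    return out


def detect_cells(
    image: SlideImage, roi: ROIMask, params: DetectionParams | None = None
) -> list[CellDetection]:
    """Detect NeuN-positive profiles whose centroid lies inside the ROI.

    Components are 8-connected; touching profiles merge into one detection
    (no splitting by default). Components smaller than
    ``min_profile_area_um2`` are discarded.
    """
    params = params or DetectionParams()
    if roi.is_empty():
        warnings.warn("empty ROI: no cells can be detected", stacklevel=2)
        return []
    mask, dab_od = _candidate_mask(image, params)
    labelled = label(mask, connectivity=2)
    if params.split_touching:
        labelled = _split_touching(labelled, image.mpp, params)
    mpp = image.mpp
    out: list[CellDetection] = []
    for region in regionprops(labelled, intensity_image=dab_od):
        area_um2 = region.area * mpp**2
        if area_um2 < params.min_profile_area_um2:
            continue
        cy, cx = region.centroid
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < roi.mask.shape[0] and 0 <= ix < roi.mask.shape[1]):
            continue
        if not roi.mask[iy, ix]:
            continue
        out.append(
            CellDetection(
                x_um=cx * mpp,
                y_um=cy * mpp,
                area_um2=area_um2,
                equivalent_diameter_um=region.equivalent_diameter_area * mpp,
                mean_intensity=float(region.intensity_mean),
                size_class=size_class_for_area(area_um2),
            )
        )
    return out


def detections_to_frame(dets: list[CellDetection]) -> pd.DataFrame:
    cols = ["x_um", "y_um", "area_um2", "equivalent_diameter_um", "mean_intensity", "size_class"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dets], columns=cols)


def write_detections_csv(dets: list[CellDetection], path: str | Path) -> None:
    detections_to_frame(dets).to_csv(path, index=False)


def sample_fields(
    roi: ROIMask,
    n_fields: int = 15,
    field_size_um: float = 800.0,
    seed: int = 0,
) -> list[ROIMask]:
    """Place up to ``n_fields`` non-overlapping square fields inside the ROI.

    Emulates pre-acquiring fields of view at fixed magnification (the default
    side approximates a 10x field). Placement is uniform over all positions
    whose full square lies inside the ROI, greedy without overlap, and
    deterministic under ``seed``. If fewer than ``n_fields`` fit, the fields
    that do fit are returned with a warning; if none fit, this is an error.
    """
    f = max(1, int(round(field_size_um / roi.mpp)))
    m = roi.mask
    # valid anchor (top-left) positions: full f x f window inside roi,
    # via an integral image so the test is exact
    s = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = m.astype(np.int64).cumsum(axis=0).cumsum(axis=1)
    if m.shape[0] < f or m.shape[1] < f:
        ys = xs = np.empty(0, dtype=int)
    else:
        win = s[f:, f:] - s[:-f, f:] - s[f:, :-f] + s[:-f, :-f]
        ys, xs = np.nonzero(win == f * f)
    if len(ys) == 0:
        raise ValueError(
            f"ROI ({roi.area_mm2:.3f} mm²) cannot contain a single "
            f"{field_size_um} μm field"
        )
    # rejection sampling: draw random valid anchors, keep non-overlapping ones
    rng = np.random.default_rng(seed)
    occupied = np.zeros_like(m)
    fields: list[ROIMask] = []
    max_tries = 200 * n_fields
    for idx in rng.integers(0, len(ys), size=max_tries):
        y, x = int(ys[idx]), int(xs[idx])
        if occupied[y : y + f, x : x + f].any():
            continue
        occupied[y : y + f, x : x + f] = True
        fm = np.zeros_like(m)
        fm[y : y + f, x : x + f] = True
        fields.append(ROIMask(mask=fm, mpp=roi.mpp, provenance=FIELD))
        if len(fields) == n_fields:
            break
    if len(fields) < n_fields:
        warnings.warn(
            f"only {len(fields)} of {n_fields} requested fields fit in the ROI",
            stacklevel=2,
        )
    return fields


def union_fields(fields: list[ROIMask]) -> ROIMask:
    """Union of sampled fields as a single counting ROI (provenance=field)."""
    if not fields:
        raise ValueError("no fields to union")
    mask = np.zeros_like(fields[0].mask)
    for fld in fields:
        mask |= fld.mask
    return ROIMask(mask=mask, mpp=fields[0].mpp, provenance=FIELD)
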