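"""Optical-disector stereology on z-resolved ground truth.

The optical disector counts each cell exactly once by a unique point — here
the topmost z of the cell's sphere — falling inside a 3D probe: a square
counting frame in (x, y) and a depth window [guard, guard + height] within
the section. Because unique points of a homogeneous cell population form a
homogeneous point process, ΣQ / (sampled volume) is an unbiased estimator of
Nv regardless of cell size or section thickness, which is why stereology
needs no Abercrombie correction.

Frames are a uniformly shuffled subset of a jittered tiling of the ROI: the
tiling is offset by a random sub-frame shift, tiles are clipped to the ROI
(clipped area counts toward the sampled volume), and a uniformly random
subset of tiles is taken until the requested fraction of the ROI area is
covered. At sampling_fraction = 1 this reduces to an exhaustive count over
the ROI. Tile subsets are nested across escalating fractions, so the
coefficient of error can only fall as sampling escalates. Frame
inclusion/exclusion edges are realised as half-open intervals — tiles
partition the plane, so no point can be counted twice or lost on an edge.

The coefficient of error uses the Poisson approximation CE = 1 / sqrt(ΣQ),
appropriate to uniform random (not systematic) sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .roi import ROIMask
from .synthetic import GroundTruth, WHITE_MATTER

#: escalation ladder for adaptive sampling
SAMPLING_LADDER = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class DisectorConfig:
    """Probe geometry and sampling control.

    ``disector_height_um`` defaults (None) to T − 2·guard at count time.
    ``sampling_fraction`` is the fraction of ROI area to cover with frames;
    values in [0.25, 1.0] mirror routine practice.
    """

    frame_size_um: float = 100.0
    disector_height_um: float | None = None
    guard_um: float = 2.0
    sampling_fraction: float = 1.0
    ce_target: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_size_um <= 0:
            raise ValueError("frame_size_um must be > 0")
        if self.disector_height_um is not None and self.disector_height_um <= 0:
            raise ValueError("disector_height_um must be > 0")
        if self.guard_um < 0:
            raise ValueError("guard_um must be >= 0")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")


@dataclass
class StereologyResult:
    sum_Q: int
    v_sampled_mm3: float
    Nv: float  # cells / mm³
    CE: float  # 1/sqrt(sum_Q); nan when sum_Q == 0
    fields_used: int
    sampling_fraction: float
    ce_met: bool


def _prepare_tiles(roi: ROIMask, frame_px: int, rng: np.random.Generator):
    """Jittered tiling of the ROI: per-tile clipped areas and a shuffle order."""
    m = roi.mask
    oy = int(rng.integers(0, frame_px))
    ox = int(rng.integers(0, frame_px))
    ys, xs = np.nonzero(m)
    ty = (ys + oy) // frame_px
    tx = (xs + ox) // frame_px
    ntx = int(tx.max()) + 1 if len(tx) else 1
    tile_id = ty * ntx + tx
    uniq, inv, counts = np.unique(tile_id, return_inverse=True, return_counts=True)
    order = rng.permutation(len(uniq))
    return uniq, inv, counts, order, (oy, ox, ntx)


def disector_count(
    truth: GroundTruth,
    roi: ROIMask,
    cfg: DisectorConfig | None = None,
    compartments: tuple[str, ...] | None = None,
) -> StereologyResult:
    """Count cells with the optical disector over sampled frames.

    A cell counts iff its unique point (sphere top, z_centre − d/2) lies in
    [guard, guard + height] and its (x, y) pixel belongs to a selected frame
    tile inside the ROI. ``compartments`` restricts which ground-truth cells
    are eligible (default: all — the ROI normally does the restricting).
    """
    cfg = cfg or DisectorConfig()
    if roi.is_empty():
        raise ValueError("ROI is empty")
    T = truth.thickness_T
    height = cfg.disector_height_um
    if height is None:
        height = max(T - 2.0 * cfg.guard_um, 1.0)
    if cfg.guard_um + height > T + 1e-9:
        raise ValueError(
            f"guard ({cfg.guard_um}) + disector height ({height}) exceeds section thickness {T}"
        )
    rng = np.random.default_rng(cfg.seed)
    frame_px = max(1, int(round(cfg.frame_size_um / roi.mpp)))
    uniq, inv, counts, order, (oy, ox, ntx) = _prepare_tiles(roi, frame_px, rng)

    roi_px = counts.sum()
    target_px = cfg.sampling_fraction * roi_px
    shuffled_counts = counts[order]
    cum = np.cumsum(shuffled_counts)
    k = int(np.searchsorted(cum, target_px - 1e-9) + 1)
    k = min(k, len(uniq))
    selected = set(uniq[order[:k]].tolist())
    area_px = int(cum[k - 1])

    cells = truth.cells
    if compartments is not None:
        cells = cells[cells["compartment"].isin(compartments)]
    q = 0
    if len(cells):
        z_top = cells["z_um"].to_numpy() - cells["diameter_um"].to_numpy() / 2.0
        in_depth = (z_top >= cfg.guard_um) & (z_top < cfg.guard_um + height)
        xs_px = np.floor(cells["x_um"].to_numpy() / roi.mpp).astype(int)
        ys_px = np.floor(cells["y_um"].to_numpy() / roi.mpp).astype(int)
        rows, cols = roi.mask.shape
        in_bounds = (xs_px >= 0) & (xs_px < cols) & (ys_px >= 0) & (ys_px < rows)
        ok = in_depth & in_bounds
        xs_px, ys_px = xs_px[ok], ys_px[ok]
        in_roi = roi.mask[ys_px, xs_px]
        xs_px, ys_px = xs_px[in_roi], ys_px[in_roi]
        tid = ((ys_px + oy) // frame_px) * ntx + (xs_px + ox) // frame_px
        q = int(sum(t in selected for t in tid.tolist()))

    v_mm3 = area_px * roi.mpp**2 * height / 1e9  # px·μm²·μm → mm³
    nv = q / v_mm3 if v_mm3 > 0 else 0.0
    ce = 1.0 / math.sqrt(q) if q > 0 else float("nan")
    return StereologyResult(
        sum_Q=q,
        v_sampled_mm3=v_mm3,
        Nv=nv,
        CE=ce,
        fields_used=k,
        sampling_fraction=cfg.sampling_fraction,
        ce_met=bool(q > 0 and ce <= cfg.ce_target),
    )


def adaptive_sampling(
    truth: GroundTruth,
    roi: ROIMask,
    cfg: DisectorConfig | None = None,
    compartments: tuple[str, ...] | None = None,
) -> StereologyResult:
    """Escalate the sampling fraction 0.25 → 0.5 → 0.75 → 1.0 until CE ≤ target.

    Tile subsets are nested (same seed ⇒ same shuffle), so ΣQ is
    non-decreasing and CE non-increasing along the ladder. If even full
    sampling leaves CE above target, the full-sampling result is returned
    with ``ce_met=False`` — the "where possible" contract.
    """
    cfg = cfg or DisectorConfig()
    result = None
    for frac in SAMPLING_LADDER:
        step = DisectorConfig(
            frame_size_um=cfg.frame_size_um,
            disector_height_um=cfg.disector_height_um,
            guard_um=cfg.guard_um,
            sampling_fraction=frac,
            ce_target=cfg.ce_target,
            seed=cfg.seed,
        )
        result = disector_count(truth, roi, step, compartments=compartments)
        if result.ce_met:
            return result
    return result


def wm_truth_roi(truth: GroundTruth, shape: tuple[int, int] | None = None) -> ROIMask:
    """Rasterised white-matter compartment of the ground truth as an ROI."""
    from .roi import rasterize_polygon

    if shape is None:
        # tissue sits inside a background margin of equal width on all sides
        minx, miny, maxx, maxy = truth.geometry.tissue.bounds
        shape = (
            int(round((maxy + miny) / truth.mpp)),
            int(round((maxx + minx) / truth.mpp)),
        )
    mask = rasterize_polygon(truth.geometry.white_matter, shape, truth.mpp)
    return ROIMask(mask=mask, mpp=truth.mpp, provenance="manual")
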