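"""Synthetic NeuN-stained slide generator with exact 3D ground truth.

The generator emulates a brightfield scan of a temporal-lobe section
immunolabelled for NeuN (brown, DAB) and counterstained with haematoxylin:
a cortical band whose deep edge (the layer-VI analogue) is densely populated
with neurons sits on top of white matter containing sparse heterotopic
neurons. Cells are spheres placed by a 3D Poisson process inside the physical
section slab [0, T]; every sphere that intersects the slab is recorded in the
ground truth and rendered as a brown disc, so the expected number of rendered
profiles per unit area is Nv * (T + h̄) / 1000 — the relationship the
Abercrombie correction inverts.

The rendered profile diameter is the *largest* chord of the sphere–slab
intersection: the full equatorial diameter when the sphere centre lies inside
the slab, and the chord cut by the nearer slab face when it does not. This is
what an extended-focus (projected) image of a thick section shows, and it is
the profile-size model under which profile counting plus Abercrombie
correction is consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon
from skimage.draw import disk

from .stains import DAB, HAEM, neutral_grey_stains, stains_to_rgb

CORTEX = "cortex"
LAYER6 = "layer6"
WHITE_MATTER = "white_matter"
COMPARTMENTS = (CORTEX, LAYER6, WHITE_MATTER)

#: 8-bit level of the slide background (glass, no tissue).
BACKGROUND_LEVEL = 235.0

#: Section thickness distribution of the emulated cohort (μm): mean 17, sd 5,
#: truncated below at 5 μm.
THICKNESS_MEAN_UM = 17.0
THICKNESS_SD_UM = 5.0
THICKNESS_MIN_UM = 5.0


class SlideSizeError(ValueError):
    """Raised when a requested raster would exceed the pixel budget."""


@dataclass(frozen=True)
class SlideConfig:
    """Parameters of one synthetic slide.

    Lengths are μm, densities cells/mm³. ``cortex_band_frac`` is the fraction
    of the tissue height occupied by cortex; the deepest
    ``layer6_band_frac`` of that band is the dense layer-VI analogue.
    """

    width_um: float = 2000.0
    height_um: float = 3000.0
    mpp: float = 1.0
    thickness_T: float = THICKNESS_MEAN_UM
    cortex_band_frac: float = 0.4
    layer6_density: float = 50_000.0
    wm_density_Nv: float = 1_500.0
    cortex_density: float = 20_000.0
    cell_diameter_mean: float = 10.0
    cell_diameter_sd: float = 2.0
    stain_noise_sd: float = 2.0
    seed: int = 0
    layer6_band_frac: float = 0.25
    background_margin_um: float = 60.0
    boundary_wave_amplitude_um: float = 0.0
    boundary_wavelength_um: float = 1000.0
    tissue_haem_od: float = 0.15
    dab_amplitude_od: float = 1.0
    max_pixels: int = 1 << 26

    def __post_init__(self) -> None:
        positive = {
            "width_um": self.width_um,
            "height_um": self.height_um,
            "mpp": self.mpp,
            "thickness_T": self.thickness_T,
            "cell_diameter_mean": self.cell_diameter_mean,
            "cell_diameter_sd": self.cell_diameter_sd,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("layer6_density", self.layer6_density),
            ("wm_density_Nv", self.wm_density_Nv),
            ("cortex_density", self.cortex_density),
        ):
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not 0 < self.cortex_band_frac < 1:
            raise ValueError("cortex_band_frac must lie in (0, 1)")
        if not 0 < self.layer6_band_frac < 1:
            raise ValueError("layer6_band_frac must lie in (0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) at the configured μm/pixel."""
        return (
            int(round(self.height_um / self.mpp)),
            int(round(self.width_um / self.mpp)),
        )


@dataclass
class SlideImage:
    """RGB brightfield raster plus the physical metadata of the section."""

    rgb: np.ndarray  # uint8, (rows, cols, 3)
    mpp: float  # μm / pixel
    thickness_T: float  # μm
    case_id: str = "case"

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def to_tiff(self, path: str | Path) -> None:
        """Write an 8-bit RGB TIFF with μm/pixel encoded in resolution tags."""
        px_per_cm = 1e4 / self.mpp
        tifffile.imwrite(
            path,
            self.rgb,
            photometric="rgb",
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
            description=json.dumps(
                {"mpp_um": self.mpp, "thickness_T_um": self.thickness_T, "case_id": self.case_id}
            ),
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "SlideImage":
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            rgb = page.asarray()
            meta = json.loads(page.tags["ImageDescription"].value)
        return cls(
            rgb=rgb,
            mpp=float(meta["mpp_um"]),
            thickness_T=float(meta["thickness_T_um"]),
            case_id=str(meta.get("case_id", "case")),
        )


@dataclass
class SlideGeometry:
    """Compartment polygons (coordinates in μm, y increasing downwards)."""

    tissue: Polygon
    cortex: Polygon
    layer6: Polygon
    white_matter: Polygon
    interface_y_um: float  # mean y of the grey/white interface
    layer6_top_y_um: float = 0.0  # mean y of the layer-VI upper edge

    def polygon(self, compartment: str) -> Polygon:
        return {CORTEX: self.cortex, LAYER6: self.layer6, WHITE_MATTER: self.white_matter}[
            compartment
        ]


@dataclass
class GroundTruth:
    """Per-cell 3D truth emitted alongside each synthetic slide.

    ``cells`` lists every cell whose sphere intersects the section slab
    [0, T]: columns x_um, y_um, z_um (centre depth), diameter_um,
    profile_diameter_um (rendered disc diameter) and compartment.
    """

    cells: pd.DataFrame
    true_Nv_wm: float  # cells/mm³, the generating density
    true_Na_wm: float  # observed WM profiles / mm²
    wm_area_mm2: float
    thickness_T: float
    mpp: float
    geometry: SlideGeometry

    def compartment_cells(self, compartment: str) -> pd.DataFrame:
        return self.cells[self.cells["compartment"] == compartment]

    def to_csv(self, path: str | Path) -> None:
        cols = ["x_um", "y_um", "z_um", "diameter_um", "profile_diameter_um", "compartment"]
        self.cells[cols].to_csv(path, index=False)

    def sidecar(self) -> dict:
        """Slide-level truth for the JSON sidecar."""
        return {
            "true_Nv_wm": self.true_Nv_wm,
            "true_Na_wm": self.true_Na_wm,
            "wm_area_mm2": self.wm_area_mm2,
            "thickness_T": self.thickness_T,
            "mpp": self.mpp,
            "interface_y_um": self.geometry.interface_y_um,
            "tissue_bounds_um": list(self.geometry.tissue.bounds),
        }


@dataclass(frozen=True)
class CohortSpec:
    """Group-structured cohort: control vs epilepsy-like WMN densities.

    Density ranges are uniform intervals in cells/mm³. The defaults put the
    epilepsy-like maximum roughly three-fold above the control maximum,
    emulating the separation reported between surgical epilepsy cases and
    controls.
    """

    n_control: int = 12
    n_epilepsy: int = 30
    control_Nv_range: tuple[float, float] = (500.0, 1500.0)
    epilepsy_Nv_range: tuple[float, float] = (800.0, 4500.0)
    seed: int = 0
    base_config: SlideConfig = field(default_factory=SlideConfig)

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_epilepsy < 1:
            raise ValueError("n_control and n_epilepsy must both be >= 1")
        for name, (lo, hi) in (
            ("control_Nv_range", self.control_Nv_range),
            ("epilepsy_Nv_range", self.epilepsy_Nv_range),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive interval, got {(lo, hi)}")
        if self.epilepsy_Nv_range[1] < self.control_Nv_range[1]:
            raise ValueError("epilepsy range upper bound must be >= control upper bound")


@dataclass
class CohortCase:
    case_id: str
    group: str  # "control" | "epilepsy"
    config: SlideConfig
    slide: SlideImage | None
    truth: GroundTruth


def slide_geometry(config: SlideConfig) -> SlideGeometry:
    """Build the compartment polygons for a slide configuration."""
    m = config.background_margin_um
    w, h = config.width_um, config.height_um
    top, bottom = m, h - m
    left, right = m, w - m
    tissue_h = bottom - top
    interface_y = top + config.cortex_band_frac * tissue_h
    layer6_top = interface_y - config.layer6_band_frac * config.cortex_band_frac * tissue_h

    if config.boundary_wave_amplitude_um > 0:
        xs = np.linspace(left, right, 257)
        wave = config.boundary_wave_amplitude_um * np.sin(
            2 * np.pi * xs / config.boundary_wavelength_um
        )
        iface = np.column_stack([xs, interface_y + wave])
        l6top = np.column_stack([xs, layer6_top + wave])
    else:
        iface = np.array([[left, interface_y], [right, interface_y]])
        l6top = np.array([[left, layer6_top], [right, layer6_top]])

    def band(upper: np.ndarray, lower: np.ndarray) -> Polygon:
        # upper/lower are left-to-right polylines; lower boundary reversed.
        return Polygon(np.vstack([upper, lower[::-1]]))

    tissue = Polygon([(left, top), (right, top), (right, bottom), (left, bottom)])
    cortex = band(np.array([[left, top], [right, top]]), l6top)
    layer6 = band(l6top, iface)
    white = band(iface, np.array([[left, bottom], [right, bottom]]))
    return SlideGeometry(
        tissue=tissue,
        cortex=cortex,
        layer6=layer6,
        white_matter=white,
        interface_y_um=interface_y,
        layer6_top_y_um=layer6_top,
    )


def _sample_compartment(
    rng: np.random.Generator,
    poly: Polygon,
    density_mm3: float,
    T: float,
    config: SlideConfig,
) -> pd.DataFrame:
    """Poisson-sample cells whose spheres intersect the slab [0, T].

    Parent process: homogeneous in 3D over the polygon footprint and an
    extended depth range [-zmax, T + zmax]; cells are kept iff the sphere
    intersects the slab. The kept count is then Poisson with mean
    density * area * (T + E[d]) / 1000 exactly.
    """
    d_hi = config.cell_diameter_mean + 6.0 * config.cell_diameter_sd
    zmax = d_hi / 2.0
    area_mm2 = poly.area / 1e6
    lam = density_mm3 * area_mm2 * (T + 2.0 * zmax) / 1000.0
    n = rng.poisson(lam)
    if n == 0:
        return pd.DataFrame({c: np.empty(0) for c in ("x_um", "y_um", "z_um", "diameter_um")})
    minx, miny, maxx, maxy = poly.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        # rejection sampling against the polygon; batch oversized for margin
        cand = max(32, int(need * 1.6))
        cx = rng.uniform(minx, maxx, cand)
        cy = rng.uniform(miny, maxy, cand)
        ok = shapely.contains_xy(poly, cx, cy)
        take = min(int(ok.sum()), need)
        xs[filled : filled + take] = cx[ok][:take]
        ys[filled : filled + take] = cy[ok][:take]
        filled += take
    d = np.clip(
        rng.normal(config.cell_diameter_mean, config.cell_diameter_sd, n), 1.0, d_hi
    )
    z = rng.uniform(-zmax, T + zmax, n)
    keep = (z >= -d / 2.0) & (z <= T + d / 2.0)
    return pd.DataFrame(
        {"x_um": xs[keep], "y_um": ys[keep], "z_um": z[keep], "diameter_um": d[keep]}
    )


def _profile_diameters(z: np.ndarray, d: np.ndarray, T: float) -> np.ndarray:
    """Largest chord of each sphere–slab intersection (projected profile)."""
    r = d / 2.0
    outside = np.maximum(0.0, np.maximum(-z, z - T))
    return 2.0 * np.sqrt(np.maximum(r * r - outside * outside, 0.0))


def sample_ground_truth(config: SlideConfig) -> GroundTruth:
    """Draw the 3D cell population and profile sizes without rendering.

    This is the fast path used by stereology and by Monte-Carlo checks; the
    returned object is identical to the truth emitted by
    :func:`generate_slide` under the same config.
    """
    rng = np.random.default_rng(config.seed)
    geom = slide_geometry(config)
    T = config.thickness_T
    frames = []
    for comp, dens in (
        (CORTEX, config.cortex_density),
        (LAYER6, config.layer6_density),
        (WHITE_MATTER, config.wm_density_Nv),
    ):
        df = _sample_compartment(rng, geom.polygon(comp), dens, T, config)
        df["compartment"] = comp
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    if len(cells):
        cells["profile_diameter_um"] = _profile_diameters(
            cells["z_um"].to_numpy(), cells["diameter_um"].to_numpy(), T
        )
    else:
        cells["profile_diameter_um"] = pd.Series(dtype=float)
    wm_area = geom.white_matter.area / 1e6
    n_wm = int((cells["compartment"] == WHITE_MATTER).sum())
    return GroundTruth(
        cells=cells,
        true_Nv_wm=config.wm_density_Nv,
        true_Na_wm=n_wm / wm_area,
        wm_area_mm2=wm_area,
        thickness_T=T,
        mpp=config.mpp,
        geometry=geom,
    )


def render_slide(config: SlideConfig, truth: GroundTruth, case_id: str = "case") -> SlideImage:
    """Render the RGB raster for an already-sampled ground truth."""
    rows, cols = config.shape
    if rows * cols > config.max_pixels:
        raise SlideSizeError(
            f"raster {rows}x{cols} = {rows * cols} px exceeds max_pixels={config.max_pixels}; "
            "reduce slide extent or increase mpp"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF00D]))
    tissue = np.zeros((rows, cols), dtype=np.uint8)
    dab_n = np.zeros((rows, cols), dtype=np.uint8)  # disc overlap count

    # tissue tint: haematoxylin over the tissue rectangle
    minx, miny, maxx, maxy = truth.geometry.tissue.bounds
    r0, r1 = int(round(miny / config.mpp)), int(round(maxy / config.mpp))
    c0, c1 = int(round(minx / config.mpp)), int(round(maxx / config.mpp))
    tissue[r0:r1, c0:c1] = 1

    cells = truth.cells
    if len(cells):
        prof_r_px = cells["profile_diameter_um"].to_numpy() / 2.0 / config.mpp
        cy = cells["y_um"].to_numpy() / config.mpp
        cx = cells["x_um"].to_numpy() / config.mpp
        for y, x, r in zip(cy, cx, prof_r_px):
            if r <= 0:
                continue
            rr, cc = disk((y, x), r, shape=(rows, cols))
            dab_n[rr, cc] += 1

    # stain ODs take few discrete values (tissue tint on/off x integer disc
    # overlap), so the Beer-Lambert transform goes through a small LUT
    # indexed by tissue*256 + overlap count
    key = (tissue.astype(np.int32) << 8) | dab_n
    levels = np.arange(512)
    stain_rows = np.zeros((512, 3))
    stain_rows[:, HAEM] = (levels >> 8) * config.tissue_haem_od
    stain_rows[:, DAB] = (levels & 255) * config.dab_amplitude_od
    stain_rows += neutral_grey_stains(BACKGROUND_LEVEL)
    rgb_lut = stains_to_rgb(stain_rows).astype(np.float32)
    rgb = rgb_lut[key]
    if config.stain_noise_sd > 0:
        rgb += config.stain_noise_sd * rng.standard_normal(rgb.shape, dtype=np.float32)
    np.clip(rgb, 0.0, 255.0, out=rgb)
    rgb = (rgb + 0.5).astype(np.uint8)  # round half up; 255.5 truncates to 255
    return SlideImage(rgb=rgb, mpp=config.mpp, thickness_T=config.thickness_T, case_id=case_id)


def generate_slide(config: SlideConfig, case_id: str = "case") -> tuple[SlideImage, GroundTruth]:
    """Generate one synthetic slide and its exact ground truth.

    Deterministic in ``config.seed``: two calls with the same config return
    bit-identical rasters and identical cell tables.
    """
    truth = sample_ground_truth(config)
    slide = render_slide(config, truth, case_id=case_id)
    return slide, truth


def generate_cohort(spec: CohortSpec, render: bool = True) -> list[CohortCase]:
    """Generate a group-structured cohort of cases.

    Per case, section thickness is drawn from N(17, 5) truncated at 5 μm and
    the true white-matter neuron density uniformly from the group's range.
    With ``render=False`` only ground truth is sampled (``slide`` is None),
    which is orders of magnitude faster and sufficient for stereology and
    statistical simulations.
    """
    root = np.random.SeedSequence(spec.seed)
    groups = ["control"] * spec.n_control + ["epilepsy"] * spec.n_epilepsy
    children = root.spawn(len(groups))
    cases = []
    for i, (group, ss) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(ss)
        T = float(max(THICKNESS_MIN_UM, rng.normal(THICKNESS_MEAN_UM, THICKNESS_SD_UM)))
        lo, hi = spec.control_Nv_range if group == "control" else spec.epilepsy_Nv_range
        nv = float(rng.uniform(lo, hi))
        case_seed = int(rng.integers(0, 2**31 - 1))
        config = dataclasses.replace(
            spec.base_config, thickness_T=T, wm_density_Nv=nv, seed=case_seed
        )
        case_id = f"{group}_{i:03d}"
        if render:
            slide, truth = generate_slide(config, case_id=case_id)
        else:
            slide, truth = None, sample_ground_truth(config)
        cases.append(CohortCase(case_id=case_id, group=group, config=config, slide=slide, truth=truth))
    return cases
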