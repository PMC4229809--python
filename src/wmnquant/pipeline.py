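"""End-to-end orchestration: simulate → segment → ROI → detect → densities →
statistics → classification.

Each stage is an importable function; ``run_pipeline`` chains them and writes
every artifact (slides, ground truth, compartment masks, detections,
densities, statistical reports, classification) plus a log of all effective
parameters into a run directory. Everything stochastic derives from the
single run seed, so re-running a config reproduces every output byte for
byte.

The simulated "user" interactions mirror the real workflow: training
examples for the compartment classifier are representative segments picked
well inside cortex, white matter and slide background; the manual ROI is the
white-matter outline eroded by the configured margin from the cortical side.
Test–retest re-analysis repeats the stochastic stages (field placement,
disector sampling) with a fresh sub-seed; fully deterministic stages
reproduce exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify as mmcd
from . import stats as cstats
from .compartments import (
    CompartmentMap,
    SegmentMap,
    TissueParams,
    classify_compartments,
    detect_tissue,
    segment_superpixels,
    train_compartment_classifier,
)
from .density import DensityResult, density_from_detections, results_to_frame
from .detection import (
    SA_RGB,
    DetectionParams,
    detect_cells,
    sample_fields,
    union_fields,
    write_detections_csv,
)
from .roi import ROIMask, exclude_boundary_margin, manual_roi, roi_from_mask
from .stereology import DisectorConfig, StereologyResult, adaptive_sampling
from .synthetic import CohortCase, CohortSpec, GroundTruth, SlideConfig, SlideImage, generate_cohort

logger = logging.getLogger("wmnquant")

ALL_METHODS = ("wsa_auto", "wsa_manual", "sa", "stereology")


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    seed: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    n_control: int = 3
    n_epilepsy: int = 3
    control_Nv_range: tuple[float, float] = (500.0, 1500.0)
    epilepsy_Nv_range: tuple[float, float] = (800.0, 4500.0)
    slide: dict = field(default_factory=dict)  # SlideConfig overrides
    tissue: dict = field(default_factory=dict)  # TissueParams overrides
    detection: dict = field(default_factory=dict)  # DetectionParams overrides
    disector: dict = field(default_factory=dict)  # DisectorConfig overrides
    segment_scale: float = 0.4
    margin_mm: float = 0.5
    n_fields: int = 15
    field_size_um: float = 300.0
    n_retest: int = 10
    n_retest_stereology: int = 2
    bonferroni_alpha: float = 0.002
    gold_method: str = "wsa_manual"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.methods = tuple(self.methods)
        self.control_Nv_range = tuple(self.control_Nv_range)
        self.epilepsy_Nv_range = tuple(self.epilepsy_Nv_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = json.loads(json.dumps(dataclasses.asdict(self)))  # tuples -> lists
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def slide_config(self, **overrides) -> SlideConfig:
        return SlideConfig(**{**self.slide, **overrides})

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_control=self.n_control,
            n_epilepsy=self.n_epilepsy,
            control_Nv_range=self.control_Nv_range,
            epilepsy_Nv_range=self.epilepsy_Nv_range,
            seed=self.seed,
            base_config=self.slide_config(),
        )


@dataclass
class CaseQuantification:
    case_id: str
    group: str
    densities: dict[str, DensityResult]
    stereology: StereologyResult | None
    compartment_map: CompartmentMap | None
    rois: dict[str, ROIMask]
    detections: dict[str, list] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Stage failure, annotated with the stage and case id."""


def _stage(stage: str, case_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage!r} failed for case {case_id!r}: {exc}") from exc
            return False

    return _Ctx()


def auto_training_labels(
    segments: SegmentMap, truth: GroundTruth, n_cortex: int = 2, n_wm: int = 2, n_background: int = 1
) -> list[tuple[int, str]]:
    """Pick representative example segments the way a user would.

    Cortex examples come from well above the layer-VI band, white-matter
    examples from well below the grey/white interface, background examples
    from segments essentially outside the tissue. Selection is deterministic
    (spread across the depth range of each candidate pool).
    """
    f = segments.features
    geom = truth.geometry
    cortex_pool = f[
        (f["tissue_fraction"] > 0.95) & (f["centroid_y_um"] < geom.layer6_top_y_um - 100.0)
    ]
    wm_pool = f[
        (f["tissue_fraction"] > 0.95) & (f["centroid_y_um"] > geom.interface_y_um + 600.0)
    ]
    bg_pool = f[f["tissue_fraction"] < 0.05]
    labels: list[tuple[int, str]] = []
    for pool, cls, n in (
        (cortex_pool, "cortex", n_cortex),
        (wm_pool, "white_matter", n_wm),
        (bg_pool, "background", n_background),
    ):
        if len(pool) < n:
            raise PipelineError(
                f"cannot pick {n} training segments for class {cls!r}; only {len(pool)} candidates"
            )
        ordered = pool.sort_values("centroid_y_um")
        picks = np.linspace(0, len(ordered) - 1, n).round().astype(int)
        labels.extend((int(ordered.index[i]), cls) for i in picks)
    return labels


def _truth_cortex_mask(truth: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Raster of everything above the grey/white interface (cortex + layer VI)."""
    from .roi import rasterize_polygon

    mask = np.zeros(shape, dtype=bool)
    for poly in (truth.geometry.cortex, truth.geometry.layer6):
        mask |= rasterize_polygon(poly, shape, truth.mpp)
    return mask


def quantify_case(
    case: CohortCase,
    config: RunConfig,
    seed: int,
    detection_overrides: dict | None = None,
) -> CaseQuantification:
    """Run every requested counting method on one case."""
    slide, truth = case.slide, case.truth
    tissue_params = TissueParams(**config.tissue)
    det_params = DetectionParams(**{**config.detection, **(detection_overrides or {})})
    sa_params = DetectionParams(**{**config.detection, "mode": SA_RGB})
    densities: dict[str, DensityResult] = {}
    rois: dict[str, ROIMask] = {}
    all_dets: dict[str, list] = {}
    cmap = None
    stereo = None

    needs_image = any(m in config.methods for m in ("wsa_auto", "wsa_manual", "sa"))
    tissue = None
    if needs_image:
        if slide is None:
            raise PipelineError(
                f"stage 'quantify' failed for case {case.case_id!r}: methods "
                f"{config.methods} need a rendered slide"
            )
        with _stage("tissue", case.case_id):
            tissue = detect_tissue(slide, tissue_params)

    if "wsa_auto" in config.methods:
        with _stage("wsa_auto", case.case_id):
            segments = segment_superpixels(
                slide, tissue, scale=config.segment_scale, detection_params=det_params
            )
            examples = auto_training_labels(segments, truth)
            clf = train_compartment_classifier(segments, examples)
            cmap = classify_compartments(segments, clf, tissue_mask=tissue)
            roi_auto = roi_from_mask(cmap.mask("white_matter"), slide.mpp, "automated")
            dets = detect_cells(slide, roi_auto, det_params)
            densities["wsa_auto"] = density_from_detections(
                dets, roi_auto, slide.thickness_T, method="wsa_auto"
            )
            rois["wsa_auto"] = roi_auto
            all_dets["wsa_auto"] = dets

    roi_manual = None
    if any(m in config.methods for m in ("wsa_manual", "sa", "stereology")):
        with _stage("manual_roi", case.case_id):
            shape = slide.shape if slide is not None else None
            if slide is not None:
                roi_wm = manual_roi(truth.geometry.white_matter, slide, tissue)
                cortex_mask = _truth_cortex_mask(truth, slide.shape)
            else:
                from .stereology import wm_truth_roi

                roi_wm = wm_truth_roi(truth)
                cortex_mask = _truth_cortex_mask(truth, roi_wm.mask.shape)
            roi_manual = exclude_boundary_margin(roi_wm, cortex_mask, config.margin_mm)

    if "wsa_manual" in config.methods:
        with _stage("wsa_manual", case.case_id):
            dets = detect_cells(slide, roi_manual, det_params)
            densities["wsa_manual"] = density_from_detections(
                dets, roi_manual, slide.thickness_T, method="wsa_manual"
            )
            rois["wsa_manual"] = roi_manual
            all_dets["wsa_manual"] = dets

    if "sa" in config.methods:
        with _stage("sa", case.case_id):
            fields = sample_fields(
                roi_manual, n_fields=config.n_fields, field_size_um=config.field_size_um, seed=seed
            )
            roi_sa = union_fields(fields)
            dets = detect_cells(slide, roi_sa, sa_params)
            densities["sa"] = density_from_detections(
                dets, roi_sa, slide.thickness_T, method="sa"
            )
            rois["sa"] = roi_sa
            all_dets["sa"] = dets

    if "stereology" in config.methods:
        with _stage("stereology", case.case_id):
            if "z_um" not in truth.cells.columns or truth.cells["z_um"].isna().any():
                raise ValueError("stereology requires z-resolved ground truth")
            cfg = DisectorConfig(**{**config.disector, "seed": seed})
            stereo = adaptive_sampling(truth, roi_manual, cfg)
            area = stereo.v_sampled_mm3 / (
                (cfg.disector_height_um or max(truth.thickness_T - 2 * cfg.guard_um, 1.0)) / 1000.0
            )
            densities["stereology"] = DensityResult(
                n_profiles=stereo.sum_Q,
                area_mm2=area,
                T_um=truth.thickness_T,
                h_um=0.0,
                Na=stereo.sum_Q / area if area > 0 else 0.0,
                abercrombie_factor=1.0,  # 3D counting needs no correction
                Nv=stereo.Nv,
                size_fractions=None,
                method="stereology",
            )
            rois["stereology"] = roi_manual

    logger.info(
        "case %s: %s",
        case.case_id,
        {m: f"n={d.n_profiles} area={d.area_mm2:.2f}mm2 Nv={d.Nv:.0f}" for m, d in densities.items()},
    )
    return CaseQuantification(
        case_id=case.case_id,
        group=case.group,
        densities=densities,
        stereology=stereo,
        compartment_map=cmap,
        rois=rois,
        detections=all_dets,
    )


def _retest_case(case: CohortCase, config: RunConfig, quant: CaseQuantification, retest_seed: int) -> dict[str, float]:
    """Repeat the analysis of one case for the reliability study."""
    out: dict[str, float] = {}
    methods = []
    for m in config.methods:
        if m in quant.densities:
            methods.append(m)
    redo = quantify_case(case, config, seed=retest_seed)
    for m in methods:
        if m in ("wsa_auto", "wsa_manual"):
            # deterministic given the raster: re-analysis reproduces exactly
            out[m] = quant.densities[m].Nv
        elif m in redo.densities:
            out[m] = redo.densities[m].Nv
    return out


def reliability_stage(
    cases: list[CohortCase],
    quants: list[CaseQuantification],
    config: RunConfig,
) -> dict[str, cstats.ReliabilityReport]:
    """Re-analyse a subset of cases and compute agreement per method."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n = min(config.n_retest, len(cases))
    idx = rng.choice(len(cases), size=n, replace=False)
    reports: dict[str, cstats.ReliabilityReport] = {}
    pairs: dict[str, list[tuple[float, float]]] = {m: [] for m in config.methods}
    for rank, i in enumerate(idx):
        case, quant = cases[i], quants[i]
        retest_seed = int(rng.integers(0, 2**31 - 1))
        redo = _retest_case(case, config, quant, retest_seed)
        for m, retest_value in redo.items():
            if m == "stereology" and rank >= config.n_retest_stereology:
                continue
            pairs[m].append((quant.densities[m].Nv, retest_value))
    for m, p in pairs.items():
        if len(p) >= 2:
            reports[m] = cstats.test_retest(p)
    return reports


def simulate_stage(config: RunConfig, out_dir: str | Path) -> list[CohortCase]:
    """Generate the cohort and write slides plus ground truth."""
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    needs_render = any(m in config.methods for m in ("wsa_auto", "wsa_manual", "sa"))
    cases = generate_cohort(config.cohort_spec(), render=needs_render)
    for case in cases:
        if case.slide is not None:
            case.slide.to_tiff(out / "slides" / f"{case.case_id}.tiff")
        case.truth.to_csv(out / "truth" / f"{case.case_id}.csv")
        (out / "truth" / f"{case.case_id}.json").write_text(
            json.dumps(
                {
                    **case.truth.sidecar(),
                    "group": case.group,
                    "config": dataclasses.asdict(case.config),
                },
                indent=1,
            )
        )
    return cases


def load_cases(run_dir: str | Path) -> list[CohortCase]:
    """Reload a simulated cohort from the artifacts written by simulate."""
    from .synthetic import sample_ground_truth, slide_geometry

    out = Path(run_dir)
    cases = []
    for sidecar in sorted((out / "truth").glob("*.json")):
        meta = json.loads(sidecar.read_text())
        cfg_dict = dict(meta["config"])
        for key in ("control_Nv_range", "epilepsy_Nv_range"):
            cfg_dict.pop(key, None)
        cfg = SlideConfig(**cfg_dict)
        case_id = sidecar.stem
        cells = pd.read_csv(out / "truth" / f"{case_id}.csv")
        truth = GroundTruth(
            cells=cells,
            true_Nv_wm=meta["true_Nv_wm"],
            true_Na_wm=meta["true_Na_wm"],
            wm_area_mm2=meta["wm_area_mm2"],
            thickness_T=meta["thickness_T"],
            mpp=meta["mpp"],
            geometry=slide_geometry(cfg),
        )
        tiff = out / "slides" / f"{case_id}.tiff"
        slide = SlideImage.from_tiff(tiff) if tiff.exists() else None
        cases.append(
            CohortCase(case_id=case_id, group=meta["group"], config=cfg, slide=slide, truth=truth)
        )
    return cases


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full simulate → quantify → stats → classify pipeline.

    Returns the run directory. See the module docstring for the artifact
    layout.
    """
    out = Path(out_dir)
    for sub in ("slides", "truth", "masks", "detections", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "effective_config.yaml")
        logger.info("effective config: %s", dataclasses.asdict(config))

        needs_render = any(m in config.methods for m in ("wsa_auto", "wsa_manual", "sa"))
        cases = generate_cohort(config.cohort_spec(), render=needs_render)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA5E]))
        quants = []
        rows: list[tuple[str, DensityResult]] = []
        for case in cases:
            if case.slide is not None:
                case.slide.to_tiff(out / "slides" / f"{case.case_id}.tiff")
            case.truth.to_csv(out / "truth" / f"{case.case_id}.csv")
            (out / "truth" / f"{case.case_id}.json").write_text(
                json.dumps(
                    {
                        **case.truth.sidecar(),
                        "group": case.group,
                        "config": dataclasses.asdict(case.config),
                    },
                    indent=1,
                )
            )
            case_seed = int(rng.integers(0, 2**31 - 1))
            quant = quantify_case(case, config, seed=case_seed)
            quants.append(quant)
            for m, dets in quant.detections.items():
                write_detections_csv(dets, out / "detections" / f"{case.case_id}_{m}.csv")
            if quant.compartment_map is not None:
                tifffile.imwrite(
                    out / "masks" / f"{case.case_id}_compartments.tiff",
                    quant.compartment_map.labels,
                )
            for m, dens in quant.densities.items():
                rows.append((case.case_id, dens))

        table = results_to_frame(rows)
        groups = {c.case_id: c.group for c in cases}
        table.insert(1, "group", table["case_id"].map(groups))
        table.to_csv(out / "densities.csv", index=False)

        # statistics: method comparison, group comparison, reliability
        wide = table.pivot(index="case_id", columns="method", values="Nv")
        report: dict = {"methods": list(config.methods)}
        if len(config.methods) >= 2 and len(wide) >= 3:
            report["method_comparison"] = [
                dataclasses.asdict(c) for c in cstats.compare_methods(wide[list(config.methods)])
            ]
        group_rows = []
        for m in config.methods:
            sub = table[table["method"] == m]
            if (sub["group"] == "control").sum() >= 1 and (sub["group"] == "epilepsy").sum() >= 1:
                comp = cstats.compare_groups(
                    sub["Nv"].to_numpy(), sub["group"].to_numpy(), "epilepsy", "control"
                )
                group_rows.append({"method": m, **dataclasses.asdict(comp)})
        report["group_comparison"] = group_rows
        reliability = reliability_stage(cases, quants, config)
        report["reliability"] = {m: dataclasses.asdict(r) for m, r in reliability.items()}
        (out / "reports" / "stats.json").write_text(json.dumps(report, indent=1, default=float))

        # classification against the control reference of the gold method
        gold = config.gold_method
        if gold in config.methods:
            sub = table[table["method"] == gold].set_index("case_id")
            controls = sub[sub["group"] == "control"]["Nv"]
            if len(controls) >= 2:
                ref = mmcd.fit_control_reference(controls.tolist(), method=gold)
                calls = mmcd.classify_cohort(sub["Nv"].to_dict(), ref)
                calls.insert(0, "group", [groups[c] for c in calls.index])
                calls.to_csv(out / "classification.csv")
        logger.info("run complete: %d cases, methods %s", len(cases), config.methods)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
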