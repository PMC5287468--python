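"""Pipeline orchestration: simulate -> detect -> measure -> symmetry ->
gold -> report, with YAML configuration and per-stage artifacts.

Every stochastic stage derives its seed deterministically from the global
seed, so a rerun with an identical config produces byte-identical
artifacts (report.json is written with sorted keys and no timestamps;
stage timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import goldassoc, imaging_io, morphometry, poredetect, symmetry, synthgen

logger = logging.getLogger("poremark")

STAGES = ("simulate", "detect", "measure", "symmetry", "gold", "report")

REPORT_SCHEMA_VERSION = 1


class PipelineStageError(RuntimeError):
    """A stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    outdir: str = "poremark_run"
    # scene
    sheet_width_nm: float = 1000.0
    sheet_height_nm: float = 1000.0
    mask_shape: str = "rectangle"  # or "ellipse"
    density_per_um2: float = synthgen.FRACTION3_DENSITY
    min_separation_nm: float = 35.0
    pore_class: str = "large"  # large | medium | small
    snr: float = 5.0
    psf_sigma_nm: float = 1.0
    pixel_size_nm: float = synthgen.PIXEL_SIZE_NM
    # detection
    radius_grid_nm: tuple[float, ...] = (14.75, 16.75, 18.75)
    score_threshold: float = 0.35
    nms_min_separation_nm: float = 30.0
    use_truth_mask: bool = True
    # morphometry
    patch_radius_nm: float = 36.85
    max_patches: int = 50
    # symmetry
    n_max: int = 12
    control_m: int = 99
    # gold
    gold_n_particles: int = 440
    gold_frac_associated: float = 0.9
    gold_threshold_nm: float = 20.0
    gold_permutations: int = 199

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list is empty")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)} (valid: {STAGES})")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["radius_grid_nm"] = list(self.radius_grid_nm)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d["stages"])
        d["radius_grid_nm"] = tuple(d["radius_grid_nm"])
        return cls(**d)


#: Presets encoding the published study conditions.
PRESETS: dict[str, dict] = {
    # negative-stain lysed-cell membrane sheets: 87 pores / um^2
    "study-lysed-sheet": {"density_per_um2": synthgen.LYSED_SHEET_DENSITY, "pore_class": "large"},
    # cryo-EM membrane fraction 3: 200 pores / um^2
    "study-fraction3-sheet": {"density_per_um2": synthgen.FRACTION3_DENSITY, "pore_class": "large"},
    # single large-pore morphometry/symmetry conditions
    "study-large-pore": {
        "density_per_um2": 40.0,
        "pore_class": "large",
        "snr": 5.0,
        "sheet_width_nm": 1200.0,
        "sheet_height_nm": 1200.0,
    },
    # immunogold counting conditions (~440 particles, 20 nm rule)
    "study-gold": {
        "density_per_um2": synthgen.LYSED_SHEET_DENSITY,
        "gold_n_particles": 440,
        "gold_frac_associated": 0.9,
        "gold_threshold_nm": 20.0,
    },
}

_CLASSES = {
    "large": synthgen.LARGE_PORE,
    "medium": synthgen.MEDIUM_PORE,
    "small": synthgen.SMALL_PORE,
}


def config_from_preset(preset: str, **overrides) -> RunConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r} (have {sorted(PRESETS)})")
    d = dict(PRESETS[preset])
    d.update(overrides)
    return RunConfig(**d)


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([global_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in canonical order; returns the report.

    All artifacts land in ``cfg.outdir``. A stage failure raises
    :class:`PipelineStageError` naming the stage; artifacts of completed
    stages are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": cfg.seed, "stages": {}}
    state: dict = {}
    model = _CLASSES[cfg.pore_class]

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            _run_stage(stage, cfg, model, state, report, outdir)
        except Exception as exc:  # noqa: BLE001 - named re-raise per contract
            raise PipelineStageError(stage, exc) from exc
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return report


def _run_stage(stage, cfg: RunConfig, model, state, report, outdir: Path) -> None:
    if stage == "simulate":
        mask_fn = synthgen.rectangle_mask if cfg.mask_shape == "rectangle" else synthgen.ellipse_mask
        mask = mask_fn(cfg.sheet_width_nm, cfg.sheet_height_nm, cfg.pixel_size_nm)
        scene = synthgen.SheetScene(
            mask=mask,
            density=cfg.density_per_um2,
            min_separation=cfg.min_separation_nm,
            pore_mix=synthgen.PoreClassMix.single(model),
            noise_sigma=synthgen.noise_sigma_for_snr(model, cfg.snr),
            psf_sigma=cfg.psf_sigma_nm,
            pixel_size=cfg.pixel_size_nm,
            seed=_stage_seed(cfg.seed, "simulate"),
        )
        img, truth = synthgen.render_sheet(scene)
        imaging_io.write_micrograph(img, outdir / "sheet.tif")
        truth.pores_csv(outdir / "truth_pores.csv")
        state.update(scene=scene, img=img, truth=truth)
        report["stages"]["simulate"] = {
            "n_pores": len(truth.pores),
            "density_requested_per_um2": cfg.density_per_um2,
            "mask_area_um2": mask.area_um2,
            "noise_sigma": scene.noise_sigma,
        }

    elif stage == "detect":
        img = state.get("img") or imaging_io.read_micrograph(outdir / "sheet.tif")
        if cfg.use_truth_mask and "scene" in state:
            mask = poredetect.MembraneMask(state["scene"].mask.mask, img.pixel_size)
        else:
            mask = poredetect.make_membrane_mask(img)
        dt = poredetect.detect_pores(
            img,
            mask,
            radius_grid_nm=cfg.radius_grid_nm,
            score_threshold=cfg.score_threshold,
            min_separation_nm=cfg.nms_min_separation_nm,
        )
        dt.to_dataframe().to_csv(outdir / "detections.csv", index=False)
        (outdir / "detect_params.json").write_text(json.dumps(dt.params_dict(), sort_keys=True))
        density = poredetect.estimate_density(dt)
        state.update(detections=dt, mask=mask)
        report["stages"]["detect"] = {
            "n_detections": len(dt),
            "density_per_um2": density["density_per_um2"],
            "density_ci95_per_um2": list(density["ci95_per_um2"]),
        }

    elif stage == "measure":
        img = state.get("img") or imaging_io.read_micrograph(outdir / "sheet.tif")
        centers = _analysis_centers(state, outdir)
        rows = []
        measured = []
        for i, (x, y) in enumerate(centers[: cfg.max_patches]):
            try:
                patch = imaging_io.extract_patch(img, (x, y), cfg.patch_radius_nm)
                meas = morphometry.measure_patch(patch)
            except ValueError:
                continue
            measured.append(meas)
            rows.append(
                {
                    "pore_id": i,
                    "d_plug_nm": meas.d_plug_nm,
                    "d_inner_nm": meas.d_inner_nm,
                    "d_outer_nm": meas.d_outer_nm,
                    "flags": ";".join(meas.flags),
                }
            )
        pd.DataFrame(rows, columns=["pore_id", "d_plug_nm", "d_inner_nm", "d_outer_nm", "flags"]).to_csv(
            outdir / "ring_measurements.csv", index=False
        )
        summary = morphometry.summarize_measurements(measured)
        (outdir / "ring_summary.json").write_text(json.dumps(summary, sort_keys=True))
        state["measurements"] = measured
        report["stages"]["measure"] = {"n_measured": len(measured), "summary": summary}

    elif stage == "symmetry":
        img = state.get("img") or imaging_io.read_micrograph(outdir / "sheet.tif")
        centers = _analysis_centers(state, outdir)
        if not centers:
            raise ValueError("no pore centre available for symmetry analysis")
        scan = None
        for x, y in centers:
            try:
                patch = imaging_io.extract_patch(img, (x, y), cfg.patch_radius_nm)
            except ValueError:
                continue
            scan = symmetry.assess_symmetry(
                patch,
                n_max=cfg.n_max,
                seed=_stage_seed(cfg.seed, "symmetry"),
                d_plug_nm=model.d_plug,
                d_outer_nm=model.d_outer,
                control_m=cfg.control_m,
            )
            break
        if scan is None:
            raise ValueError("no analyzable patch for symmetry")
        (outdir / "symmetry_scan.json").write_text(json.dumps(scan.as_dict(), sort_keys=True))
        report["stages"]["symmetry"] = scan.as_dict()

    elif stage == "gold":
        truth = state.get("truth")
        if truth is None or len(truth.pores) == 0:
            raise ValueError("gold stage requires a simulated scene with pores")
        scene = state["scene"]
        truth = synthgen.place_gold(
            truth,
            scene.mask,
            frac_associated=cfg.gold_frac_associated,
            threshold=cfg.gold_threshold_nm,
            n_particles=cfg.gold_n_particles,
            seed=_stage_seed(cfg.seed, "gold"),
        )
        truth.gold_csv(outdir / "truth_gold.csv")
        pores = truth.pores[["x_nm", "y_nm", "r_outer_nm"]].to_numpy()
        g = goldassoc.GoldParticleSet(
            truth.gold[["x_nm", "y_nm"]].to_numpy(),
            pores=pores,
            threshold_nm=cfg.gold_threshold_nm,
        )
        mmask = poredetect.MembraneMask(scene.mask.mask, scene.pixel_size)
        p, res = goldassoc.permutation_enrichment(
            g, mmask, B=cfg.gold_permutations, seed=_stage_seed(cfg.seed, "gold") + 1
        )
        res.to_dataframe().to_csv(outdir / "gold_association.csv", index=False)
        state["gold_result"] = res
        report["stages"]["gold"] = res.as_dict()

    elif stage == "report":
        # ground-truth comparison where the scene is known
        if "truth" in state and "measurements" in state:
            truth_model = model
            report["recovery"] = {
                "true_d_outer_nm": truth_model.d_outer,
                "true_d_inner_nm": truth_model.d_inner,
                "true_d_plug_nm": truth_model.d_plug,
            }
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))


def _analysis_centers(state, outdir: Path) -> list[tuple[float, float]]:
    """Pore centres for measurement: detections when available (best score
    first, edge detections last), else ground truth."""
    if "detections" in state:
        dets = sorted(state["detections"].detections, key=lambda d: (d.edge, -d.score))
        return [(d.x_nm, d.y_nm) for d in dets]
    det_csv = outdir / "detections.csv"
    if det_csv.exists():
        df = pd.read_csv(det_csv).sort_values(["edge_flag", "score"], ascending=[True, False])
        return list(zip(df.x_nm, df.y_nm))
    if "truth" in state:
        df = state["truth"].pores
        return list(zip(df.x_nm, df.y_nm))
    truth_csv = outdir / "truth_pores.csv"
    if truth_csv.exists():
        df = pd.read_csv(truth_csv)
        return list(zip(df.x_nm, df.y_nm))
    return []
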