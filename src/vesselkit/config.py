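"""Pipeline configuration and orchestration.

A :class:`PipelineConfig` bundles every stage's parameters with the
published defaults (demons sigma 1.3, 1/99 normalization percentiles,
1 um^3 resampling, 3x3x3 mean filter, 100-voxel object filter, 11-voxel
dead-end pruning, 10 um capillary cutoff, 50% dropout) and round-trips
through YAML.  :func:`run_pipeline` executes the stages in acquisition
order — register, normalize, resample, segment, postprocess, centerline,
morphometry, evaluate — writing each stage's artifact plus a provenance
record (config hash, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import centerline, io, metrics, morphometry, phantom, postprocess, preprocess
from ._version import __version__
from .core import ImageStack
from .model import ModelConfig, PRESETS, VesselPatchCNN, predict_volume

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class StageToggles:
    register: bool = True
    normalize: bool = True
    resample: bool = True
    segment: bool = True
    postprocess: bool = True
    centerline: bool = True
    morphometry: bool = True
    evaluate: bool = False


@dataclass
class PipelineConfig:
    schema_version: int = CONFIG_SCHEMA_VERSION
    input_path: str = ""
    output_dir: str = "vesselkit_out"
    ground_truth_path: str | None = None
    weights_path: str | None = None
    voxel_size_um: tuple[float, float, float] | None = None
    stages: StageToggles = field(default_factory=StageToggles)
    registration_sigma: float = preprocess.DEFAULT_DEMONS_SIGMA
    registration_iterations: int = preprocess.DEFAULT_DEMONS_ITERATIONS
    registration_levels: int = preprocess.DEFAULT_PYRAMID_LEVELS
    normalize_low_pct: float = 1.0
    normalize_high_pct: float = 99.0
    resample_target_um: float = 1.0
    model_preset: str = "desk"
    model: ModelConfig = field(default_factory=lambda: dataclasses.replace(PRESETS["desk"]))
    segment_threshold: float = 0.5
    min_object_voxels: int = postprocess.DEFAULT_MIN_VOXELS
    min_deadend_len: int = centerline.DEFAULT_MIN_DEADEND_LEN
    centerline_repair: bool = True
    capillary_max_diameter_um: float = morphometry.CAPILLARY_MAX_DIAMETER_UM
    boundary_connectivity: int = 1
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if d.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {d.get('schema_version')}")
        if "stages" in d and isinstance(d["stages"], dict):
            d["stages"] = StageToggles(**d["stages"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        if d.get("voxel_size_um") is not None:
            d["voxel_size_um"] = tuple(d["voxel_size_um"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    provenance = {
        "vesselkit_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages_run": [],
    }

    def _stage(name):
        def deco(fn):
            def run(*a, **k):
                try:
                    r = fn(*a, **k)
                except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                    _write_provenance()
                    raise PipelineError(name, exc) from exc
                provenance["stages_run"].append(name)
                return r

            return run

        return deco

    def _write_provenance():
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        artifacts["provenance"] = str(out_dir / "provenance.json")

    stack = io.read_image(cfg.input_path, cfg.voxel_size_um)
    log.info("input %s: shape=%s spacing=%s um", cfg.input_path, stack.shape, stack.voxel_size_um)

    if cfg.stages.register:
        stack, fields = _stage("register")(preprocess.register_stack)(
            stack, cfg.registration_sigma, cfg.registration_iterations, cfg.registration_levels
        )
        io.write_image(out_dir / "registered.tif", stack)
        np.savez_compressed(out_dir / "deformation_fields.npz", fields=fields.fields)
        artifacts["registered"] = str(out_dir / "registered.tif")

    if cfg.stages.normalize:
        stack = _stage("normalize")(preprocess.normalize_intensity)(
            stack, cfg.normalize_low_pct, cfg.normalize_high_pct
        )
    if cfg.stages.resample:
        stack = _stage("resample")(preprocess.resample_isotropic)(stack, cfg.resample_target_um)
    if cfg.stages.normalize or cfg.stages.resample:
        io.write_image(out_dir / "preprocessed.tif", stack)
        artifacts["preprocessed"] = str(out_dir / "preprocessed.tif")
    log.info("preprocessed: shape=%s spacing=%s um", stack.shape, stack.voxel_size_um)

    seg = None
    if cfg.stages.segment:
        if cfg.weights_path is None:
            raise PipelineError("segment", ValueError("segmentation requires weights_path"))
        model = VesselPatchCNN.load(cfg.weights_path, cfg=cfg.model)
        prob, seg = _stage("segment")(predict_volume)(model, stack, cfg.segment_threshold)
        io.write_image(out_dir / "probability.tif", ImageStack(prob, stack.voxel_size_um))
        io.write_mask(out_dir / "mask.tif", seg, stack.voxel_size_um)
        artifacts["mask"] = str(out_dir / "mask.tif")

    if cfg.stages.postprocess and seg is not None:
        seg = _stage("postprocess")(postprocess.postprocess_volume)(seg, cfg.min_object_voxels)
        io.write_mask(out_dir / "mask_clean.tif", seg, stack.voxel_size_um)
        artifacts["mask_clean"] = str(out_dir / "mask_clean.tif")

    graph = None
    if cfg.stages.centerline and seg is not None:
        graph = _stage("centerline")(centerline.extract_centerline_graph)(
            seg, stack.voxel_size_um, cfg.centerline_repair, cfg.min_deadend_len
        )
        graph.save_json(out_dir / "centerlines.json")
        artifacts["centerlines"] = str(out_dir / "centerlines.json")
        log.info("centerline graph: %d nodes, %d edges", len(graph.nodes), len(graph.edges))

    if cfg.stages.morphometry and graph is not None and seg is not None:
        segments = _stage("morphometry")(morphometry.measure_segments)(graph, seg)
        io.write_segments_csv(out_dir / "segments.csv", segments)
        capillaries = morphometry.capillary_filter(segments, cfg.capillary_max_diameter_um)
        io.write_segments_csv(out_dir / "capillaries.csv", capillaries)
        artifacts["segments"] = str(out_dir / "segments.csv")
        artifacts["capillaries"] = str(out_dir / "capillaries.csv")

    if cfg.stages.evaluate:
        if cfg.ground_truth_path is None:
            raise PipelineError("evaluate", ValueError("evaluation requires ground_truth_path"))
        gt = io.read_mask(cfg.ground_truth_path)
        target = seg if seg is not None else io.read_mask(cfg.input_path)
        report = _stage("evaluate")(metrics.evaluation_report)(target, gt, cfg.boundary_connectivity)
        (out_dir / "metrics.json").write_text(json.dumps(report, indent=2))
        artifacts["metrics"] = str(out_dir / "metrics.json")

    _write_provenance()
    return artifacts


FIXTURE_NAMES = ("straight_tube", "y_junction", "gapped_tube", "loop", "network")


def make_fixtures(seed: int, out_dir) -> dict[str, dict[str, str]]:
    """Write the canonical phantom suite (image + truth mask + truth graph).

    Five cases: a straight tube, a Y junction, a gapped tube, a loop, and a
    multi-vessel network degraded with shadows, depth decay, noise and
    per-slice motion.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = phantom.PhantomSpec(seed=seed)
    cases = {
        "straight_tube": phantom.straight_tube_phantom(),
        "y_junction": phantom.y_junction_phantom(),
        "gapped_tube": phantom.gapped_tube_phantom(),
        "loop": phantom.loop_phantom(),
        "network": phantom.add_slice_motion(
            phantom.add_noise_and_depth_decay(
                phantom.add_rbc_shadows(phantom.generate_tube_network(spec), spec), spec
            ),
            spec,
        ),
    }
    written: dict[str, dict[str, str]] = {}
    for name, out in cases.items():
        paths = {
            "image": str(out_dir / f"{name}_image.tif"),
            "mask": str(out_dir / f"{name}_mask.tif"),
            "graph": str(out_dir / f"{name}_graph.json"),
            "segments": str(out_dir / f"{name}_segments.csv"),
        }
        io.write_image(paths["image"], out.image)
        io.write_mask(paths["mask"], out.truth_mask, out.image.voxel_size_um)
        out.truth_centerlines.save_json(paths["graph"])
        io.write_segments_csv(paths["segments"], out.truth_segments)
        written[name] = paths
    return written
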