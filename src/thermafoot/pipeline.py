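"""End-to-end session processing: decode -> correct -> invert -> register.

Runs the full chain on one radiometric container and a set of calibration
gain fields, writing every intermediate raster to the session directory and
appending one provenance entry per stage to the patient record.  A stage
failure aborts with the stage name while preserving the partial record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from . import flir_io, radiometry, registration, vignetting
from .flir_io import PatientRecord, append_step, init_record
from .geometry import CameraIntrinsics, undistort
from .marker_lwir import ComponentFilterConfig, detect_lwir_markers
from .marker_vis import VisMarkerConfig, detect_vis_markers
from .matching import MatchConfig, NoMatchError, ransac_match

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_session"]


@dataclass
class PipelineConfig:
    """Every tunable default of the chain, overridable from file or CLI."""

    vis_markers: VisMarkerConfig = field(default_factory=VisMarkerConfig)
    lwir_markers: ComponentFilterConfig = field(default_factory=ComponentFilterConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)
    transform_family: str = "affine"
    fusion_mode: str = "edges"
    fusion_alpha: float = 0.5
    master_rms_threshold: float = vignetting.MASTER_RMS_THRESHOLD
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "vis_markers" in kw:
            kw["vis_markers"] = VisMarkerConfig(**kw["vis_markers"])
        if "lwir_markers" in kw:
            kw["lwir_markers"] = ComponentFilterConfig(**kw["lwir_markers"])
        if "matching" in kw:
            kw["matching"] = MatchConfig(**kw["matching"])
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text) or {})
        if str(path).endswith(".toml"):
            import tomllib
            return cls.from_dict(tomllib.loads(text))
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial record."""

    def __init__(self, stage: str, cause: Exception, record: PatientRecord):
        self.stage = stage
        self.cause = cause
        self.record = record
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


def _zero_intrinsics(width: int, height: int) -> CameraIntrinsics:
    return CameraIntrinsics(fx=max(width, height), fy=max(width, height),
                            cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                            width=width, height=height)


def run_session(jpeg_path, out_dir, gains: list[vignetting.GainField],
                config: PipelineConfig | None = None,
                lwir_intrinsics: CameraIntrinsics | None = None,
                vis_intrinsics: CameraIntrinsics | None = None
                ) -> PatientRecord:
    """Process one radiometric container end to end.

    Stages: decode, vignetting correction (master or interpolated gain),
    temperature inversion, undistortion of both modalities, marker
    detection in both, RANSAC matching, transform fit + warp + fusion.
    Returns the enriched record (also written to ``out_dir/record.json``).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record: PatientRecord | None = None
    digest = cfg.digest()

    def _stage(name):
        def deco(fn):
            def run(*a, **kw):
                t0 = time.perf_counter()
                result = fn(*a, **kw)
                log.info("stage=%s elapsed=%.3fs config=%s",
                         name, time.perf_counter() - t0, digest)
                return result
            return run
        return deco

    def _append(rec, name, params):
        # deterministic provenance timestamps (stage index) so that rerun
        # with the same config/seed produces bit-identical records
        return append_step(rec, name, params,
                           timestamp=float(len(rec.provenance)))

    def _fail(stage: str, exc: Exception):
        if record is not None:
            record.to_json(out / "record.json")
        raise PipelineError(stage, exc, record) from exc

    # 1. decode ------------------------------------------------------------
    try:
        frame, visible, params, meta = flir_io.read_radiometric_jpeg(jpeg_path)
    except Exception as e:
        raise PipelineError("decode", e, None) from e
    record = init_record(meta, params)
    tifffile.imwrite(out / "raw_counts.tiff",
                     frame.counts.astype(np.float32))
    Image.fromarray(visible).save(out / "visible.png")
    record.artifacts["raw"] = str(out / "raw_counts.tiff")
    record.artifacts["vis"] = str(out / "visible.png")
    record = _append(record, "decode", {"source": str(jpeg_path),
                                            "config": digest})

    # 2. vignetting correction ----------------------------------------------
    try:
        gain, gain_mode = vignetting.select_gain(
            gains, frame.timestamp, cfg.master_rms_threshold)
        corrected = vignetting.apply_gain_correction(frame, gain)
    except Exception as e:
        _fail("vignetting", e)
    tifffile.imwrite(out / "corrected_counts.tiff",
                     corrected.counts.astype(np.float32))
    record.artifacts["corrected"] = str(out / "corrected_counts.tiff")
    record = _append(record, "vignetting",
                         {"mode": gain_mode,
                          "threshold": cfg.master_rms_threshold})

    # 3. temperature ---------------------------------------------------------
    try:
        T = radiometry.frame_to_temperature(corrected, None, params)
    except Exception as e:
        _fail("temperature", e)
    tifffile.imwrite(out / "temperature.tiff", T.values.astype(np.float32))
    record.artifacts["temperature"] = str(out / "temperature.tiff")
    record = _append(record, "temperature",
                         {"atm_formula": params.atm_formula,
                          "emissivity": params.emissivity})

    # 4. undistortion --------------------------------------------------------
    try:
        li = lwir_intrinsics or _zero_intrinsics(frame.width, frame.height)
        vi = vis_intrinsics or _zero_intrinsics(visible.shape[1],
                                                visible.shape[0])
        T_und, lwir_valid = undistort(T.values, li)
        vis_und, vis_valid = undistort(visible, vi)
    except Exception as e:
        _fail("undistort", e)
    record = _append(record, "undistort",
                         {"lwir": dataclasses.asdict(li),
                          "vis": dataclasses.asdict(vi)})

    # 5-6. marker detection ---------------------------------------------------
    try:
        vis_dets = detect_vis_markers(vis_und, cfg.vis_markers,
                                      valid_mask=vis_valid)
    except Exception as e:
        _fail("detect_vis", e)
    record = _append(record, "detect_vis",
                         {"n": len(vis_dets),
                          **dataclasses.asdict(cfg.vis_markers)})
    try:
        lwir_dets = detect_lwir_markers(T_und, cfg.lwir_markers)
    except Exception as e:
        _fail("detect_lwir", e)
    record = _append(record, "detect_lwir",
                         {"n": len(lwir_dets),
                          **dataclasses.asdict(cfg.lwir_markers)})
    dets_json = {
        "vis": [dataclasses.asdict(d) for d in vis_dets],
        "lwir": [dataclasses.asdict(d) for d in lwir_dets],
    }
    (out / "detections.json").write_text(json.dumps(dets_json, indent=2))
    record.artifacts["detections"] = str(out / "detections.json")

    # 7. matching --------------------------------------------------------------
    ir_pts = np.array([[d.x, d.y] for d in lwir_dets])
    vis_pts = np.array([[d.x, d.y] for d in vis_dets])
    try:
        corr = ransac_match(ir_pts, vis_pts, cfg.matching, seed=cfg.seed)
    except NoMatchError as e:
        record = _append(record, "match",
                             {"status": "no-match", **e.diagnostics})
        _fail("match", e)
    except Exception as e:
        _fail("match", e)
    corr_json = {"pairs": corr.pairs,
                 "matrix": corr.transform.as_matrix()[:2].ravel().tolist(),
                 "residuals": corr.residuals.tolist(),
                 "rho_x": corr.rho_x, "rho_y": corr.rho_y,
                 "seed": cfg.seed, "config": digest}
    (out / "correspondences.json").write_text(json.dumps(corr_json, indent=2))
    record.artifacts["correspondences"] = str(out / "correspondences.json")
    record = _append(record, "match",
                         {"n_pairs": corr.n_pairs, "seed": cfg.seed,
                          "rho_x": corr.rho_x, "rho_y": corr.rho_y})

    # 8. registration + fusion ----------------------------------------------
    try:
        matched_vis = vis_pts[[j for _, j in corr.pairs]]
        matched_ir = ir_pts[[i for i, _ in corr.pairs]]
        fitted = registration.fit_transform(matched_vis, matched_ir,
                                            cfg.transform_family)
        warped, _valid = registration.warp_vis_to_lwir(
            vis_und, fitted, T_und.shape)
        fused = registration.fuse_overlay(T_und, warped, mode=cfg.fusion_mode,
                                          alpha=cfg.fusion_alpha)
    except Exception as e:
        _fail("register", e)
    Image.fromarray((fused * 255).astype(np.uint8)).save(out / "fused.png")
    record.artifacts["registered"] = str(out / "fused.png")
    fitted.to_json(out / "transform.json")
    record.artifacts["transform"] = str(out / "transform.json")
    record = _append(record, "register",
                         {"family": cfg.transform_family,
                          "residual_rms": fitted.rms,
                          "mode": cfg.fusion_mode})

    record.to_json(out / "record.json")
    return record
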