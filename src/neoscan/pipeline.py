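"""Three-plane analysis pipeline: configuration, execution, rendering.

A run is described by a versioned YAML config listing one or more scan
planes (image path, polygon ROIs, circular reference region) plus the
preprocessing and GLCM parameters.  Each plane is processed as
crop -> adaptive median filter -> CLAHE -> mask construction ->
echo-intensity + echo-homogeneity reports; stage images, masks, CSV/JSON
tables and a parameter/checksum log are written per plane.  A failing
plane is recorded and the remaining planes continue.

Re-running the same config (same seed for synthetic inputs) is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import io as nio
from .preprocess import (AmfConfig, ClaheConfig, adaptive_median_filter,
                         clahe, crop_black_margins)
from .quantify import (GlcmConfig, EchoIntensityReport, TextureFeatureTable,
                       homogeneity_report, intensity_report)
from .roi import RegionMask, circle_mask, polygon_mask

__all__ = ["PipelineConfig", "PlaneConfig", "RoiConfig", "PlaneBundle",
           "PipelineResult", "run_pipeline", "render_tables", "fmt4"]

SCHEMA_VERSION = 1
log = logging.getLogger("neoscan")


def fmt4(x: float) -> str:
    """4-decimal presentation, rounding half away from zero."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.0001"),
                                                rounding=ROUND_HALF_UP))


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")


@dataclass(frozen=True)
class RoiConfig:
    name: str
    vertices: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class PlaneConfig:
    name: str
    image: str
    rois: tuple[RoiConfig, ...]
    reference_center: tuple[float, float]
    reference_radius: float


@dataclass(frozen=True)
class PipelineConfig:
    planes: tuple[PlaneConfig, ...]
    crop_threshold: float = 0.95
    amf: AmfConfig = field(default_factory=AmfConfig)
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    output_dir: str = "neoscan-out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("config must list at least one plane")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        _check_keys(data, {"version", "seed", "output_dir", "preprocess",
                           "glcm", "planes"}, "config")
        version = data.get("version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config version {version}")
        pp = data.get("preprocess", {})
        _check_keys(pp, {"crop_threshold", "amf", "clahe"}, "preprocess")
        amf_d = pp.get("amf", {})
        _check_keys(amf_d, {"initial_window", "max_window"}, "preprocess.amf")
        clahe_d = pp.get("clahe", {})
        _check_keys(clahe_d, {"tile_rows", "tile_cols", "clip_factor"},
                    "preprocess.clahe")
        glcm_d = dict(data.get("glcm", {}))
        _check_keys(glcm_d, {"levels", "distance", "entropy_log_base",
                             "symmetric"}, "glcm")
        if glcm_d.get("entropy_log_base") == "e":
            glcm_d["entropy_log_base"] = math.e

        planes = []
        for pd_ in data.get("planes", []):
            _check_keys(pd_, {"name", "image", "rois", "reference"}, "plane")
            rois = []
            for rd in pd_.get("rois", []):
                _check_keys(rd, {"name", "vertices"}, "roi")
                rois.append(RoiConfig(str(rd["name"]),
                                      tuple(tuple(map(float, v))
                                            for v in rd["vertices"])))
            ref = pd_["reference"]
            _check_keys(ref, {"center", "radius"}, "reference")
            planes.append(PlaneConfig(
                name=str(pd_["name"]), image=str(pd_["image"]),
                rois=tuple(rois),
                reference_center=tuple(map(float, ref["center"])),
                reference_radius=float(ref["radius"])))
        return cls(
            planes=tuple(planes),
            crop_threshold=float(pp.get("crop_threshold", 0.95)),
            amf=AmfConfig(int(amf_d.get("initial_window", 3)),
                          int(amf_d.get("max_window", 7))),
            clahe=ClaheConfig(int(clahe_d.get("tile_rows", 8)),
                              int(clahe_d.get("tile_cols", 8)),
                              float(clahe_d.get("clip_factor", 4.0))),
            glcm=GlcmConfig(**glcm_d),
            output_dir=str(data.get("output_dir", "neoscan-out")),
            seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PlaneBundle:
    """Everything computed for one successfully processed plane."""

    name: str
    crop_bounds: dict[str, int]
    intensity: EchoIntensityReport
    homogeneity: list[TextureFeatureTable]
    roi_names: list[str]
    checksums: dict[str, str]


@dataclass
class PipelineResult:
    bundles: list[PlaneBundle]
    failures: list[dict[str, str]]

    @property
    def ok(self) -> bool:
        return not self.failures


def _build_masks(plane: PlaneConfig, shape: tuple[int, int],
                 ) -> tuple[list[RegionMask], RegionMask]:
    h, w = shape
    rois = [polygon_mask(r.vertices, h, w) for r in plane.rois]
    ref = circle_mask(plane.reference_center, plane.reference_radius, h, w)
    return rois, ref


def _process_plane(plane: PlaneConfig, cfg: PipelineConfig,
                   out_dir: Path) -> PlaneBundle:
    image = nio.read_gray(plane.image)
    checksums = {"input": _sha256(image.tobytes())}

    bounds, cropped = crop_black_margins(image, cfg.crop_threshold)
    filtered = adaptive_median_filter(cropped, cfg.amf)
    enhanced = clahe(filtered, cfg.clahe)
    for stage, arr in (("cropped", cropped), ("filtered", filtered),
                       ("clahe", enhanced)):
        path = out_dir / f"{plane.name}_{stage}.png"
        nio.write_gray(path, arr)
        checksums[stage] = _sha256(arr.tobytes())

    roi_masks, ref_mask = _build_masks(plane, enhanced.shape)
    for rcfg, mask in zip(plane.rois, roi_masks):
        nio.write_mask(out_dir / f"{plane.name}_mask_{rcfg.name}.png", mask.mask)
    nio.write_mask(out_dir / f"{plane.name}_mask_reference.png", ref_mask.mask)

    intensity = intensity_report(enhanced, roi_masks, ref_mask)
    homogeneity = homogeneity_report(enhanced, roi_masks, cfg.glcm)
    return PlaneBundle(plane.name, bounds.as_dict(), intensity, homogeneity,
                       [r.name for r in plane.rois], checksums)


def render_tables(bundle: PlaneBundle, out_dir: Path,
                  glcm_config: GlcmConfig) -> None:
    """Write a plane's intensity/homogeneity CSVs (4-decimal presentation)
    and a JSON report holding the full-precision values and parameters."""
    out_dir = Path(out_dir)
    intensity_df = bundle.intensity.to_frame()
    intensity_df["value"] = intensity_df["value"].map(fmt4)
    intensity_df.to_csv(out_dir / f"{bundle.name}_intensity.csv",
                        index_label="quantity")

    frames = []
    for suffix, table in enumerate(bundle.homogeneity, start=1):
        df = table.to_frame().map(fmt4)
        df.index = [f"{feat}{suffix}" for feat in df.index]
        frames.append(df)
    pd.concat(frames).to_csv(out_dir / f"{bundle.name}_homogeneity.csv",
                             index_label="feature")

    report = {
        "plane": bundle.name,
        "crop_bounds": bundle.crop_bounds,
        "checksums": bundle.checksums,
        "glcm": {"levels": glcm_config.levels, "distance": glcm_config.distance,
                 "entropy_log_base": ("e" if glcm_config.entropy_log_base == math.e
                                      else glcm_config.entropy_log_base),
                 "symmetric": glcm_config.symmetric},
        "intensity": {
            "roi_names": bundle.roi_names,
            "roi_means": list(bundle.intensity.roi_means),
            "reference_mean": bundle.intensity.reference_mean,
            "relative_gray_values": list(bundle.intensity.relative_values),
        },
        "homogeneity": [
            {row: dict(cols) for row, cols in
             table.to_frame().iterrows()}
            for table in bundle.homogeneity
        ],
    }
    with open(out_dir / f"{bundle.name}_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig,
                 output_dir: str | Path | None = None) -> PipelineResult:
    """Execute every plane of a pipeline config.

    Stage images, masks, CSV/JSON reports and a run log are written under
    ``output_dir`` (defaults to the config's).  A plane that raises is
    recorded as a machine-readable failure and the others continue.
    """
    out_dir = Path(output_dir if output_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    bundles: list[PlaneBundle] = []
    failures: list[dict[str, str]] = []
    try:
        log.info("parameters crop_threshold=%s amf=(%d,%d) clahe=(%dx%d,%s) "
                 "glcm=(G=%d,d=%d,base=%s,symmetric=%s) seed=%d",
                 config.crop_threshold, config.amf.initial_window,
                 config.amf.max_window, config.clahe.tile_rows,
                 config.clahe.tile_cols, config.clahe.clip_factor,
                 config.glcm.levels, config.glcm.distance,
                 config.glcm.entropy_log_base, config.glcm.symmetric,
                 config.seed)
        for plane in config.planes:
            try:
                bundle = _process_plane(plane, config, out_dir)
                render_tables(bundle, out_dir, config.glcm)
                bundles.append(bundle)
                for stage, digest in bundle.checksums.items():
                    log.info("plane=%s stage=%s sha256=%s",
                             plane.name, stage, digest)
            except Exception as exc:  # noqa: BLE001 - per-plane isolation
                record = {"plane": plane.name, "error": type(exc).__name__,
                          "message": str(exc)}
                failures.append(record)
                log.error("plane=%s failed: %s: %s", plane.name,
                          record["error"], record["message"])
        with open(out_dir / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=2)
    finally:
        log.removeHandler(handler)
        handler.close()
    return PipelineResult(bundles, failures)
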