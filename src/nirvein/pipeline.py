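"""End-to-end vein imaging chain and its YAML-backed configuration.

``run_pipeline`` executes preprocess -> segmentation -> centerline ->
stereo matching on a rectified NIR pair and writes every intermediate:
the enhanced images, the vein probability map and mask, the refined
centerline, and the disparity map (full and gated to the vein mask,
which is what a puncture-planning consumer reads depth from).
Segmentation uses a trained network checkpoint when one is configured
and otherwise falls back to thresholding the Hessian vesselness
response, so the classical path runs with no trained weights at all.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import centerline as C
from . import preprocess as P
from . import segnet as S
from . import stereo as ST
from .io import write_image, write_pfm

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: P.PreprocessConfig = field(default_factory=P.PreprocessConfig)
    hessian: C.HessianConfig = field(default_factory=C.HessianConfig)
    refine: C.RefineConfig = field(default_factory=C.RefineConfig)
    stereo: ST.StereoParams = field(default_factory=ST.StereoParams)
    net: S.NetConfig = field(default_factory=S.NetConfig)
    checkpoint: str | None = None
    stereo_input: str = "preprocessed"  # or "segmented"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stereo_input not in ("preprocessed", "segmented"):
            raise ValueError("stereo_input must be 'preprocessed' or 'segmented'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["clahe_tile_grid"] = list(self.preprocess.clahe_tile_grid)
        d["hessian"]["sigmas"] = list(self.hessian.sigmas)
        d["stereo"]["census_window"] = list(self.stereo.census_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = P.PreprocessConfig.from_dict(d["preprocess"])
        if "hessian" in d:
            h = dict(d["hessian"])
            h["sigmas"] = tuple(h["sigmas"])
            d["hessian"] = C.HessianConfig(**h)
        if "refine" in d:
            d["refine"] = C.RefineConfig(**d["refine"])
        if "stereo" in d:
            s = dict(d["stereo"])
            s["census_window"] = tuple(s["census_window"])
            d["stereo"] = ST.StereoParams(**s)
        if "net" in d:
            d["net"] = S.NetConfig(**d["net"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _segment(img: np.ndarray, cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg.checkpoint is not None:
        path = Path(cfg.checkpoint)
        if not path.exists():
            raise FileNotFoundError(
                f"segmentation checkpoint {path} not found; train one with "
                "'nirvein train' or drop the checkpoint setting to use the "
                "Hessian-response fallback"
            )
        net = S.load_checkpoint(path)
        return S.segment(net, img)
    resp = C.multiscale_response(img, cfg.hessian)
    mask = resp >= cfg.hessian.response_threshold
    return resp, mask


def run_pipeline(
    left: np.ndarray,
    right: np.ndarray,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Run the full chain on a rectified pair; returns all products.

    When ``out_dir`` is given every intermediate is written there along
    with the resolved configuration (``config.yaml``).
    """
    cfg = cfg or PipelineConfig()
    if cfg.stereo.d_max >= left.shape[1]:
        raise ValueError(
            f"d_max={cfg.stereo.d_max} must be smaller than the image width {left.shape[1]}"
        )
    pre_l = P.preprocess_pipeline(left, cfg.preprocess)
    pre_r = P.preprocess_pipeline(right, cfg.preprocess)
    prob, mask = _segment(pre_l, cfg)
    skel = C.extract_centerline(
        C.multiscale_response(pre_l, cfg.hessian), cfg.hessian
    )
    skel = C.refine_centerline(skel, cfg.refine)

    if cfg.stereo_input == "segmented":
        s_l, s_r = mask.astype(np.float64), _segment(pre_r, cfg)[1].astype(np.float64)
    else:
        s_l, s_r = pre_l, pre_r
    disparity = ST.match_pair(s_l, s_r, cfg.stereo)
    vein_disparity = np.where(mask, disparity, ST.INVALID)

    out = {
        "preprocessed_left": pre_l,
        "preprocessed_right": pre_r,
        "probability": prob,
        "mask": mask,
        "centerline": skel,
        "disparity": disparity,
        "vein_disparity": vein_disparity,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")
        write_image(out_dir / "preprocessed_left.png", pre_l)
        write_image(out_dir / "preprocessed_right.png", pre_r)
        write_image(out_dir / "mask.png", mask)
        write_image(out_dir / "centerline.png", skel)
        write_pfm(out_dir / "disparity.pfm", disparity)
        write_pfm(out_dir / "vein_disparity.pfm", vein_disparity)
        log.info("pipeline outputs written to %s", out_dir)
    return out
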