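"""End-to-end orchestration: borders → hairs → enhancement → GrabCut.

The returned mask always lives in the original input frame: when corner
borders were detached, the segmentation runs on the crop and the mask is
re-embedded at the recorded offset with the detached ring set to 0.  The
stage log records what each stage saw (borders/hairs present, the rectangle
used, iterations run) so a batch run is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import border_removal as br
from . import enhancement as enh
from . import grabcut as gc
from . import hair_removal as hr
from .image_core import StageError, rgb_to_gray, validate_rgb

__all__ = ["PipelineConfig", "StageLog", "run_pipeline"]


@dataclass
class PipelineConfig:
    border: br.BorderSearchConfig = field(default_factory=br.BorderSearchConfig)
    hair: hr.HairConfig = field(default_factory=hr.HairConfig)
    enhance: enh.EnhanceConfig = field(default_factory=enh.EnhanceConfig)
    grabcut: gc.GrabCutConfig = field(default_factory=gc.GrabCutConfig)
    border_removal_enabled: bool = True
    hair_removal_enabled: bool = True
    enhancement_enabled: bool = True


@dataclass
class StageLog:
    stages: list = field(default_factory=list)
    borders_present: bool = False
    hairs_present: bool = False
    corner_searches: int = 0
    offset: tuple[int, int] = (0, 0)
    rect: gc.RectSpec | None = None
    iterations: int = 0
    energy_trace: list = field(default_factory=list)


def run_pipeline(img: np.ndarray, cfg: PipelineConfig | None = None) -> tuple[np.ndarray, StageLog]:
    """Segment a dermoscopic image; returns the lesion mask (original frame) and a log."""
    cfg = cfg or PipelineConfig()
    img = validate_rgb(img)
    orig_shape = img.shape[:2]
    log = StageLog()
    work = img

    if cfg.border_removal_enabled:
        try:
            rects = br.detect_inner_rectangle(rgb_to_gray(work), cfg.border)
            log.borders_present = rects.borders_present
            log.corner_searches = rects.searches_run
            work, offset = br.remove_borders(work, rects)
            log.offset = offset
        except Exception as exc:
            raise StageError(f"border_removal: {exc}") from exc
        log.stages.append("border_removal")

    if cfg.hair_removal_enabled:
        try:
            work, hairs_present = hr.remove_hairs(work, cfg.hair)
            log.hairs_present = hairs_present
        except Exception as exc:
            raise StageError(f"hair_removal: {exc}") from exc
        log.stages.append("hair_removal")

    if cfg.enhancement_enabled:
        try:
            work = enh.enhance_image(work, cfg.enhance)
        except Exception as exc:
            raise StageError(f"enhancement: {exc}") from exc
        log.stages.append("enhancement")

    try:
        h, w = work.shape[:2]
        rect = gc.auto_rect(h, w, cfg.grabcut)
        trimap = gc.init_trimap(rect, h, w)
        state = gc.grabcut_iterate(work, trimap, cfg.grabcut)
        mask = (state.alpha * 255).astype(np.uint8)
        log.rect = rect
        log.iterations = state.iterations
        log.energy_trace = list(state.energy_trace)
    except Exception as exc:
        raise StageError(f"segmentation: {exc}") from exc
    log.stages.append("segmentation")

    return br.embed_mask(mask, log.offset, orig_shape), log
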