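"""End-to-end detection pipeline and suite evaluation.

``detect`` runs the full chain on one RGB image:

1. center-crop to an extent divisible by the window size (canonically
   400x400);
2. one HSV conversion; fruit/background separation by a single global Otsu
   threshold on the saturation channel;
3. two sliding-window passes over the masked saturation image — primary
   grid at the origin, secondary grid offset by half a window;
4. per-pass defect maps (fruit-masked complement of sound, within each
   pass's coverage) fused by weighted union, then morphological refinement;
5. stem rejection by circularity + hue;
6. optional evaluation against a ground-truth defect mask.

Everything is deterministic for a fixed input and configuration.  The run
log records per-stage timings and the Otsu bookkeeping that carries the
method's efficiency argument (one global threshold; few genuinely
thresholded windows).
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import background, windows
from ._counters import counters, reset_counters
from .color import rgb_to_hsv8
from .errors import ConfigError
from .fuse import DefectMap, FusionWeights, SE_POLICIES, fuse as fuse_maps, refine, to_defect_map
from .metrics import ConfusionCounts, MetricSet, mask_iou, metrics as compute_metrics, pixel_confusion, region_confusion
from .stems import StemFilterResult, filter_stems
from .synthetic import Scene


@dataclass
class PipelineConfig:
    """All tunable knobs of the detector, serializable to flat YAML."""

    window_n: int = 100
    delta_gate: float = 30.0
    pass2_offset: int | None = None  # None -> window_n // 2
    step: int | None = None  # None -> window_n; set window_n // 2 for 50% overlap
    alpha: float = 0.6
    beta: float = 0.4
    se_policy: str = "default"
    circ_min: float = 0.8
    hue_lo: float = 23.0
    hue_hi: float = 35.0
    invert: bool = False
    min_pixels: int = 20
    match_iou: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.window_n < 4:
            raise ConfigError("window_n must be >= 4")
        if self.delta_gate <= 0:
            raise ConfigError("delta_gate must be > 0")
        if not (0 < self.circ_min <= 1.2):
            raise ConfigError("circ_min out of range")
        if self.se_policy not in SE_POLICIES:
            raise ConfigError(f"unknown se_policy {self.se_policy!r}")
        FusionWeights(self.alpha, self.beta)  # validates alpha > beta >= 0

    @property
    def effective_offset(self) -> int:
        return self.window_n // 2 if self.pass2_offset is None else self.pass2_offset

    @property
    def effective_step(self) -> int:
        return self.window_n if self.step is None else self.step

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "PipelineConfig":
        p = Path(text_or_path) if isinstance(text_or_path, (str, Path)) else None
        text = p.read_text() if p is not None and p.exists() else str(text_or_path)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class DetectionResult:
    """Everything one detection run produced."""

    fruit_mask: np.ndarray
    defect_map: DefectMap | None
    stem_result: StemFilterResult | None
    pass_results: list[windows.PassResult]
    overlay: np.ndarray | None
    pixel_metrics: MetricSet | None
    region_metrics: MetricSet | None
    log: dict
    empty: bool = False  # True when no fruit was found

    @property
    def records(self) -> list[windows.WindowRecord]:
        return [r for p in self.pass_results for r in p.records]

    @property
    def n_otsu_segmented(self) -> int:
        return sum(p.n_otsu_segmented for p in self.pass_results)


def center_crop(image: np.ndarray, n: int) -> np.ndarray:
    """Largest centered crop whose sides are divisible by the window size."""
    h, w = image.shape[:2]
    th, tw = (h // n) * n, (w // n) * n
    if th == 0 or tw == 0:
        raise ConfigError(f"image {h}x{w} smaller than window size {n}")
    y0, x0 = (h - th) // 2, (w - tw) // 2
    return image[y0 : y0 + th, x0 : x0 + tw]


def _overlay(image: np.ndarray, stem_filtered: StemFilterResult) -> np.ndarray:
    from skimage.segmentation import find_boundaries

    out = image.copy()
    if stem_filtered.defect_mask.any():
        out[find_boundaries(stem_filtered.defect_mask, mode="outer")] = (255, 0, 0)
    if stem_filtered.stem_mask.any():
        out[find_boundaries(stem_filtered.stem_mask, mode="outer")] = (0, 0, 255)
    return out


def detect(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    truth_defect_mask: np.ndarray | None = None,
    *,
    reset: bool = True,
) -> DetectionResult:
    """Run the full defect-detection pipeline on one RGB image."""
    cfg = config or PipelineConfig()
    if reset:
        reset_counters()
    log: dict = {"stages": {}}
    t_all = time.perf_counter()

    image = center_crop(image, cfg.window_n)
    if truth_defect_mask is not None:
        truth_defect_mask = center_crop(truth_defect_mask, cfg.window_n)

    t0 = time.perf_counter()
    hsv8 = rgb_to_hsv8(image)  # the single HSV conversion for the whole run
    s_full = hsv8[..., 1]
    fruit = background.compute_fruit_mask(image, s_channel=s_full)
    log["stages"]["background"] = time.perf_counter() - t0
    log["global_otsu_calls"] = counters["otsu_calls"] if reset else None

    if not fruit.mask.any():
        log["warning"] = "no fruit found"
        return DetectionResult(
            fruit_mask=fruit.mask, defect_map=None, stem_result=None, pass_results=[],
            overlay=None, pixel_metrics=None, region_metrics=None, log=log, empty=True,
        )

    masked = background.apply_mask(image, fruit, s_channel=s_full)

    t0 = time.perf_counter()
    off = cfg.effective_offset
    pass1 = windows.run_pass(
        masked.s_channel, fruit.mask, cfg.window_n, offset=(0, 0), step=cfg.effective_step,
        delta_gate=cfg.delta_gate, pass_id=1, min_pixels=cfg.min_pixels, invert=cfg.invert,
    )
    pass2 = windows.run_pass(
        masked.s_channel, fruit.mask, cfg.window_n, offset=(off, off), step=cfg.effective_step,
        delta_gate=cfg.delta_gate, pass_id=2, min_pixels=cfg.min_pixels, invert=cfg.invert,
    )
    log["stages"]["window_passes"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    # defects are holes in each pass's sound surface, within that pass's coverage
    defect1 = to_defect_map(pass1.sound_map, fruit.mask & pass1.coverage)
    defect2 = to_defect_map(pass2.sound_map, fruit.mask & pass2.coverage)
    fused = fuse_maps(defect1, defect2, FusionWeights(cfg.alpha, cfg.beta))
    defect_map = refine(fused, cfg.se_policy)
    log["stages"]["fuse_refine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stem_result = filter_stems(defect_map, hsv8, circ_min=cfg.circ_min, hue_range=(cfg.hue_lo, cfg.hue_hi))
    log["stages"]["stem_filter"] = time.perf_counter() - t0

    pixel_m = region_m = None
    if truth_defect_mask is not None:
        counts = pixel_confusion(stem_result.defect_mask, truth_defect_mask, domain=fruit.mask)
        pixel_m = compute_metrics(counts)
        pred_comps = [defect_map.labels == c.label for c in stem_result.defect_components]
        from skimage import measure as _measure

        truth_labels = _measure.label(truth_defect_mask, connectivity=2)
        region_m = compute_metrics(region_confusion(pred_comps, truth_labels, match_iou=cfg.match_iou))

    overlay = _overlay(image, stem_result)
    log["otsu_segmented_windows"] = int(counters["otsu_segmented_windows"]) if reset else None
    log["hsv_conversions"] = int(counters["hsv_conversions"]) if reset else None
    log["otsu_calls_total"] = int(counters["otsu_calls"]) if reset else None
    log["stages"]["total"] = time.perf_counter() - t_all
    return DetectionResult(
        fruit_mask=fruit.mask,
        defect_map=defect_map,
        stem_result=stem_result,
        pass_results=[pass1, pass2],
        overlay=overlay,
        pixel_metrics=pixel_m,
        region_metrics=region_m,
        log=log,
    )


@dataclass
class SuiteReport:
    """Aggregate evaluation of a detection run over a scene suite."""

    per_scene: list[dict]
    region_counts: ConfusionCounts
    region_metrics: MetricSet
    mean_pixel_iou: float | None  # over scenes with non-empty truth, percent
    mean_pixel_dice: float | None
    stem_scenes: int
    stems_excluded: int
    total_otsu_segmented: int

    @property
    def stem_exclusion_rate(self) -> float | None:
        return None if self.stem_scenes == 0 else 100.0 * self.stems_excluded / self.stem_scenes


def run_suite(scenes: list[Scene], config: PipelineConfig | None = None) -> SuiteReport:
    """Detect on every scene and aggregate region/pixel metrics vs ground truth.

    A stem-bearing scene counts as "stem excluded" when no final defect
    component overlaps the true stem mask at the matching IoU — i.e. the
    stem was either rejected by the filter or never flagged at all.
    """
    from skimage import measure as _measure

    cfg = config or PipelineConfig()
    per_scene = []
    tp = fp = fn = 0
    ious: list[float] = []
    dices: list[float] = []
    stem_scenes = stems_excluded = 0
    total_otsu_segmented = 0
    for i, scene in enumerate(scenes):
        res = detect(scene.image, cfg, truth_defect_mask=scene.defect_mask)
        total_otsu_segmented += res.n_otsu_segmented
        pred_comps = []
        pred_mask = np.zeros_like(scene.defect_mask)
        if not res.empty and res.stem_result is not None:
            pred_comps = [res.defect_map.labels == c.label for c in res.stem_result.defect_components]
            pred_mask = res.stem_result.defect_mask
        truth_labels = _measure.label(scene.defect_mask, connectivity=2)
        rc = region_confusion(pred_comps, truth_labels, match_iou=cfg.match_iou)
        tp, fp, fn = tp + rc.tp, fp + rc.fp, fn + rc.fn
        entry = {
            "index": i,
            "label": scene.label,
            "region": rc,
            "n_otsu_segmented": res.n_otsu_segmented,
        }
        if scene.defect_mask.any():
            pc = pixel_confusion(pred_mask, scene.defect_mask, domain=scene.fruit_mask)
            m = compute_metrics(pc)
            ious.append(m.iou)
            dices.append(m.dice)
            entry["pixel_iou"] = m.iou
        if scene.stem_mask.any():
            stem_scenes += 1
            leaked = any(mask_iou(pm, scene.stem_mask) >= cfg.match_iou for pm in pred_comps)
            excluded = not leaked
            stems_excluded += int(excluded)
            entry["stem_excluded"] = excluded
        per_scene.append(entry)
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0, level="region")
    return SuiteReport(
        per_scene=per_scene,
        region_counts=counts,
        region_metrics=compute_metrics(counts),
        mean_pixel_iou=float(np.mean(ious)) if ious else None,
        mean_pixel_dice=float(np.mean(dices)) if dices else None,
        stem_scenes=stem_scenes,
        stems_excluded=stems_excluded,
        total_otsu_segmented=total_otsu_segmented,
    )
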