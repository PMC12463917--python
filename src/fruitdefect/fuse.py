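"""Pass fusion, defect-map extraction and morphological refinement.

Each sliding-window pass produces a sound-surface map over the pixels it
covers; defects are the fruit-masked complement of sound within that
coverage.  The two per-pass defect maps are combined by a weighted sum
binarized at > 0 — because the maps are binary, any admissible weights
(alpha > beta >= 0, beta > 0) reduce to their union, which is made explicit
here rather than pretending numeric precision.  The fused map is then
cleaned morphologically: closing fills interior voids, opening removes
specks and burrs, and components below a minimum area are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import ExtentMismatchError, WeightError


@dataclass(frozen=True)
class FusionWeights:
    """Weights for the two passes; the first pass dominates (alpha > beta >= 0)."""

    alpha: float = 0.6
    beta: float = 0.4

    def __post_init__(self):
        if not (self.alpha > self.beta >= 0):
            raise WeightError(f"require alpha > beta >= 0, got alpha={self.alpha}, beta={self.beta}")


@dataclass(frozen=True)
class SEPolicy:
    """Structuring-element policy: full widths of closing/opening disks.

    Smaller openings preserve small defects at the price of more speck noise;
    larger ones clean aggressively but erode fine detail.
    """

    close_size: int = 7
    open_size: int = 3
    min_area: int = 30


SE_POLICIES = {
    "default": SEPolicy(7, 3, 30),
    "small": SEPolicy(5, 3, 30),
    "medium": SEPolicy(9, 5, 30),
    "large": SEPolicy(11, 7, 30),
}


@dataclass(frozen=True)
class ComponentInfo:
    label: int
    area: int
    perimeter: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]


@dataclass
class DefectMap:
    """Refined binary defect mask with its connected components."""

    mask: np.ndarray  # bool, True = defect
    labels: np.ndarray  # int component labels, 0 = background
    components: list[ComponentInfo]
    policy: SEPolicy


def fuse(map1: np.ndarray, map2: np.ndarray, weights: FusionWeights = FusionWeights()) -> np.ndarray:
    """Weighted combination of two binary maps, binarized at > 0.

    With beta = 0 the result equals ``map1`` alone; for any beta > 0 it is
    the union of the two maps.
    """
    if map1.shape != map2.shape:
        raise ExtentMismatchError("fusion inputs differ in extent")
    combined = weights.alpha * map1.astype(np.float64) + weights.beta * map2.astype(np.float64)
    return combined > 0


def to_defect_map(sound_map: np.ndarray, domain_mask: np.ndarray) -> np.ndarray:
    """Defect = domain minus sound (defects are holes in the sound surface)."""
    if sound_map.shape != domain_mask.shape:
        raise ExtentMismatchError("sound map and domain mask differ in extent")
    return domain_mask.astype(bool) & ~sound_map.astype(bool)


def _disk(size: int):
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 1")
    return morphology.disk(size // 2)


def label_components(mask: np.ndarray) -> tuple[np.ndarray, list[ComponentInfo]]:
    labels = measure.label(mask, connectivity=2)
    comps = [
        ComponentInfo(
            label=int(p.label),
            area=int(p.area),
            perimeter=float(p.perimeter_crofton),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            bbox=tuple(int(v) for v in p.bbox),
        )
        for p in measure.regionprops(labels)
    ]
    return labels, comps


def refine(raw_mask: np.ndarray, policy: SEPolicy | str = "default") -> DefectMap:
    """Morphological cleanup of a raw defect mask.

    Closing (void filling) then opening (speck/burr removal) then a
    minimum-area component filter; idempotent for a fixed policy.
    """
    if isinstance(policy, str):
        policy = SE_POLICIES[policy]
    mask = np.asarray(raw_mask, dtype=bool)
    mask = morphology.closing(mask, _disk(policy.close_size))
    mask = morphology.opening(mask, _disk(policy.open_size))
    labels, comps = label_components(mask)
    small = [c for c in comps if c.area < policy.min_area]
    if small:
        for c in small:
            mask[labels == c.label] = False
        labels, comps = label_components(mask)
    return DefectMap(mask=mask, labels=labels, components=comps, policy=policy)
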