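"""Stem identification among detected defect components.

A fruit stem (calyx button) survives window segmentation as a low-saturation
"defect" component, but unlike true defects it is compact and yellow-green.
A component is declared a stem when BOTH hold:

* circularity 4*pi*A / P**2 exceeds ``circ_min`` (default 0.8) — 1 for a
  disk, lower for elongated or ragged shapes;
* the circular mean of its hue lies inside ``hue_range`` (default 23-35 on
  the half-degree [0, 180) wheel, i.e. 46-70 true degrees).

Stems are removed from the defect set and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .fuse import ComponentInfo, DefectMap, label_components

MIN_COMPONENT_AREA = 5


@dataclass(frozen=True)
class ComponentShape:
    area: int
    perimeter: float
    circularity: float
    mean_hue: float  # half-degrees in [0, 180)


@dataclass(frozen=True)
class StemDecision:
    component: int  # label id
    is_stem: bool
    circularity: float
    mean_hue: float
    circ_min: float
    hue_range: tuple[float, float]


@dataclass
class StemFilterResult:
    defect_components: list[ComponentInfo]
    stem_components: list[ComponentInfo]
    decisions: list[StemDecision]
    defect_mask: np.ndarray  # final mask with stems removed
    stem_mask: np.ndarray


def circularity(component_mask: np.ndarray) -> float:
    """Isoperimetric ratio 4*pi*A / P**2 of a single component.

    The perimeter is the 4-direction Cauchy-Crofton estimate, which tracks
    the true contour length of smooth rasterized shapes closely (a naive
    boundary walk overstates it and would push a 2:1 ellipse below the stem
    threshold); rasterization can still push the ratio slightly above 1.
    Components below 5 px are rejected as degenerate.
    """
    mask = np.asarray(component_mask, dtype=bool)
    area = int(mask.sum())
    if area < MIN_COMPONENT_AREA:
        raise ValueError(f"component area {area} < {MIN_COMPONENT_AREA} px")
    perim = float(measure.perimeter_crofton(mask, directions=4))
    if perim <= 0:
        raise ValueError("degenerate component (zero perimeter)")
    return 4.0 * np.pi * area / perim**2


def mean_hue(hsv8: np.ndarray, component_mask: np.ndarray) -> float:
    """Circular mean of the hue channel over a component, on the [0, 180) wheel."""
    mask = np.asarray(component_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty component")
    h = hsv8[..., 0][mask].astype(np.float64)
    theta = h * (2.0 * np.pi / 180.0)
    ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    hue = (ang * 180.0 / (2.0 * np.pi)) % 180.0
    return 0.0 if hue >= 180.0 - 1e-9 else float(hue)


def _hue_in_range(h: float, lo: float, hi: float) -> bool:
    if lo <= hi:
        return lo <= h <= hi
    return h >= lo or h <= hi  # wrap-around band


def filter_stems(
    defect_map: DefectMap,
    hsv8: np.ndarray,
    circ_min: float = 0.8,
    hue_range: tuple[float, float] = (23.0, 35.0),
) -> StemFilterResult:
    """Partition defect components into true defects and stems.

    Both the circularity and the hue criterion must hold for a stem; tiny
    components (below 5 px, for which circularity is undefined) are kept as
    defects.
    """
    decisions: list[StemDecision] = []
    stems: list[ComponentInfo] = []
    defects: list[ComponentInfo] = []
    stem_mask = np.zeros_like(defect_map.mask, dtype=bool)
    for comp in defect_map.components:
        cmask = defect_map.labels == comp.label
        if comp.area >= MIN_COMPONENT_AREA:
            circ = circularity(cmask)
            hue = mean_hue(hsv8, cmask)
            is_stem = circ > circ_min and _hue_in_range(hue, *hue_range)
        else:
            circ, hue, is_stem = float("nan"), float("nan"), False
        decisions.append(StemDecision(
            component=comp.label, is_stem=is_stem, circularity=circ, mean_hue=hue,
            circ_min=circ_min, hue_range=tuple(hue_range),
        ))
        if is_stem:
            stems.append(comp)
            stem_mask |= cmask
        else:
            defects.append(comp)
    defect_mask = defect_map.mask & ~stem_mask
    return StemFilterResult(
        defect_components=defects,
        stem_components=stems,
        decisions=decisions,
        defect_mask=defect_mask,
        stem_mask=stem_mask,
    )
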