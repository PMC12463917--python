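"""Seeded synthetic fruit scenes with exact ground truth.

The generator emulates the statistical structure the detector assumes for a
quasi-spherical citrus fruit photographed against a dark background:

* a bright-center / dim-edge fruit disk — saturation and value fall off
  quadratically with radial distance, so edge windows see a smooth gradient
  rather than uniform gray;
* low-saturation defect patches, either ``point_like`` (a single compact
  ellipse, like a thrips scar or canker spot) or ``blocky`` (a union of
  jittered ellipses with an irregular diffuse boundary, like sunburn);
* an optional elliptical stem whose hue lies in the yellow-green 23-35
  half-degree band, saturation well below the peel's.

Every scene carries the exact rasterized fruit / defect / stem masks, so the
whole pipeline is testable without any image dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .color import hsv8_to_rgb
from .errors import ParameterError

SUITE_PROPORTIONS = {"sound": 0.2, "point": 0.4, "blocky": 0.2, "stem": 0.2}


@dataclass(frozen=True)
class DefectSpec:
    """A low-saturation defect patch, wholly inside the fruit disk.

    ``center`` is (x, y) in pixels; ``radii`` are the ellipse semi-axes; the
    patch drops the underlying saturation/value by ``saturation_delta`` /
    ``value_delta`` 8-bit levels.  ``blocky`` patches are rendered as a union
    of 3-6 jittered sub-ellipses contained in the spec ellipse's bounding
    circle, so the spec radii bound the patch extent for both kinds.
    """

    kind: str  # {"point_like", "blocky"}
    center: tuple[float, float]
    radii: tuple[float, float]
    angle: float = 0.0  # degrees
    saturation_delta: int = 60
    value_delta: int = 30

    def __post_init__(self):
        if self.kind not in ("point_like", "blocky"):
            raise ParameterError(f"unknown defect kind {self.kind!r}")
        if self.saturation_delta < 0 or self.value_delta < 0:
            raise ParameterError("defect deltas must be >= 0")
        if min(self.radii) <= 0:
            raise ParameterError("defect radii must be positive")
        if np.pi * self.radii[0] * self.radii[1] < 5:
            raise ParameterError("defect patch area must be >= 5 px")


@dataclass(frozen=True)
class StemSpec:
    """An elliptical stem patch: yellow-green hue, modest axis ratio.

    The axis ratio is capped at 2.2 so the rasterized component keeps a
    circularity above 0.8 (the stem identification threshold).
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    angle: float = 0.0
    hue: int = 29  # half-degrees, must lie in [23, 35]
    saturation: int = 70
    value: int = 120

    def __post_init__(self):
        a, b = max(self.radii), min(self.radii)
        if b <= 0:
            raise ParameterError("stem radii must be positive")
        if a / b > 2.2:
            raise ParameterError("stem axis ratio must be <= 2.2 (circularity > 0.8)")
        if not (23 <= self.hue <= 35):
            raise ParameterError("stem hue must lie in [23, 35] half-degrees")


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of one synthetic fruit scene."""

    image_size: tuple[int, int] = (400, 400)  # (height, width)
    fruit_center: tuple[float, float] = (200.0, 200.0)  # (x, y)
    fruit_radius: float = 185.0
    fruit_hue: int = 12  # half-degrees (orange peel)
    fruit_saturation_center: int = 210
    saturation_edge_factor: float = 0.82  # rim saturation as a fraction of center
    value_center: int = 200
    value_edge_factor: float = 0.75
    background_hsv: tuple[int, int, int] = (105, 25, 40)
    defect_specs: tuple[DefectSpec, ...] = ()
    stem_spec: StemSpec | None = None
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        cx, cy = self.fruit_center
        r = self.fruit_radius
        if r <= 0:
            raise ParameterError("fruit radius must be positive")
        if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
            raise ParameterError("fruit disk must lie fully inside the image frame")
        for name in ("saturation_edge_factor", "value_edge_factor"):
            f = getattr(self, name)
            if not (0 < f <= 1):
                raise ParameterError(f"{name} must lie in (0, 1]")
        for spec in self.defect_specs:
            self._check_inside(spec.center, max(spec.radii), "defect")
        if self.stem_spec is not None:
            self._check_inside(self.stem_spec.center, max(self.stem_spec.radii), "stem")

    def _check_inside(self, center, reach, what):
        cx, cy = self.fruit_center
        d = np.hypot(center[0] - cx, center[1] - cy)
        if d + reach > self.fruit_radius:
            raise ParameterError(f"{what} patch extends outside the fruit disk")


@dataclass
class Scene:
    """A rendered image plus its exact ground-truth masks."""

    image: np.ndarray  # (H, W, 3) uint8 RGB
    fruit_mask: np.ndarray  # bool
    defect_mask: np.ndarray  # bool
    stem_mask: np.ndarray  # bool
    params: SceneParams
    label: str = ""


def _ellipse_mask(shape, center, radii, angle_deg):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    th = np.deg2rad(angle_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _rasterize_defect(spec: DefectSpec, shape, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "point_like":
        return _ellipse_mask(shape, spec.center, spec.radii, spec.angle)
    # blocky: union of jittered sub-ellipses inside the spec's bounding circle
    n_sub = int(rng.integers(3, 7))
    mask = np.zeros(shape, dtype=bool)
    a, b = spec.radii
    for _ in range(n_sub):
        off = rng.uniform(-0.45, 0.45, size=2) * (a, b)
        sub_radii = (a * rng.uniform(0.35, 0.55), b * rng.uniform(0.35, 0.55))
        sub_center = (spec.center[0] + off[0], spec.center[1] + off[1])
        mask |= _ellipse_mask(shape, sub_center, sub_radii, rng.uniform(0, 180))
    return mask


def render_scene(params: SceneParams, label: str = "") -> Scene:
    """Render one scene deterministically from ``params`` (seed included)."""
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = params.fruit_center
    rho = np.hypot(xx - cx, yy - cy)
    fruit = rho <= params.fruit_radius

    bh, bs, bv = params.background_hsv
    H = np.full((h, w), bh, dtype=np.float64)
    S = np.full((h, w), float(bs), dtype=np.float64)
    V = np.full((h, w), float(bv), dtype=np.float64)

    rel = (rho[fruit] / params.fruit_radius) ** 2
    H[fruit] = params.fruit_hue
    S[fruit] = params.fruit_saturation_center * (1 - (1 - params.saturation_edge_factor) * rel)
    V[fruit] = params.value_center * (1 - (1 - params.value_edge_factor) * rel)

    defect_mask = np.zeros((h, w), dtype=bool)
    for spec in params.defect_specs:
        m = _rasterize_defect(spec, (h, w), rng) & fruit
        if m.sum() < 5:
            raise ParameterError("rasterized defect patch smaller than 5 px")
        S[m] -= spec.saturation_delta
        V[m] -= spec.value_delta
        defect_mask |= m

    stem_mask = np.zeros((h, w), dtype=bool)
    if params.stem_spec is not None:
        sp = params.stem_spec
        stem_mask = _ellipse_mask((h, w), sp.center, sp.radii, sp.angle) & fruit
        H[stem_mask] = sp.hue
        S[stem_mask] = sp.saturation
        V[stem_mask] = sp.value
        defect_mask &= ~stem_mask

    # gray level 0 is reserved for removed background
    S[fruit] = np.clip(S[fruit], 1, 255)
    V = np.clip(V, 0, 255)

    hsv8 = np.stack(
        [
            np.round(H).astype(np.uint8),
            np.round(S).astype(np.uint8),
            np.round(V).astype(np.uint8),
        ],
        axis=-1,
    )
    rgb = hsv8_to_rgb(hsv8).astype(np.float64)
    if params.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sigma, rgb.shape)
    image = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    return Scene(
        image=image,
        fruit_mask=fruit,
        defect_mask=defect_mask,
        stem_mask=stem_mask,
        params=params,
        label=label,
    )


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    keys = list(proportions)
    exact = np.array([proportions[k] * n for k in keys])
    base = np.floor(exact).astype(int)
    rem = exact - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _random_point_defect(rng, params_center, params_radius, kind="point_like"):
    if kind == "point_like":
        a = rng.uniform(13, 22)
        b = a * rng.uniform(0.8, 1.0)
        max_dist = 0.8 * params_radius
    else:
        a = rng.uniform(28, 45)
        b = a * rng.uniform(0.7, 1.0)
        max_dist = 0.65 * params_radius
    reach = max(a, b)
    dist = np.sqrt(rng.uniform()) * min(max_dist, params_radius - reach - 2)
    ang = rng.uniform(0, 2 * np.pi)
    center = (params_center[0] + dist * np.cos(ang), params_center[1] + dist * np.sin(ang))
    delta = 60 if kind == "point_like" else 50
    return DefectSpec(
        kind=kind,
        center=center,
        radii=(a, b),
        angle=rng.uniform(0, 180),
        saturation_delta=delta,
        value_delta=30,
    )


def _random_stem(rng, params_center, params_radius):
    a = rng.uniform(26, 36)
    b = a / rng.uniform(1.3, 1.8)
    dist = rng.uniform(0.30, 0.55) * params_radius
    dist = min(dist, params_radius - a - 2)
    ang = rng.uniform(0, 2 * np.pi)
    center = (params_center[0] + dist * np.cos(ang), params_center[1] + dist * np.sin(ang))
    return StemSpec(
        center=center,
        radii=(a, b),
        angle=rng.uniform(0, 180),
        hue=int(rng.integers(26, 34)),
    )


def make_scene_params(label: str, seed: int, image_size=(400, 400)) -> SceneParams:
    """Randomized but seed-deterministic parameters for one labeled scene."""
    rng = np.random.default_rng(seed)
    h, w = image_size
    center = (
        w / 2 + rng.uniform(-8, 8),
        h / 2 + rng.uniform(-8, 8),
    )
    radius = rng.uniform(0.875, 0.94) * (min(h, w) / 2 - 12)
    defects: list[DefectSpec] = []
    stem = None
    if label == "point":
        for _ in range(int(rng.integers(1, 3))):
            defects.append(_random_point_defect(rng, center, radius))
    elif label == "blocky":
        defects.append(_random_point_defect(rng, center, radius, kind="blocky"))
    elif label == "stem":
        stem = _random_stem(rng, center, radius)
        # keep the companion defect clear of the stem so truth components stay separate
        for _ in range(60):
            d = _random_point_defect(rng, center, radius)
            gap = np.hypot(d.center[0] - stem.center[0], d.center[1] - stem.center[1])
            if gap > max(stem.radii) + max(d.radii) + 12:
                defects.append(d)
                break
    elif label != "sound":
        raise ParameterError(f"unknown scene label {label!r}")
    return SceneParams(
        image_size=image_size,
        fruit_center=center,
        fruit_radius=radius,
        defect_specs=tuple(defects),
        stem_spec=stem,
        seed=int(rng.integers(2**31)),
    )


def scene_suite(
    n_scenes: int,
    seed: int = 0,
    proportions: dict[str, float] | None = None,
    image_size=(400, 400),
) -> list[Scene]:
    """A deterministic mixed suite of labeled scenes.

    Proportions default to 20% sound / 40% point-defect / 20% blocky-defect /
    20% stem-bearing; exact per-label counts come from the largest-remainder
    rounding of ``proportion * n_scenes``.
    """
    if n_scenes < 1:
        raise ParameterError("n_scenes must be >= 1")
    proportions = dict(proportions or SUITE_PROPORTIONS)
    counts = _largest_remainder_counts(n_scenes, proportions)
    labels = [lab for lab, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    scenes = []
    for lab in labels:
        sub_seed = int(rng.integers(2**31))
        scenes.append(render_scene(make_scene_params(lab, sub_seed, image_size), label=lab))
    return scenes


# ---------------------------------------------------------------------------
# on-disk round trip: PNG image + 0/255 mask PNGs + JSON parameter sidecar


def write_scene(scene: Scene, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "image.png", scene.image)
    for name in ("fruit_mask", "defect_mask", "stem_mask"):
        iio.imwrite(out / f"{name}.png", getattr(scene, name).astype(np.uint8) * 255)
    sidecar = dataclasses.asdict(scene.params)
    sidecar["label"] = scene.label
    (out / "params.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_scene(scene_dir: str | Path) -> Scene:
    d = Path(scene_dir)
    raw = json.loads((d / "params.json").read_text())
    label = raw.pop("label", "")
    raw["defect_specs"] = tuple(DefectSpec(**{**ds, "center": tuple(ds["center"]), "radii": tuple(ds["radii"])}) for ds in raw["defect_specs"])
    if raw.get("stem_spec") is not None:
        ss = raw["stem_spec"]
        raw["stem_spec"] = StemSpec(**{**ss, "center": tuple(ss["center"]), "radii": tuple(ss["radii"])})
    for key in ("image_size", "fruit_center", "background_hsv"):
        raw[key] = tuple(raw[key])
    params = SceneParams(**raw)
    return Scene(
        image=iio.imread(d / "image.png"),
        fruit_mask=iio.imread(d / "fruit_mask.png") > 0,
        defect_mask=iio.imread(d / "defect_mask.png") > 0,
        stem_mask=iio.imread(d / "stem_mask.png") > 0,
        params=params,
        label=label,
    )
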