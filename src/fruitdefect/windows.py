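"""Sliding-window tiling, window classification and per-class segmentation.

The masked saturation image is tiled into n-by-n windows and scanned twice:
a primary pass aligned with the image origin and a secondary pass offset by
half a window in each direction.  Each window is classified by its count of
reserved-zero (background) pixels:

* background — all pixels zero;
* edge — more than 1/20 of the pixels zero (the window straddles the rim);
* foreground — everything else.

Background windows are skipped outright.  Edge and foreground windows build
a zero-excluded histogram; only when the inter-class average grayscale
difference delta_d reaches the gate is the window actually thresholded
(pixels above the Otsu threshold are sound, the low-saturation class is
defect).  Windows failing the gate adopt the fruit mask as their result —
no local evidence of a defect — which is what keeps the number of genuine
threshold segmentations far below the window count.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import otsu
from ._counters import counters
from .errors import ConfigError, ExtentMismatchError

DEFAULT_DELTA_GATE = 30.0
DEFAULT_MIN_PIXELS = 20


class WindowClass(str, Enum):
    BACKGROUND = "background"
    EDGE = "edge"
    FOREGROUND = "foreground"


class WindowAction(str, Enum):
    SKIP_ZERO = "skip_zero"
    ADOPT_MASK = "adopt_mask"
    OTSU_SEGMENTED = "otsu_segmented"


@dataclass(frozen=True)
class Window:
    """Half-open pixel rectangle [y0, y1) x [x0, x1) at grid position (row, col)."""

    row: int
    col: int
    y0: int
    x0: int
    y1: int
    x1: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class WindowGrid:
    extent: tuple[int, int]  # (height, width)
    n: int
    offset: tuple[int, int]  # (y0, x0)
    step: int
    windows: tuple[Window, ...]

    def __len__(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class WindowRecord:
    """Per-window provenance: what the segmenter decided and why."""

    pass_id: int
    grid_pos: tuple[int, int]
    window_class: WindowClass
    T: int | None
    delta_d: float | None
    action: WindowAction


@dataclass
class PassResult:
    """One sliding-window pass: the sound-surface map plus audit records.

    ``coverage`` marks the pixels visited by this pass's windows; an offset
    pass leaves an uncovered half-window frame whose pixels carry no opinion
    and are recovered from the other pass at fusion.
    """

    pass_id: int
    sound_map: np.ndarray  # bool, True = sound fruit surface
    coverage: np.ndarray  # bool, True = visited by some window
    records: list[WindowRecord]

    @property
    def n_otsu_segmented(self) -> int:
        return sum(1 for r in self.records if r.action is WindowAction.OTSU_SEGMENTED)


def tile(extent: tuple[int, int], n: int, offset: tuple[int, int] = (0, 0), step: int | None = None) -> WindowGrid:
    """Enumerate all fully contained n-by-n windows, row-major.

    With a zero offset and step == n the windows must partition the image
    exactly; a non-divisible extent is a configuration error (canonical
    inputs are center-cropped to 400x400 first).
    """
    h, w = extent
    step = n if step is None else step
    if n < 4:
        raise ConfigError("window side must be >= 4")
    if step < 1:
        raise ConfigError("step must be >= 1")
    oy, ox = offset
    if not (0 <= oy < n and 0 <= ox < n):
        raise ConfigError("offset components must lie in [0, n)")
    if offset == (0, 0) and step == n and (h % n or w % n):
        raise ConfigError(f"extent {extent} not divisible by window size {n}")
    wins = []
    for r, y0 in enumerate(range(oy, h - n + 1, step)):
        for c, x0 in enumerate(range(ox, w - n + 1, step)):
            wins.append(Window(row=r, col=c, y0=y0, x0=x0, y1=y0 + n, x1=x0 + n))
    return WindowGrid(extent=(h, w), n=n, offset=(oy, ox), step=step, windows=tuple(wins))


def classify_window(s_window: np.ndarray) -> WindowClass:
    """Three-way classification by the count of reserved-zero pixels."""
    total = s_window.size
    if total == 0:
        raise ValueError("empty window")
    zeros = total - int(np.count_nonzero(s_window))
    if zeros == total:
        return WindowClass.BACKGROUND
    if zeros > total / 20:
        return WindowClass.EDGE
    return WindowClass.FOREGROUND


def segment_window(
    s_window: np.ndarray,
    mask_window: np.ndarray,
    window_class: WindowClass,
    delta_gate: float = DEFAULT_DELTA_GATE,
    *,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    invert: bool = False,
    pass_id: int = 1,
    grid_pos: tuple[int, int] = (0, 0),
) -> tuple[np.ndarray, WindowRecord]:
    """Apply the per-class segmentation policy to one window.

    Returns the window's sound-surface map and its :class:`WindowRecord`.
    Background windows (and near-empty edge slivers below ``min_pixels``
    nonzero pixels) are skipped without touching Otsu.  Otherwise the window
    is thresholded only when the zero-excluded histogram's delta_d reaches
    ``delta_gate``; failing the gate, the fruit mask is adopted wholesale.
    """
    if delta_gate <= 0:
        raise ConfigError("delta_gate must be > 0")
    if s_window.shape != mask_window.shape:
        raise ExtentMismatchError("window and mask extents differ")

    def record(action, T=None, dd=None):
        return WindowRecord(pass_id=pass_id, grid_pos=tuple(grid_pos), window_class=window_class,
                            T=T, delta_d=dd, action=action)

    if window_class is WindowClass.BACKGROUND:
        return np.zeros_like(mask_window, dtype=bool), record(WindowAction.SKIP_ZERO)

    hist = otsu.build_histogram(s_window, exclude_zero=True)
    if hist.total < min_pixels:
        return np.zeros_like(mask_window, dtype=bool), record(WindowAction.SKIP_ZERO)

    t = otsu.otsu_threshold(hist)
    stats = otsu.class_stats(hist, t)
    if stats.degenerate:
        # uniform window: no second class, treated as defect-free
        return mask_window.astype(bool), record(WindowAction.ADOPT_MASK, T=t, dd=None)
    if stats.delta_d >= delta_gate:
        counters["otsu_segmented_windows"] += 1
        if invert:
            sound = (s_window <= t) & (s_window > 0)
        else:
            sound = s_window > t
        sound &= mask_window.astype(bool)
        return sound, record(WindowAction.OTSU_SEGMENTED, T=t, dd=stats.delta_d)
    return mask_window.astype(bool), record(WindowAction.ADOPT_MASK, T=t, dd=stats.delta_d)


def run_pass(
    s_image: np.ndarray,
    fruit_mask: np.ndarray,
    n: int,
    offset: tuple[int, int] = (0, 0),
    step: int | None = None,
    delta_gate: float = DEFAULT_DELTA_GATE,
    pass_id: int = 1,
    *,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    invert: bool = False,
) -> PassResult:
    """Tile + classify + segment every window of one sliding-window pass."""
    if s_image.shape != fruit_mask.shape:
        raise ExtentMismatchError("saturation image and fruit mask extents differ")
    grid = tile(s_image.shape, n, offset=offset, step=step)
    defect_evidence = np.zeros(s_image.shape, dtype=bool)
    coverage = np.zeros(s_image.shape, dtype=bool)
    records: list[WindowRecord] = []
    for win in grid.windows:
        sl = win.slices
        w_sound, rec = segment_window(
            s_image[sl],
            fruit_mask[sl],
            classify_window(s_image[sl]),
            delta_gate,
            min_pixels=min_pixels,
            invert=invert,
            pass_id=pass_id,
            grid_pos=(win.row, win.col),
        )
        # overlapping windows (step < n) accumulate defect evidence by union:
        # a defect flagged by any window covering a pixel survives
        defect_evidence[sl] |= fruit_mask[sl].astype(bool) & ~w_sound
        coverage[sl] = True
        records.append(rec)
    sound = coverage & fruit_mask.astype(bool) & ~defect_evidence
    return PassResult(pass_id=pass_id, sound_map=sound, coverage=coverage, records=records)


def records_to_csv(records: list[WindowRecord]) -> str:
    """Window records as CSV (pass, row, col, class, T, delta_d, action)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["pass", "row", "col", "class", "T", "delta_d", "action"])
    for r in records:
        writer.writerow([
            r.pass_id, r.grid_pos[0], r.grid_pos[1], r.window_class.value,
            "" if r.T is None else r.T,
            "" if r.delta_d is None else f"{r.delta_d:.2f}",
            r.action.value,
        ])
    return buf.getvalue()
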