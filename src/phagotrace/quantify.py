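"""ROI-based intensity measurements on time-lapse stacks.

Implements the four per-phagosome readouts:

* luminal relative intensity — background-subtracted sum over a small
  box at the phagosome center, normalised to the sealing frame (T0);
* surface relative intensity — unit intensity of the "donut" between
  two closed polygons outlining the phagosome surface, background-
  corrected per unit area and normalised to T0;
* acidification index — the GFP/mCherry center-box ratio at Tn divided
  by the same ratio at T0 (no background subtraction by definition);
* disc diameter — full-width-at-half-maximum chords through a bright
  disc (engulfed nucleus or phagosome marker), and its T0-normalised
  ratio.

Coordinates are 0-based (row, col) = (y, x) with pixel centers at
integer positions; boxes are half-open windows.  Polygon areas are
rasterised pixel counts (pixel-center-in-polygon), matching how the
intensity is summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .render import ImageStack
from .scene import GroundTruthScene

__all__ = [
    "RoiAnnotation",
    "TimeCourse",
    "annotation_from_scene",
    "box_intensity",
    "luminal_relative_intensity",
    "surface_relative_intensity",
    "acidification_index",
    "measure_disc_diameter",
    "nuclear_diameter_ratio",
    "disc_diameter_timecourse",
    "rasterize_polygon",
]

TIMECOURSE_KINDS = (
    "luminal_rint", "surface_rint", "acidification_index",
    "diameter_um", "diameter_ratio",
)


@dataclass
class TimeCourse:
    """A per-frame scalar measurement series.

    ``anchor_value`` is the raw T0 quantity used for normalisation (or
    the T0 diameter for ratio series).  Normalised kinds start at 1.0
    by construction.
    """

    times: np.ndarray      # min from sealing
    values: np.ndarray
    anchor_value: float
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in TIMECOURSE_KINDS:
            raise ValueError(f"unknown TimeCourse kind {self.kind!r}")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RoiAnnotation:
    """Per-phagosome manual-style annotations.

    ``center_track`` is an (N, 2) array of per-frame (y, x) centers;
    ``inner_polygons``/``outer_polygons`` are per-frame (k, 2) closed
    vertex lists in (y, x) pixel coordinates; ``background_box`` is a
    fixed (y, x, height, width) box outside the embryo.
    """

    center_track: np.ndarray
    inner_polygons: list[np.ndarray]
    outer_polygons: list[np.ndarray]
    background_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.center_track = np.asarray(self.center_track, dtype=float)
        if self.center_track.ndim != 2 or self.center_track.shape[1] != 2:
            raise ValueError("center_track must be (N, 2)")
        if not (len(self.inner_polygons) == len(self.outer_polygons)
                == len(self.center_track)):
            raise ValueError("per-frame annotation lengths differ")


def annotation_from_scene(
    scene: GroundTruthScene,
    rim_halfwidth: float = 3.0,
    n_vertices: int = 32,
    background_box: tuple[int, int, int, int] | None = None,
) -> RoiAnnotation:
    """Build annotations from ground truth (simulation workflows).

    The surface polygons are regular ``n_vertices``-gons at radius
    ``r -/+ rim_halfwidth``; the background box defaults to an 8x8
    window in the image corner farthest from the phagosome.
    """
    centers = np.array([f.phagosome_center for f in scene.frames])
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    inner, outer = [], []
    for f in scene.frames:
        cy, cx = f.phagosome_center
        r_in = max(f.phagosome_radius - rim_halfwidth, 0.5)
        r_out = f.phagosome_radius + rim_halfwidth
        inner.append(np.column_stack([cy + r_in * np.sin(theta),
                                      cx + r_in * np.cos(theta)]))
        outer.append(np.column_stack([cy + r_out * np.sin(theta),
                                      cx + r_out * np.cos(theta)]))
    if background_box is None:
        h, w = scene.image_shape
        cy, cx = centers.mean(axis=0)
        corner_y = 0 if cy > h / 2 else h - 8
        corner_x = 0 if cx > w / 2 else w - 8
        background_box = (corner_y, corner_x, 8, 8)
    return RoiAnnotation(centers, inner, outer, background_box)


# --- box sums -------------------------------------------------------


def _box_window(center: tuple[float, float], box_side: int) -> tuple[int, int]:
    """Upper-left corner of the half-open window.

    Odd sides center on the pixel; even sides put the center pixel at
    the upper-left of the central 2x2 block.
    """
    cy = int(math.floor(center[0] + 0.5))
    cx = int(math.floor(center[1] + 0.5))
    off = (box_side - 1) // 2
    return cy - off, cx - off


def box_intensity(
    stack: ImageStack,
    frame: int,
    channel: int,
    center: tuple[float, float],
    box_side: int = 4,
) -> float:
    """Sum of intensities over a ``box_side`` square window at ``center``."""
    if box_side < 1:
        raise ValueError("box_side must be >= 1")
    y0, x0 = _box_window(center, box_side)
    h, w = stack.data.shape[2:]
    if y0 < 0 or x0 < 0 or y0 + box_side > h or x0 + box_side > w:
        raise ValueError(
            f"box [{y0}:{y0 + box_side}, {x0}:{x0 + box_side}] out of bounds "
            f"for image {h}x{w}")
    return float(stack.data[frame, channel, y0:y0 + box_side, x0:x0 + box_side].sum())


def _background_center(box: tuple[int, int, int, int]) -> tuple[float, float]:
    y, x, h, w = box
    return (y + (h - 1) / 2.0, x + (w - 1) / 2.0)


# --- polygon rasterization -----------------------------------------


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be a (k>=3, 2) vertex array")
    y0 = max(int(math.floor(poly[:, 0].min())), 0)
    y1 = min(int(math.ceil(poly[:, 0].max())) + 1, shape[0])
    x0 = max(int(math.floor(poly[:, 1].min())), 0)
    x1 = min(int(math.ceil(poly[:, 1].max())) + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([xx.ravel(), yy.ravel()])  # MplPath wants (x, y)
    path = MplPath(poly[:, ::-1])
    inside = path.contains_points(pts).reshape(yy.shape)
    mask[y0:y1, x0:x1] = inside
    return mask


def _polygon_sum(img: np.ndarray, polygon: np.ndarray) -> tuple[float, int]:
    mask = rasterize_polygon(polygon, img.shape)
    return float(img[mask].sum()), int(mask.sum())


# --- relative intensity time courses -------------------------------


def luminal_relative_intensity(
    stack: ImageStack,
    channel: int,
    annotation: RoiAnnotation,
    box_side: int = 4,
) -> TimeCourse:
    """Background-subtracted center-box intensity, normalised to T0.

    ``RInt(Tn) = (Int_center - Int_bg)_Tn / (Int_center - Int_bg)_T0``;
    1.0 means no label entry into the lumen.
    """
    n = stack.data.shape[0]
    bg_center = _background_center(annotation.background_box)
    raw = np.empty(n)
    for t in range(n):
        c = tuple(annotation.center_track[t])
        raw[t] = (box_intensity(stack, t, channel, c, box_side)
                  - box_intensity(stack, t, channel, bg_center, box_side))
    if raw[0] <= 0:
        raise ValueError(
            "non-positive background-subtracted intensity at T0; "
            "check that the background ROI lies outside the embryo")
    return TimeCourse(stack.times, raw / raw[0], anchor_value=float(raw[0]),
                      kind="luminal_rint")


def surface_relative_intensity(
    stack: ImageStack,
    channel: int,
    annotation: RoiAnnotation,
) -> TimeCourse:
    """Donut unit-intensity between the two surface polygons, normalised.

    ``UI_phag = (Int_outer - Int_inner) / (Area_outer - Area_inner)``,
    ``UI_bg = Int_bg / Area_bg``,
    ``RInt(Tn) = (UI_phag - UI_bg)_Tn / (UI_phag - UI_bg)_T0``.
    """
    n = stack.data.shape[0]
    by, bx, bh, bw = annotation.background_box
    raw = np.empty(n)
    for t in range(n):
        img = stack.data[t, channel]
        int_out, area_out = _polygon_sum(img, annotation.outer_polygons[t])
        int_in, area_in = _polygon_sum(img, annotation.inner_polygons[t])
        if area_out - area_in < 1:
            raise ValueError(f"degenerate polygons at frame {t}: "
                             f"donut area {area_out - area_in} px^2")
        ui_phag = (int_out - int_in) / (area_out - area_in)
        ui_bg = float(img[by:by + bh, bx:bx + bw].sum()) / (bh * bw)
        raw[t] = ui_phag - ui_bg
    if raw[0] <= 0:
        raise ValueError("non-positive surface unit intensity at T0")
    return TimeCourse(stack.times, raw / raw[0], anchor_value=float(raw[0]),
                      kind="surface_rint")


def acidification_index(
    stack: ImageStack,
    gfp_channel: int,
    mcherry_channel: int,
    annotation: RoiAnnotation,
    box_side: int = 3,
    background_correct: bool = False,
) -> TimeCourse:
    """GFP/mCherry center-box ratio at Tn over the ratio at T0.

    By definition no background is subtracted; ``background_correct``
    enables an off-by-default corrected variant.
    """
    n = stack.data.shape[0]
    bg_center = _background_center(annotation.background_box)
    ratios = np.empty(n)
    for t in range(n):
        c = tuple(annotation.center_track[t])
        g = box_intensity(stack, t, gfp_channel, c, box_side)
        m = box_intensity(stack, t, mcherry_channel, c, box_side)
        if background_correct:
            g -= box_intensity(stack, t, gfp_channel, bg_center, box_side)
            m -= box_intensity(stack, t, mcherry_channel, bg_center, box_side)
        if m <= 0:
            raise ValueError(f"non-positive mCherry intensity at frame {t}; "
                             "acidification index undefined")
        ratios[t] = g / m
    return TimeCourse(stack.times, ratios / ratios[0], anchor_value=float(ratios[0]),
                      kind="acidification_index")


# --- disc diameter (FWHM) ------------------------------------------


def _fwhm_chord(profile: np.ndarray, center_idx: int, threshold: float) -> float | None:
    """Chord length where ``profile >= threshold`` around ``center_idx``.

    Crossing positions are linearly interpolated between pixels.
    """
    n = len(profile)
    if profile[center_idx] < threshold:
        return None
    i = center_idx
    while i > 0 and profile[i - 1] >= threshold:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        lo, hi = profile[i - 1], profile[i]
        left = (i - 1) + (threshold - lo) / (hi - lo)
    j = center_idx
    while j < n - 1 and profile[j + 1] >= threshold:
        j += 1
    if j == n - 1:
        right = float(n - 1)
    else:
        hi, lo = profile[j], profile[j + 1]
        right = j + (hi - threshold) / (hi - lo)
    return right - left


def measure_disc_diameter(
    stack: ImageStack,
    frame: int,
    channel: int,
    seed_point: tuple[float, float],
    min_contrast: float = 1.0,
) -> float:
    """FWHM diameter (um) of a bright disc at ``seed_point``.

    The threshold is halfway between the disc-center intensity (3x3
    mean around the seed) and the local background (median of the 10
    outermost pixels at each end of the profiles).  The diameter is the
    mean of the horizontal and vertical FWHM chords times the pixel
    size.  Returns ``nan`` when no above-threshold disc is found.
    """
    img = stack.data[frame, channel]
    h, w = img.shape
    cy = min(max(int(math.floor(seed_point[0] + 0.5)), 1), h - 2)
    cx = min(max(int(math.floor(seed_point[1] + 0.5)), 1), w - 2)
    center_val = float(img[cy - 1:cy + 2, cx - 1:cx + 2].mean())
    row = img[cy, :].astype(float)
    col = img[:, cx].astype(float)
    local_bg = float(np.median(np.concatenate([
        row[:10], row[-10:], col[:10], col[-10:]])))
    if center_val - local_bg < min_contrast:
        return math.nan
    threshold = local_bg + 0.5 * (center_val - local_bg)
    chord_h = _fwhm_chord(row, cx, threshold)
    chord_v = _fwhm_chord(col, cy, threshold)
    if chord_h is None or chord_v is None:
        return math.nan
    return 0.5 * (chord_h + chord_v) * stack.pixel_size


def disc_diameter_timecourse(
    stack: ImageStack,
    channel: int,
    annotation: RoiAnnotation,
) -> TimeCourse:
    """Per-frame disc diameters (um) along the annotated center track."""
    n = stack.data.shape[0]
    diam = np.array([
        measure_disc_diameter(stack, t, channel, tuple(annotation.center_track[t]))
        for t in range(n)
    ])
    anchor = diam[0] if len(diam) else math.nan
    return TimeCourse(stack.times, diam, anchor_value=float(anchor), kind="diameter_um")


def nuclear_diameter_ratio(
    stack: ImageStack,
    channel: int,
    annotation: RoiAnnotation,
) -> TimeCourse:
    """Nuclear disc diameter at Tn over the diameter at T0.

    Frames where the disc is not found propagate as ``nan``; an
    unmeasurable T0 raises.
    """
    diam = disc_diameter_timecourse(stack, channel, annotation)
    if not len(diam) or math.isnan(diam.values[0]) or diam.values[0] <= 0:
        raise ValueError("nuclear disc not measurable at T0")
    return TimeCourse(diam.times, diam.values / diam.values[0],
                      anchor_value=float(diam.values[0]), kind="diameter_ratio")
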