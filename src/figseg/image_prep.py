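"""Figure binarization and connected-component extraction.

The intensity histogram is thresholded with the triangle method (maximum
perpendicular distance between the histogram profile and the line joining
the peak with the far non-zero tail). Foreground is taken as the minority
side of the threshold, so both dark-on-light and light-on-dark panels
binarize the same way. Text regions are cleared, components are labeled
with 4-connectivity, small regions are dropped, and overlapping bounding
boxes are merged to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from figseg.geometry import BBox, bbox_overlaps, bbox_union

__all__ = [
    "ConnectedComponent",
    "to_gray",
    "intensity_histogram",
    "triangle_threshold",
    "binarize",
    "extract_components",
    "preprocess_figure",
    "DEFAULT_MIN_AREA",
]

DEFAULT_MIN_AREA = 50

# ITU-R BT.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ConnectedComponent:
    """A foreground region summarized by area and bounding box."""

    id: int
    area: int
    bbox: BBox

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("empty component")
        if self.area > self.bbox.area:
            raise ValueError("area exceeds bounding-box area")

    def to_dict(self) -> dict:
        return {"id": self.id, "area": self.area, "bbox": self.bbox.to_list()}


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an image array to uint8 grayscale (luma weights for RGB)."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def intensity_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a uint8 grayscale image."""
    return np.bincount(gray.ravel(), minlength=256)[:256]


def triangle_threshold(hist: np.ndarray) -> int:
    """Triangle-method threshold over a 256-bin histogram.

    A line is drawn from the histogram peak (bin of maximum count; lowest
    bin on ties) to the non-zero extreme bin farther from the peak. The
    returned threshold is the bin strictly between them whose count has
    the maximum perpendicular distance to that line; ties resolve to the
    bin nearest the tail, then to the lower bin index.
    """
    h = np.asarray(hist, dtype=np.float64)
    nz = np.flatnonzero(h)
    if nz.size == 0:
        raise ValueError("empty histogram")
    if nz.size == 1:
        warnings.warn("degenerate histogram with a single non-zero bin")
        return int(nz[0])

    peak = int(np.argmax(h))
    lo, hi = int(nz[0]), int(nz[-1])
    tail = lo if (peak - lo) >= (hi - peak) else hi

    lo_b, hi_b = (tail, peak) if tail < peak else (peak, tail)
    bins = np.arange(lo_b + 1, hi_b)
    if bins.size == 0:
        return peak

    # Perpendicular distance from (b, h[b]) to the peak-tail line.
    x1, y1 = float(peak), h[peak]
    x2, y2 = float(tail), h[tail]
    norm = np.hypot(y2 - y1, x2 - x1)
    dist = np.abs((y2 - y1) * bins - (x2 - x1) * h[bins] + x2 * y1 - y2 * x1) / norm

    best = dist.max()
    candidates = bins[np.isclose(dist, best, rtol=0.0, atol=1e-12)]
    # Tie: nearest the tail, then lower index.
    order = np.lexsort((candidates, np.abs(candidates - tail)))
    return int(candidates[order[0]])


def binarize(gray: np.ndarray, t: int) -> np.ndarray:
    """Boolean foreground mask from a gray image and a threshold.

    Foreground is the side of ``t`` holding the minority of pixels, which
    keeps ink as foreground for both polarities of figure.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold out of range: {t}")
    low = gray <= t
    n_low = int(low.sum())
    if n_low * 2 <= gray.size:
        return low
    return ~low


def extract_components(
    mask: np.ndarray,
    text_boxes: list[BBox] | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    text_box_padding: int = 0,
) -> list[ConnectedComponent]:
    """Label the mask (4-connectivity) and return merged component boxes.

    Pixels inside ``text_boxes`` (optionally padded) are cleared first;
    components smaller than ``min_area`` are dropped; overlapping bounding
    boxes are then merged transitively (union box, summed area) until no
    two boxes overlap.
    """
    work = np.asarray(mask, dtype=bool).copy()
    h, w = work.shape
    for tb in text_boxes or []:
        p = text_box_padding
        y0, y1 = max(0, tb.y_min - p), min(h, tb.y_max + p)
        x0, x1 = max(0, tb.x_min - p), min(w, tb.x_max + p)
        work[y0:y1, x0:x1] = False

    labeled = cc_label(work, connectivity=1)
    comps: list[ConnectedComponent] = []
    for i, rp in enumerate(regionprops(labeled)):
        if rp.area < min_area:
            continue
        y0, x0, y1, x1 = rp.bbox
        comps.append(ConnectedComponent(i, int(rp.area), BBox(x0, y0, x1, y1)))
    return merge_overlapping(comps)


def merge_overlapping(comps: list[ConnectedComponent]) -> list[ConnectedComponent]:
    """Merge components with overlapping boxes to a fixed point."""
    items = [(c.area, c.bbox) for c in comps]
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, BBox]] = []
        for area, box in items:
            for k, (oarea, obox) in enumerate(out):
                if bbox_overlaps(box, obox):
                    out[k] = (oarea + area, bbox_union(box, obox))
                    changed = True
                    break
            else:
                out.append((area, box))
        items = out
    items.sort(key=lambda ab: (ab[1].y_min, ab[1].x_min))
    return [ConnectedComponent(i, a, b) for i, (a, b) in enumerate(items)]


def preprocess_figure(
    img: np.ndarray,
    text_boxes: list[BBox] | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    text_box_padding: int = 0,
) -> tuple[np.ndarray, int, list[ConnectedComponent]]:
    """Full preprocessing: gray, threshold, binarize, extract components.

    Returns ``(mask, threshold, components)``.
    """
    gray = to_gray(img)
    hist = intensity_histogram(gray)
    if np.count_nonzero(hist) < 2:
        # Uniform image: nothing to segment.
        return np.zeros_like(gray, dtype=bool), int(gray.flat[0]), []
    t = triangle_threshold(hist)
    mask = binarize(gray, t)
    comps = extract_components(mask, text_boxes, min_area, text_box_padding)
    return mask, t, comps
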