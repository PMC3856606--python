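"""Figure--caption harvesting from a typed document operator stream.

The document is consumed as an ordered stream of text/image operators (a
thin adapter over a PDF layout parser can produce this; tests use the
synthetic generator). An event-driven finite state machine merges caption
paragraphs and collects placed images; logos outside the page text
rectangle are dropped, fragmented figures are reconstructed at the
resolution implied by their smallest scaling factor, spurious captions
(in-text figure citations) are removed by descriptor clustering, and
figures are matched to captions by a greedy minimum-cost assignment.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from figseg.geometry import BBox, bbox_min_distance, bbox_overlaps, bbox_union

__all__ = [
    "Operator",
    "CaptionObject",
    "FigureObject",
    "MatchCandidate",
    "extract_objects",
    "filter_logos",
    "merge_subfigures",
    "group_consecutive_figures",
    "caption_descriptor",
    "select_caption_group",
    "assign_column_tag",
    "match_document",
    "harvest_document",
    "read_operator_stream",
    "write_operator_stream",
    "DEFAULT_PENALTY",
]

log = logging.getLogger(__name__)

DEFAULT_PENALTY = 10.0

_CAPTION_CUE = re.compile(r"^\s*(?:fig\.?|figure)\b", re.IGNORECASE)
_FIGURE_NUMBER = re.compile(r"^\s*(?:fig\.?|figure)\s*\.?\s*(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class Operator:
    """One drawing operator of the document stream."""

    kind: str  # "text" | "image"
    page: int
    bbox: BBox  # placement rectangle in page coordinates
    text: str | None = None
    image: np.ndarray | None = None
    orientation: int = 0  # 0 / 90 / 180 / 270 degrees

    def __post_init__(self) -> None:
        if self.kind not in ("text", "image"):
            raise ValueError(f"unknown operator kind {self.kind!r}")
        if self.page < 0:
            raise ValueError("negative page index")
        if self.kind == "text" and self.text is None:
            raise ValueError("text operator without payload")
        if self.kind == "image" and self.image is None:
            raise ValueError("image operator without payload")
        if self.orientation not in (0, 90, 180, 270):
            raise ValueError(f"unsupported orientation {self.orientation}")


@dataclass
class CaptionObject:
    text: str
    page: int
    bbox: BBox
    column_tag: str = "double"
    figure_number: int | None = None
    descriptor: str | None = None


@dataclass
class FigureObject:
    image: np.ndarray
    page: int
    bbox: BBox  # placement on the page, page coordinates
    orientation: int = 0
    column_tag: str = "double"
    is_reconstructed: bool = False
    stream_index: int = 0

    @property
    def actual_size(self) -> tuple[int, int]:
        """(width, height) of the stored pixel array before placement."""
        h, w = self.image.shape[:2]
        return (w, h)


@dataclass(frozen=True)
class MatchCandidate:
    """A scored figure--caption pairing: cost = distance * penalty * disparity."""

    figure: FigureObject
    caption: CaptionObject
    distance: float
    penalty: float
    disparity: float = 1.0

    @property
    def cost(self) -> float:
        return self.distance * self.penalty * self.disparity


# ---------------------------------------------------------------------------
# FSM extraction


def _continues_paragraph(prev: Operator, op: Operator) -> bool:
    """Heuristic: a text operator continues the open caption paragraph when
    it sits on the same page, directly below the previous line (gap below
    1.5 line heights), with horizontal overlap."""
    if op.kind != "text" or op.page != prev.page:
        return False
    line_h = prev.bbox.height
    gap = op.bbox.y_min - prev.bbox.y_max
    if gap < -line_h or gap > 1.5 * line_h:
        return False
    return op.bbox.x_min < prev.bbox.x_max and prev.bbox.x_min < op.bbox.x_max


def _finalize_caption(lines: list[Operator]) -> CaptionObject:
    text = " ".join(op.text.strip() for op in lines)
    box = lines[0].bbox
    for op in lines[1:]:
        box = bbox_union(box, op.bbox)
    m = _FIGURE_NUMBER.match(text)
    number = int(m.group(1)) if m else None
    return CaptionObject(text, lines[0].page, box, figure_number=number)


def extract_objects(
    stream: list[Operator],
) -> tuple[list[CaptionObject], list[FigureObject]]:
    """Run the four-state FSM over the operator stream.

    Consecutive text operators forming one caption paragraph (starting with
    a figure cue) merge into one :class:`CaptionObject`; every image
    operator yields a :class:`FigureObject`. Exhausting the stream ends
    the machine cleanly from any state.
    """
    captions: list[CaptionObject] = []
    figures: list[FigureObject] = []
    pending: list[Operator] = []  # open caption lines ("Reading Caption")

    for idx, op in enumerate(stream):
        if not isinstance(op, Operator):
            log.warning("skipping malformed operator at index %d", idx)
            continue
        if pending:
            if _continues_paragraph(pending[-1], op):
                pending.append(op)
                continue
            captions.append(_finalize_caption(pending))
            pending = []
        if op.kind == "image":
            figures.append(
                FigureObject(
                    op.image,
                    op.page,
                    op.bbox,
                    orientation=op.orientation,
                    stream_index=idx,
                )
            )
        elif op.kind == "text" and _CAPTION_CUE.match(op.text):
            pending = [op]
    if pending:
        captions.append(_finalize_caption(pending))
    return captions, figures


# ---------------------------------------------------------------------------
# Figure filtering and N-to-1 reconstruction


def filter_logos(
    figures: list[FigureObject], text_rects: dict[int, BBox]
) -> list[FigureObject]:
    """Drop figures lying entirely outside the page text rectangle."""
    kept = []
    for fig in figures:
        rect = text_rects.get(fig.page)
        if rect is None:
            log.warning("page %d has no text rectangle; keeping figure", fig.page)
            kept.append(fig)
        elif bbox_overlaps(fig.bbox, rect):
            kept.append(fig)
    return kept


def _oriented(img: np.ndarray, orientation: int) -> np.ndarray:
    return np.rot90(img, k=orientation // 90) if orientation else img


def _nearest_resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    sh, sw = img.shape[:2]
    if (sh, sw) == (h, w):
        return img
    rows = np.minimum((np.arange(h) * sh) // h, sh - 1)
    cols = np.minimum((np.arange(w) * sw) // w, sw - 1)
    return img[np.ix_(rows, cols)]


def merge_subfigures(subfigs: list[FigureObject]) -> FigureObject:
    """Reconstruct one figure from N placed fragments.

    Each fragment's scaling factor is placed size over actual pixel size;
    the output canvas is the page-space bounding box of all placements
    rendered at the resolution implied by the smallest scaling factor, so
    the sharpest fragment loses no resolution.
    """
    if not subfigs:
        raise ValueError("no subfigures to merge")
    if len(subfigs) == 1:
        return subfigs[0]

    scales = []
    for f in subfigs:
        src = _oriented(f.image, f.orientation)
        sh, sw = src.shape[:2]
        scales.append(min(f.bbox.width / sw, f.bbox.height / sh))
    s_min = min(scales)

    union = subfigs[0].bbox
    for f in subfigs[1:]:
        union = bbox_union(union, f.bbox)
    canvas_w = max(1, round(union.width / s_min))
    canvas_h = max(1, round(union.height / s_min))
    canvas = np.full((canvas_h, canvas_w), 255, dtype=np.uint8)
    painted = np.zeros((canvas_h, canvas_w), dtype=bool)

    for f in subfigs:
        src = _oriented(f.image, f.orientation)
        x0 = round((f.bbox.x_min - union.x_min) / s_min)
        y0 = round((f.bbox.y_min - union.y_min) / s_min)
        tw = max(1, round(f.bbox.width / s_min))
        th = max(1, round(f.bbox.height / s_min))
        x0, y0 = min(x0, canvas_w - 1), min(y0, canvas_h - 1)
        tw, th = min(tw, canvas_w - x0), min(th, canvas_h - y0)
        tile = _nearest_resize(src, th, tw)
        if painted[y0 : y0 + th, x0 : x0 + tw].any():
            log.warning("overlapping subfigure placements; later fragment wins")
        canvas[y0 : y0 + th, x0 : x0 + tw] = tile
        painted[y0 : y0 + th, x0 : x0 + tw] = True

    return FigureObject(
        canvas,
        subfigs[0].page,
        union,
        is_reconstructed=True,
        stream_index=subfigs[0].stream_index,
    )


def group_consecutive_figures(
    figures: list[FigureObject],
) -> list[FigureObject]:
    """Merge runs of stream-consecutive figures on one page into single
    reconstructed figures (N-to-1 correspondence)."""
    out: list[FigureObject] = []
    run: list[FigureObject] = []
    for fig in sorted(figures, key=lambda f: f.stream_index):
        if run and (fig.page != run[-1].page or fig.stream_index != run[-1].stream_index + 1):
            out.append(merge_subfigures(run))
            run = []
        run.append(fig)
    if run:
        out.append(merge_subfigures(run))
    return out


# ---------------------------------------------------------------------------
# Caption filtering


def caption_descriptor(text: str) -> str:
    """Descriptor from the first two words with digit runs replaced by '#'.

    >>> caption_descriptor("Figure 2. Binding assay")
    'Figure #.'
    """
    words = text.split()
    if not words:
        raise ValueError("empty caption text")
    head = words[:2]
    return " ".join(re.sub(r"\d+", "#", w) for w in head)


def select_caption_group(captions: list[CaptionObject]) -> list[CaptionObject]:
    """Keep the descriptor cluster with the most unique figure links.

    Captions are clustered by identical descriptor; the cluster whose
    members reference the largest number of distinct figure numbers wins
    (ties go to the cluster appearing earliest in the document).
    """
    if not captions:
        return []
    clusters: dict[str, list[CaptionObject]] = {}
    for cap in captions:
        if cap.descriptor is None:
            cap.descriptor = caption_descriptor(cap.text)
        clusters.setdefault(cap.descriptor, []).append(cap)

    def score(members: list[CaptionObject]):
        unique = len({c.figure_number for c in members if c.figure_number is not None})
        first = min((c.page, c.bbox.y_min, c.bbox.x_min) for c in members)
        return (-unique, first)

    winner = min(clusters.values(), key=score)
    return winner


# ---------------------------------------------------------------------------
# Figure--caption matching


def assign_column_tag(bbox: BBox, text_rect: BBox, tol: float = 0.05) -> str:
    """left / right / double classification against the page text rectangle."""
    mid = (text_rect.x_min + text_rect.x_max) / 2.0
    slack = tol * text_rect.width
    if bbox.x_max <= mid + slack:
        return "left"
    if bbox.x_min >= mid - slack:
        return "right"
    return "double"


def _obj_key(obj) -> tuple:
    return (obj.page, obj.bbox.y_min, obj.bbox.x_min)


def _greedy(
    candidates: list[MatchCandidate],
) -> list[MatchCandidate]:
    """Repeatedly take the global-minimum-cost pair, removing both objects;
    ties resolve by lowest (page, y_min, x_min) of figure then caption."""
    pool = sorted(
        candidates,
        key=lambda mc: (mc.cost, _obj_key(mc.figure), _obj_key(mc.caption)),
    )
    used_f: set[int] = set()
    used_c: set[int] = set()
    out = []
    for mc in pool:
        if id(mc.figure) in used_f or id(mc.caption) in used_c:
            continue
        out.append(mc)
        used_f.add(id(mc.figure))
        used_c.add(id(mc.caption))
    return out


def match_document(
    figures: list[FigureObject],
    captions: list[CaptionObject],
    penalty_factor: float = DEFAULT_PENALTY,
) -> tuple[list[MatchCandidate], list[FigureObject], list[CaptionObject]]:
    """Greedy minimum-cost 1-to-1 figure--caption matching.

    Per page: a lone figure and lone caption pair directly; otherwise a
    cost matrix ``C = d * p`` (p = 1 for a shared column tag, else
    ``penalty_factor``) is consumed greedily. Leftovers from all pages are
    pooled with ``C = d * p * disparity`` where
    ``disparity = 1 + |page(figure) - page(caption)|``.

    Returns (matches, unmatched figures, unmatched captions).
    """
    matches: list[MatchCandidate] = []
    leftover_f: list[FigureObject] = []
    leftover_c: list[CaptionObject] = []

    pages = sorted({f.page for f in figures} | {c.page for c in captions})
    for page in pages:
        figs = [f for f in figures if f.page == page]
        caps = [c for c in captions if c.page == page]
        if len(figs) == 1 and len(caps) == 1:
            f, c = figs[0], caps[0]
            p = 1.0 if f.column_tag == c.column_tag else penalty_factor
            matches.append(MatchCandidate(f, c, bbox_min_distance(f.bbox, c.bbox), p))
            continue
        cands = [
            MatchCandidate(
                f,
                c,
                bbox_min_distance(f.bbox, c.bbox),
                1.0 if f.column_tag == c.column_tag else penalty_factor,
            )
            for f in figs
            for c in caps
        ]
        page_matches = _greedy(cands)
        matches.extend(page_matches)
        matched_f = {id(m.figure) for m in page_matches}
        matched_c = {id(m.caption) for m in page_matches}
        leftover_f.extend(f for f in figs if id(f) not in matched_f)
        leftover_c.extend(c for c in caps if id(c) not in matched_c)

    if leftover_f and leftover_c:
        cands = [
            MatchCandidate(
                f,
                c,
                bbox_min_distance(f.bbox, c.bbox),
                1.0 if f.column_tag == c.column_tag else penalty_factor,
                disparity=1.0 + abs(f.page - c.page),
            )
            for f in leftover_f
            for c in leftover_c
        ]
        cross = _greedy(cands)
        matches.extend(cross)
        matched_f = {id(m.figure) for m in cross}
        matched_c = {id(m.caption) for m in cross}
        leftover_f = [f for f in leftover_f if id(f) not in matched_f]
        leftover_c = [c for c in leftover_c if id(c) not in matched_c]

    for f in leftover_f:
        log.warning("unmatched figure on page %d at %s", f.page, f.bbox.to_list())
    for c in leftover_c:
        log.warning("unmatched caption on page %d: %.40s", c.page, c.text)
    return matches, leftover_f, leftover_c


def harvest_document(
    stream: list[Operator],
    text_rects: dict[int, BBox],
    penalty_factor: float = DEFAULT_PENALTY,
) -> tuple[list[MatchCandidate], list[FigureObject], list[CaptionObject]]:
    """Full harvesting pipeline over one operator stream."""
    captions, figures = extract_objects(stream)
    figures = filter_logos(figures, text_rects)
    figures = group_consecutive_figures(figures)
    captions = select_caption_group(captions)
    for fig in figures:
        rect = text_rects.get(fig.page)
        if rect is not None:
            fig.column_tag = assign_column_tag(fig.bbox, rect)
    for cap in captions:
        rect = text_rects.get(cap.page)
        if rect is not None:
            cap.column_tag = assign_column_tag(cap.bbox, rect)
    return match_document(figures, captions, penalty_factor)


# ---------------------------------------------------------------------------
# Operator stream I/O (JSON lines; image pixels referenced as PNG files)


def write_operator_stream(
    stream: list[Operator], path: str | Path, image_dir: str | Path | None = None
) -> None:
    """Write operators as JSON lines; image payloads go to PNG files next
    to the stream (referenced by relative path)."""
    from PIL import Image

    path = Path(path)
    image_dir = Path(image_dir) if image_dir else path.parent
    image_dir.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, op in enumerate(stream):
            rec: dict = {"kind": op.kind, "page": op.page, "bbox": op.bbox.to_list()}
            if op.kind == "text":
                rec["text"] = op.text
            else:
                ref = f"{path.stem}_img{i}.png"
                Image.fromarray(op.image).save(image_dir / ref)
                rec["image_ref"] = ref
                rec["placement"] = {"orientation": op.orientation}
            fh.write(json.dumps(rec) + "\n")


def read_operator_stream(path: str | Path) -> list[Operator]:
    """Read a JSONL operator stream, loading referenced images from the
    same directory."""
    from PIL import Image

    path = Path(path)
    ops: list[Operator] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            bbox = BBox.from_list(rec["bbox"])
            if rec["kind"] == "text":
                ops.append(Operator("text", rec["page"], bbox, text=rec["text"]))
            else:
                img = np.asarray(Image.open(path.parent / rec["image_ref"]))
                orientation = rec.get("placement", {}).get("orientation", 0)
                ops.append(
                    Operator(
                        "image", rec["page"], bbox, image=img, orientation=orientation
                    )
                )
    return ops
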